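"""Approximate-Bayes-factor colocalization of two traits in a gene region.

Per-variant evidence for association with each trait is summarized by the
Wakefield approximate Bayes factor computed from the estimated effect and its
standard error: with V = se^2, W = prior_sd^2, z = beta/se and r = W/(V+W),

    log ABF = 0.5 * (log(1 - r) + r * z^2).

Five hypotheses are compared over a region: H0 no association with either
trait, H1/H2 association with one trait only, H3 two distinct causal
variants, H4 one shared causal variant. Posterior probabilities combine the
per-variant Bayes factors with per-variant priors p1, p2 (single-trait) and
p12 (shared), assuming at most one causal variant per trait. The conditional
probability PP4/(PP3+PP4) expresses colocalization given that the second
trait has a causal variant in the region, which is informative when power
for the outcome trait is low. All sums are done in log space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

from .instruments import GeneRegion
from .sumstats import InputError, SummaryDataset, VariantAssociation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColocConfig:
    """Priors and filters for regional colocalization."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_sd_quant: float = 0.15
    prior_sd_binary: float = 0.2
    maf_min: float = 0.001

    def __post_init__(self) -> None:
        if min(self.p1, self.p2, self.p12) <= 0:
            raise ValueError("all priors must be positive")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0, 0.5)")

    def prior_sd(self, trait_type: str) -> float:
        return self.prior_sd_binary if trait_type == "binary" else self.prior_sd_quant


@dataclass
class ColocResult:
    pp: np.ndarray  # PP0..PP4
    conditional_pp4: float | None
    per_variant_h4: pd.Series  # indexed by variant_id, sums to 1
    lead_variant: str
    n_variants_tested: int

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        if abs(self.pp.sum() - 1.0) > 1e-9:
            raise ValueError("posterior probabilities must sum to 1")
        if abs(float(self.per_variant_h4.sum()) - 1.0) > 1e-9:
            raise ValueError("per-variant shared-signal posteriors must sum to 1")

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    def to_dict(self) -> dict:
        return {
            "pp": {f"PP{h}": float(p) for h, p in enumerate(self.pp)},
            "conditional_pp4": self.conditional_pp4,
            "lead_variant": self.lead_variant,
            "lead_variant_h4": float(self.per_variant_h4.max()),
            "n_variants_tested": self.n_variants_tested,
        }


def log_abf(v: VariantAssociation | float, se: float | None = None,
            prior_sd: float = 0.15) -> float:
    """Wakefield log approximate Bayes factor for one association."""
    if isinstance(v, VariantAssociation):
        beta, se = v.beta, v.se
    else:
        beta = float(v)
    if se is None or not se > 0:
        raise ValueError("se must be positive")
    V = se * se
    W = prior_sd * prior_sd
    if W == 0:
        return 0.0
    r = W / (V + W)
    z = beta / se
    return 0.5 * (math.log1p(-r) + r * z * z)


def _region_frame(ds: SummaryDataset, region: GeneRegion, maf_min: float) -> pd.DataFrame:
    df = ds.df
    mask = ((df["chromosome"].astype(str) == region.chromosome)
            & (df["position"] >= region.start - region.flank)
            & (df["position"] <= region.end + region.flank))
    sub = df[mask]
    maf = np.minimum(sub["eaf"], 1 - sub["eaf"])
    # variants without a frequency cannot be MAF-filtered; keep them
    return sub[maf.isna() | (maf > maf_min)]


def colocalize(trait1: SummaryDataset, trait2: SummaryDataset, region: GeneRegion,
               cfg: ColocConfig = ColocConfig()) -> ColocResult:
    """Posterior probabilities PP0..PP4 for two traits sharing a causal variant.

    Only variants present in both traits within the region (after the MAF
    filter) are tested; with a single shared variant the distinct-variant
    hypothesis H3 is undefined and its posterior is set to zero.
    """
    d1 = _region_frame(trait1, region, cfg.maf_min).set_index("variant_id")
    d2 = _region_frame(trait2, region, cfg.maf_min).set_index("variant_id")
    shared = d1.index.intersection(d2.index)
    if len(shared) == 0:
        raise InputError(f"{region.gene_name}: no shared variants in region after MAF filter")
    d1, d2 = d1.loc[shared], d2.loc[shared]

    sd1 = cfg.prior_sd(trait1.trait_type)
    sd2 = cfg.prior_sd(trait2.trait_type)
    z1 = d1["beta"] / d1["se"]
    z2 = d2["beta"] / d2["se"]
    r1 = sd1**2 / (d1["se"] ** 2 + sd1**2)
    r2 = sd2**2 / (d2["se"] ** 2 + sd2**2)
    lbf1 = (0.5 * (np.log1p(-r1) + r1 * z1**2)).to_numpy()
    lbf2 = (0.5 * (np.log1p(-r2) + r2 * z2**2)).to_numpy()

    s1 = float(logsumexp(lbf1))
    s2 = float(logsumexp(lbf2))
    s12 = float(logsumexp(lbf1 + lbf2))
    # sum over ordered pairs i != j of BF1_i * BF2_j, in log space
    if len(shared) == 1 or s12 >= s1 + s2:
        if len(shared) > 1:
            logger.info("%s: cross-pair sum not positive; PP3 set to 0", region.gene_name)
        else:
            logger.info("%s: single shared variant; PP3 undefined, set to 0", region.gene_name)
        s3 = -np.inf
    else:
        s3 = (s1 + s2) + math.log1p(-math.exp(s12 - s1 - s2))

    log_post = np.array([
        0.0,
        math.log(cfg.p1) + s1,
        math.log(cfg.p2) + s2,
        math.log(cfg.p1) + math.log(cfg.p2) + s3,
        math.log(cfg.p12) + s12,
    ])
    pp = softmax(log_post)

    denom = pp[3] + pp[4]
    conditional = float(pp[4] / denom) if denom > 0 else None

    h4 = pd.Series(softmax(lbf1 + lbf2), index=shared, name="h4_posterior")
    lead = str(h4.idxmax())
    return ColocResult(pp, conditional, h4, lead, int(len(shared)))


def conditional_probability(res: ColocResult) -> float | None:
    """PP4 / (PP3 + PP4): colocalization given a causal variant for trait 2."""
    denom = float(res.pp[3] + res.pp[4])
    if denom == 0:
        return None
    return float(res.pp[4] / denom)
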