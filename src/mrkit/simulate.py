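"""Synthetic GWAS summary statistics with known truth.

Three generators emulate the statistical structure of the study data:

* :func:`simulate_genome` — genome-wide significant exposure variants for a
  quantitative trait (plasma lipid level, SD units) together with a binary
  outcome GWAS (log-odds scale) in which each variant's outcome effect is a
  cluster-specific linear function of its exposure effect: substantive
  clusters have Gamma_j = mu_k * gamma_j, a null cluster has Gamma_j = 0 and
  a junk cluster draws Gamma_j from an independent pleiotropy distribution.
  Standard errors use the standardized-genotype approximation
  se = 1/sqrt(n), with the binomial variance factor n*phi*(1-phi) for the
  binary outcome.
* :func:`simulate_region` — a cis region of correlated variants (AR(1) LD)
  for two traits whose z-score vectors are drawn from the multivariate
  normal sampling model z ~ MVN(sqrt(n) R b, R), with causal configurations
  for the colocalization hypotheses (shared, distinct, trait1_only, none).
* :func:`simulate_multistudy` — several outcome studies sharing (or not)
  the same true causal slopes, for meta-analysis tests.

All generators are fully deterministic given their config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import RatioEstimate
from .instruments import GENOME_WIDE_P
from .sumstats import CANONICAL, LDMatrix, SummaryDataset

_Z_GW = float(stats.norm.isf(GENOME_WIDE_P / 2))  # two-sided genome-wide z
_ALLELES = np.array(["A", "C", "G", "T"])
_REJECTION_CAP = 10_000


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GenomeSimConfig:
    """Genome-wide generator settings.

    Defaults follow the study conditions: a very large exposure GWAS
    (~1.2M, the lipid-consortium scale), a biobank-sized binary outcome
    (~367k with ~8.3% cases), and substantive clusters with opposing
    slopes plus null and junk variants.
    """

    n_variants: int = 100
    cluster_slopes: tuple[float, ...] = (-0.3, 0.4)
    cluster_weights: tuple[float, ...] = (0.4, 0.4)  # substantive, in slope order
    null_weight: float = 0.15
    junk_weight: float = 0.05
    exposure_n: int = 1_200_000
    outcome_n: int = 367_289
    outcome_case_fraction: float = 0.083
    exposure_effect_sd: float = 0.05
    junk_pleiotropy_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cluster_slopes) != len(self.cluster_weights):
            raise SimulationConfigError("cluster_slopes and cluster_weights differ in length")
        total = sum(self.cluster_weights) + self.null_weight + self.junk_weight
        if abs(total - 1.0) > 1e-9:
            raise SimulationConfigError(f"component weights sum to {total}, not 1")
        if self.exposure_n <= 0 or self.outcome_n <= 0:
            raise SimulationConfigError("sample sizes must be positive")
        if not (0 < self.outcome_case_fraction < 1):
            raise SimulationConfigError("case fraction must lie in (0,1)")


@dataclass(frozen=True)
class RegionSimConfig:
    """Cis-region generator settings for colocalization tests."""

    n_variants: int = 200
    ld_rho: float = 0.9
    causal_mode: str = "shared"  # shared | distinct | trait1_only | none
    causal_betas: tuple[float, float] = (0.05, 0.05)
    n1: int = 50_000
    n2: int = 50_000
    chromosome: str = "5"
    region_start: int = 1_000_000
    position_step: int = 1_000
    causal_index: int | None = None
    causal_index2: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.ld_rho) < 1:
            raise SimulationConfigError("|ld_rho| must be < 1")
        if self.causal_mode not in ("shared", "distinct", "trait1_only", "none"):
            raise SimulationConfigError(f"unknown causal_mode {self.causal_mode!r}")
        for idx in (self.causal_index, self.causal_index2):
            if idx is not None and not (0 <= idx < self.n_variants):
                raise SimulationConfigError(f"causal index {idx} out of range")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    cluster_labels: list[str] | None = None  # per-variant: "cluster_k" | "null" | "junk"
    true_slopes: dict[str, float] = field(default_factory=dict)
    true_exposure_betas: np.ndarray | None = None
    true_outcome_betas: np.ndarray | None = None
    causal_variants: dict[str, str | None] = field(default_factory=dict)


def _random_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-palindromic allele pairs so harmonization keeps every variant."""
    pairs = np.array([("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                      ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")])
    pick = rng.integers(0, len(pairs), size=n)
    return pairs[pick, 0], pairs[pick, 1]


def _dataset(ids, chrom, pos, ea, oa, eaf, beta, se, n, trait_name, trait_type,
             case_fraction=None) -> SummaryDataset:
    z = beta / se
    df = pd.DataFrame({
        "variant_id": ids, "chromosome": chrom, "position": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se,
        "p_value": np.clip(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0),
        "n": n,
    })[list(CANONICAL)]
    return SummaryDataset(trait_name, trait_type, df, case_fraction)


def _draw_genome_truth(cfg: GenomeSimConfig, rng: np.random.Generator):
    """True effects and variant metadata shared by every study observing them."""
    J = cfg.n_variants
    se_g = 1.0 / np.sqrt(cfg.exposure_n)

    # true exposure effects, conditioned to be genome-wide detectable
    gamma = np.empty(J)
    thresh = _Z_GW * se_g
    for j in range(J):
        for _ in range(_REJECTION_CAP):
            draw = rng.normal(0.0, cfg.exposure_effect_sd)
            if abs(draw) > thresh:
                gamma[j] = draw
                break
        else:
            raise SimulationConfigError(
                "rejection sampling exhausted: increase exposure_effect_sd "
                f"(threshold |gamma| > {thresh:.4g})")

    components = [f"cluster_{k}" for k in range(len(cfg.cluster_slopes))] + ["null", "junk"]
    weights = list(cfg.cluster_weights) + [cfg.null_weight, cfg.junk_weight]
    labels = rng.choice(len(components), size=J, p=np.array(weights) / np.sum(weights))

    Gamma = np.zeros(J)
    for j, lab in enumerate(labels):
        name = components[lab]
        if name.startswith("cluster_"):
            Gamma[j] = cfg.cluster_slopes[lab] * gamma[j]
        elif name == "junk":
            Gamma[j] = rng.normal(0.0, cfg.junk_pleiotropy_sd)

    meta = {
        "eaf": rng.uniform(0.05, 0.95, size=J),
        "alleles": _random_alleles(rng, J),
        "ids": [f"rs{j+1}" for j in range(J)],
        "chrom": [str(j % 22 + 1) for j in range(J)],
        "pos": [1_000_000 + 10_000 * j for j in range(J)],
    }
    truth = SimTruth(
        cluster_labels=[components[lab] for lab in labels],
        true_slopes={f"cluster_{k}": s for k, s in enumerate(cfg.cluster_slopes)},
        true_exposure_betas=gamma, true_outcome_betas=Gamma)
    return gamma, Gamma, meta, truth


def _observe_study(gamma, Gamma, meta, cfg: GenomeSimConfig,
                   rng: np.random.Generator) -> tuple[SummaryDataset, SummaryDataset]:
    """Observed exposure/outcome GWAS: study-specific noise around the truth."""
    J = gamma.size
    se_g = 1.0 / np.sqrt(cfg.exposure_n)
    phi = cfg.outcome_case_fraction
    se_G = 1.0 / np.sqrt(cfg.outcome_n * phi * (1 - phi))
    ea, oa = meta["alleles"]
    exposure = _dataset(meta["ids"], meta["chrom"], meta["pos"], ea, oa,
                        meta["eaf"], rng.normal(gamma, se_g),
                        np.full(J, se_g), cfg.exposure_n, "exposure", "quantitative")
    outcome = _dataset(meta["ids"], meta["chrom"], meta["pos"], ea, oa,
                       meta["eaf"], rng.normal(Gamma, se_G),
                       np.full(J, se_G), cfg.outcome_n, "outcome", "binary",
                       case_fraction=phi)
    return exposure, outcome


def simulate_genome(cfg: GenomeSimConfig) -> tuple[SummaryDataset, SummaryDataset, SimTruth]:
    """Exposure and outcome summary statistics for independent genome-wide variants."""
    rng = np.random.default_rng(cfg.seed)
    gamma, Gamma, meta, truth = _draw_genome_truth(cfg, rng)
    exposure, outcome = _observe_study(gamma, Gamma, meta, cfg, rng)
    return exposure, outcome, truth


def ar1_correlation(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_region(cfg: RegionSimConfig) -> tuple[SummaryDataset, SummaryDataset,
                                                   LDMatrix, SimTruth]:
    """Two traits over one LD region, under a chosen causal configuration."""
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_variants
    R = ar1_correlation(J, cfg.ld_rho)
    chol = np.linalg.cholesky(R + 1e-10 * np.eye(J))

    i1 = cfg.causal_index if cfg.causal_index is not None else J // 2
    if cfg.causal_index2 is not None:
        i2 = cfg.causal_index2
    else:
        i2 = (i1 + J // 2) % J  # far apart: negligible LD under AR(1)

    b1 = np.zeros(J)
    b2 = np.zeros(J)
    if cfg.causal_mode in ("shared", "distinct", "trait1_only"):
        b1[i1] = cfg.causal_betas[0]
    if cfg.causal_mode == "shared":
        b2[i1] = cfg.causal_betas[1]
    elif cfg.causal_mode == "distinct":
        b2[i2] = cfg.causal_betas[1]

    traits = []
    for b, n, name in ((b1, cfg.n1, "trait1"), (b2, cfg.n2, "trait2")):
        mean = np.sqrt(n) * (R @ b)
        z = mean + chol @ rng.standard_normal(J)
        se = np.full(J, 1.0 / np.sqrt(n))
        traits.append((z * se, se, n, name))

    eaf = rng.uniform(0.05, 0.95, size=J)
    ea, oa = _random_alleles(rng, J)
    ids = [f"rs{j+1}" for j in range(J)]
    pos = [cfg.region_start + cfg.position_step * j for j in range(J)]
    chrom = [cfg.chromosome] * J

    datasets = [
        _dataset(ids, chrom, pos, ea, oa, eaf, beta, se, n, name, "quantitative")
        for beta, se, n, name in traits
    ]
    truth = SimTruth(causal_variants={
        "trait1": ids[i1] if cfg.causal_mode != "none" else None,
        "trait2": (ids[i1] if cfg.causal_mode == "shared"
                   else ids[i2] if cfg.causal_mode == "distinct" else None),
    })
    return datasets[0], datasets[1], LDMatrix(ids, R), truth


def simulate_multistudy(configs: Sequence[GenomeSimConfig], shared_truth: bool = True,
                        seed: int | None = None,
                        ) -> list[tuple[SummaryDataset, SummaryDataset, SimTruth]]:
    """Several studies of the same variants with independent sampling noise.

    With ``shared_truth`` the per-variant true effects are drawn once from the
    first config and every study observes them with its own noise — the
    fixed-effects regime. Otherwise each study draws its own truth.
    """
    if len(configs) < 2:
        raise SimulationConfigError("multistudy simulation needs at least two configs")
    rng = np.random.default_rng(seed)
    if shared_truth:
        if len({cfg.n_variants for cfg in configs}) != 1:
            raise SimulationConfigError("shared truth requires equal n_variants")
        gamma, Gamma, meta, truth = _draw_genome_truth(configs[0], rng)
        return [(*_observe_study(gamma, Gamma, meta, cfg, rng), truth)
                for cfg in configs]
    out = []
    for cfg in configs:
        study_seed = int(rng.integers(0, 2**31 - 1))
        out.append(simulate_genome(replace(cfg, seed=study_seed)))
    return out


def simulate_wald_ratios(means: Sequence[float], weights: Sequence[float],
                         sigma: float | Sequence[float], n_variants: int,
                         seed: int | None = None, null_weight: float = 0.0,
                         junk_weight: float = 0.0, junk_sd: float = 1.0,
                         ) -> tuple[list[RatioEstimate], list[str]]:
    """Variant-level ratio estimates drawn directly around cluster means.

    A lightweight front door to the clustering model: theta_j ~ N(mu_c, sigma_j^2)
    for substantive clusters, N(0, sigma_j^2) for null, N(0, junk_sd^2 + sigma_j^2)
    for junk. Returns the ratios and the true component labels.
    """
    total = sum(weights) + null_weight + junk_weight
    if abs(total - 1.0) > 1e-9:
        raise SimulationConfigError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    comps = [f"cluster_{k}" for k in range(len(means))] + ["null", "junk"]
    p = np.array(list(weights) + [null_weight, junk_weight])
    labels_idx = rng.choice(len(comps), size=n_variants, p=p / p.sum())
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), (n_variants,)).copy()
    theta = np.empty(n_variants)
    for j, li in enumerate(labels_idx):
        if comps[li] == "null":
            theta[j] = rng.normal(0.0, sig[j])
        elif comps[li] == "junk":
            theta[j] = rng.normal(0.0, np.sqrt(junk_sd**2 + sig[j] ** 2))
        else:
            theta[j] = rng.normal(means[li], sig[j])
    ratios = [RatioEstimate(f"rs{j+1}", float(theta[j]), float(sig[j]))
              for j in range(n_variants)]
    return ratios, [comps[li] for li in labels_idx]
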