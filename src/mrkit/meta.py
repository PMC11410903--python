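"""Cross-study meta-analysis of MR estimates and subgroup comparison.

Per-study causal estimates are pooled by inverse-variance weighting. The
``auto`` rule follows common practice for multi-biobank MR: a fixed-effects
pool unless Cochran's Q suggests heterogeneity (q_p below ``het_alpha``),
in which case a DerSimonian-Laird random-effects pool is used, with
tau^2 = max(0, (Q - (S-1)) / (sum w - sum w^2 / sum w)) and weights
1/(se_s^2 + tau^2). Subgroup (e.g. sex or ancestry) differences are tested
with a two-sided z-test on the difference of estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import MREstimate


@dataclass(frozen=True)
class MetaResult:
    pooled_slope: float
    pooled_se: float
    model: str  # "fixed" | "random"
    q_statistic: float
    q_p_value: float
    tau2: float
    study_labels: list[str]

    def __post_init__(self) -> None:
        if self.model == "fixed" and self.tau2 != 0.0:
            raise ValueError("tau2 must be 0 under a fixed-effects model")
        if self.q_statistic < 0:
            raise ValueError("negative Q statistic")

    @property
    def ci(self) -> tuple[float, float]:
        z = stats.norm.ppf(0.975)
        return (self.pooled_slope - z * self.pooled_se,
                self.pooled_slope + z * self.pooled_se)

    @property
    def p_value(self) -> float:
        return float(2 * stats.norm.sf(abs(self.pooled_slope / self.pooled_se)))


def meta_analyze(estimates: Sequence[MREstimate], rule: str = "auto",
                 het_alpha: float = 0.05,
                 study_labels: Sequence[str] | None = None) -> MetaResult:
    """Pool per-study estimates; switch to random effects on heterogeneity."""
    if len(estimates) < 2:
        raise ValueError("meta-analysis requires at least two studies")
    orientations = {e.orientation for e in estimates}
    if len(orientations) > 1:
        raise ValueError(f"mixed orientations across studies: {sorted(orientations)}")
    b = np.array([e.slope for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    labels = list(study_labels) if study_labels is not None else [
        f"study_{i+1}" for i in range(len(estimates))]

    w = 1.0 / se**2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    q = max(float(np.sum(w * (b - pooled) ** 2)), 0.0)
    df = len(b) - 1
    q_p = float(stats.chi2.sf(q, df))

    model = rule
    if rule == "auto":
        model = "random" if q_p < het_alpha else "fixed"

    tau2 = 0.0
    if model == "random":
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        w_star = 1.0 / (se**2 + tau2)
        pooled = float(np.sum(w_star * b) / np.sum(w_star))
        pooled_se = float(np.sum(w_star) ** -0.5)

    return MetaResult(pooled, pooled_se, model, q, q_p, tau2, labels)


def subgroup_z_test(a: MREstimate, b: MREstimate) -> tuple[float, float]:
    """Two-sided z-test for a difference between two subgroup estimates."""
    if a.orientation != b.orientation:
        raise ValueError("subgroup estimates must share an orientation")
    z = (a.slope - b.slope) / np.sqrt(a.se**2 + b.se**2)
    return float(z), float(2 * stats.norm.sf(abs(z)))
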