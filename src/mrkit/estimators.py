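"""Causal-effect estimators for two-sample summary-data MR.

The estimators regress per-variant outcome associations (Gamma, log-odds for
a binary outcome) on exposure associations (gamma, SD units) with
inverse-variance weights 1/se(Gamma)^2 (first-order weights, ignoring
exposure error):

* ``IVWEstimator`` — weighted regression through the origin; equivalently
  the inverse-variance-weighted average of per-variant Wald ratios
  Gamma_j/gamma_j. Fixed-effect se, or multiplicative random-effects se
  inflated by max(1, sqrt(Q/(J-1))); the ``auto`` rule uses fixed effects
  for three or fewer instruments and random effects for four or more.
  An LD correlation matrix switches the fit to generalized weighted least
  squares with covariance Omega_ij = se(Gamma_i) se(Gamma_j) rho_ij.
* ``EggerEstimator`` — the same regression with an intercept after
  orienting all exposure effects positive; a non-zero intercept indicates
  directional pleiotropy.
* ``WeightedMedianEstimator`` — weighted median of Wald ratios with a
  parametric-bootstrap standard error; consistent when instruments carrying
  at least half the weight are valid.

All classes follow the scikit-learn estimator protocol: hyperparameters in
``__init__``, ``fit(X, y, ...)``, fitted attributes with a trailing
underscore, and ``predict``. Confidence intervals and p-values use the
normal distribution, the convention for summary-data MR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .sumstats import HarmonizedInstrument, LDMatrix

logger = logging.getLogger(__name__)

Z95 = float(stats.norm.ppf(0.975))
OMEGA_RIDGE = 1e-8


class DegenerateInstrumentError(ValueError):
    """The exposure association is zero; the Wald ratio is undefined."""


class MethodInapplicableError(ValueError):
    """Too few instruments for the requested estimator."""


@dataclass(frozen=True)
class RatioEstimate:
    """Per-variant Wald ratio theta = Gamma/gamma with first-order se."""

    variant_id: str
    theta: float
    theta_se: float

    def __post_init__(self) -> None:
        if not self.theta_se > 0:
            raise ValueError(f"{self.variant_id}: theta_se must be positive")


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate per 1-SD change in the exposure."""

    method: str
    slope: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_snps: int
    q_statistic: float | None = None
    q_p_value: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    orientation: str = "raising"

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("se must be positive")
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("slope outside its confidence interval")
        if self.q_statistic is not None and self.q_statistic < -1e-12:
            raise ValueError("negative Q statistic")

    def odds_ratio(self) -> tuple[float, float, float]:
        """exp-transformed (OR, low, high) — meaningful for binary outcomes."""
        return float(np.exp(self.slope)), float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _unpack(instruments: Sequence[HarmonizedInstrument]):
    g = np.array([i.exposure_beta for i in instruments], dtype=float)
    gs = np.array([i.exposure_se for i in instruments], dtype=float)
    G = np.array([i.outcome_beta for i in instruments], dtype=float)
    Gs = np.array([i.outcome_se for i in instruments], dtype=float)
    return g, gs, G, Gs


def _normal_p(z: np.ndarray | float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _omega(outcome_se: np.ndarray, rho: np.ndarray) -> np.ndarray:
    omega = np.outer(outcome_se, outcome_se) * rho
    min_eig = float(np.linalg.eigvalsh(omega)[0])
    if min_eig <= 0:
        # ridge-condition only when needed, so a well-posed Omega is untouched
        omega = omega + OMEGA_RIDGE * np.eye(len(outcome_se))
        min_eig = float(np.linalg.eigvalsh(omega)[0])
        if min_eig <= 0:
            raise np.linalg.LinAlgError(
                "instrument covariance not positive definite "
                f"(min eigenvalue {min_eig:.3e})")
    return omega


def wald_ratio(inst: HarmonizedInstrument) -> RatioEstimate:
    """Single-variant causal estimate: outcome effect over exposure effect."""
    if inst.exposure_beta == 0:
        raise DegenerateInstrumentError(f"{inst.variant_id}: zero exposure effect")
    theta = inst.outcome_beta / inst.exposure_beta
    return RatioEstimate(inst.variant_id, theta, inst.outcome_se / abs(inst.exposure_beta))


def wald_ratios(instruments: Sequence[HarmonizedInstrument]) -> list[RatioEstimate]:
    return [wald_ratio(i) for i in instruments]


class IVWEstimator(RegressorMixin, BaseEstimator):
    """Inverse-variance-weighted MR, optionally with correlated instruments.

    Parameters
    ----------
    effects_model : {"auto", "fixed", "random"}
        ``auto`` uses fixed effects for J <= 3 instruments and multiplicative
        random effects for J >= 4.
    """

    def __init__(self, effects_model: str = "auto"):
        self.effects_model = effects_model

    def fit(self, X, y, outcome_se=None, ld=None):
        """Fit the weighted origin regression of outcome on exposure effects.

        Parameters
        ----------
        X : array-like, shape (J,) or (J, 1) — exposure betas gamma_j
        y : array-like, shape (J,) — outcome betas Gamma_j
        outcome_se : array-like, shape (J,) — se(Gamma_j), required
        ld : optional (J, J) signed correlation matrix for GLS weighting
        """
        g = np.asarray(X, dtype=float).reshape(-1)
        G = np.asarray(y, dtype=float).reshape(-1)
        if outcome_se is None:
            raise ValueError("outcome_se is required")
        Gs = np.asarray(outcome_se, dtype=float).reshape(-1)
        J = g.size
        if J < 1:
            raise MethodInapplicableError("IVW requires at least one instrument")
        if np.any(g == 0):
            raise DegenerateInstrumentError("zero exposure effect among instruments")

        model = self.effects_model
        if model == "auto":
            model = "fixed" if J <= 3 else "random"
        if model == "random" and J == 1:
            logger.warning("single instrument: falling back to fixed effects")
            model = "fixed"

        if ld is not None:
            omega_inv = np.linalg.inv(_omega(Gs, np.asarray(ld, dtype=float)))
            gWg = float(g @ omega_inv @ g)
            slope = float(g @ omega_inv @ G) / gWg
            se_fixed = gWg ** -0.5
            resid = G - slope * g
            q = float(resid @ omega_inv @ resid)
        else:
            w = 1.0 / Gs**2
            gWg = float(np.sum(g * g * w))
            slope = float(np.sum(g * G * w)) / gWg
            se_fixed = gWg ** -0.5
            q = float(np.sum(w * (G - slope * g) ** 2))

        q = max(q, 0.0)
        if J > 1:
            q_p = float(stats.chi2.sf(q, J - 1))
        else:
            q, q_p = None, None
        se = se_fixed
        if model == "random" and J > 1:
            se = se_fixed * max(1.0, np.sqrt(q / (J - 1)))

        self.slope_ = slope
        self.se_ = float(se)
        self.ci_low_ = slope - Z95 * self.se_
        self.ci_high_ = slope + Z95 * self.se_
        self.p_value_ = _normal_p(slope / self.se_)
        self.q_statistic_ = q
        self.q_p_value_ = q_p
        self.n_snps_ = J
        self.effects_model_used_ = model
        self.method_ = "wald" if J == 1 else ("ivw_fixed" if model == "fixed" else "ivw_random")
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        return np.asarray(X, dtype=float).reshape(-1) * self.slope_

    def estimate(self) -> MREstimate:
        check_is_fitted(self, "slope_")
        return MREstimate(self.method_, self.slope_, self.se_, self.ci_low_,
                          self.ci_high_, self.p_value_, self.n_snps_,
                          self.q_statistic_, self.q_p_value_)


class EggerEstimator(RegressorMixin, BaseEstimator):
    """MR-Egger regression: weighted fit of outcome on exposure effects with
    an intercept, after flipping signs so all exposure effects are positive.

    The intercept estimates the average directional pleiotropy; the slope is
    the causal effect under the InSIDE assumption.
    """

    def __init__(self, effects_model: str = "auto"):
        self.effects_model = effects_model

    def fit(self, X, y, outcome_se=None, ld=None):
        g = np.asarray(X, dtype=float).reshape(-1)
        G = np.asarray(y, dtype=float).reshape(-1)
        if outcome_se is None:
            raise ValueError("outcome_se is required")
        Gs = np.asarray(outcome_se, dtype=float).reshape(-1)
        J = g.size
        if J < 3:
            raise MethodInapplicableError("MR-Egger requires at least 3 instruments")

        # orientation: Egger is not invariant to allele coding, so all
        # exposure effects are made positive (outcome flipped in step)
        flip = np.where(g < 0, -1.0, 1.0)
        g, G = g * flip, G * flip

        D = np.column_stack([np.ones(J), g])
        if ld is not None:
            rho = np.asarray(ld, dtype=float)
            rho = rho * np.outer(flip, flip)  # re-sign LD to the flipped coding
            omega_inv = np.linalg.inv(_omega(Gs, rho))
        else:
            omega_inv = np.diag(1.0 / Gs**2)
        xtwx = D.T @ omega_inv @ D
        cov = np.linalg.inv(xtwx)
        coef = cov @ (D.T @ omega_inv @ G)
        resid = G - D @ coef
        q = max(float(resid @ omega_inv @ resid), 0.0)

        model = self.effects_model
        if model == "auto":
            model = "fixed" if J <= 3 else "random"
        scale = 1.0
        if model == "random" and J > 2:
            scale = max(1.0, np.sqrt(q / (J - 2)))

        se = np.sqrt(np.diag(cov)) * scale
        self.intercept_, self.slope_ = float(coef[0]), float(coef[1])
        self.intercept_se_, self.se_ = float(se[0]), float(se[1])
        self.ci_low_ = self.slope_ - Z95 * self.se_
        self.ci_high_ = self.slope_ + Z95 * self.se_
        self.p_value_ = _normal_p(self.slope_ / self.se_)
        self.intercept_p_ = _normal_p(self.intercept_ / self.intercept_se_)
        self.q_statistic_ = q
        self.q_p_value_ = float(stats.chi2.sf(q, J - 2)) if J > 2 else None
        self.n_snps_ = J
        self.effects_model_used_ = model
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        g = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * np.abs(g)

    def estimate(self) -> MREstimate:
        check_is_fitted(self, "slope_")
        return MREstimate("egger", self.slope_, self.se_, self.ci_low_,
                          self.ci_high_, self.p_value_, self.n_snps_,
                          self.q_statistic_, self.q_p_value_,
                          self.intercept_, self.intercept_se_, self.intercept_p_)


class WeightedMedianEstimator(RegressorMixin, BaseEstimator):
    """Weighted median of Wald ratios with parametric-bootstrap se.

    Weights are proportional to gamma_j^2/se(Gamma_j)^2. The median is the
    linear interpolation of the sorted ratios at cumulative weight one half,
    using midpoint cumulative sums. The se is the standard deviation of the
    statistic over ``n_boot`` parametric resamples of (gamma_hat, Gamma_hat)
    from their stated normal errors.
    """

    def __init__(self, n_boot: int = 1000, seed: int | None = None):
        self.n_boot = n_boot
        self.seed = seed

    @staticmethod
    def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
        order = np.argsort(theta)
        theta, w = theta[order], w[order]
        w = w / w.sum()
        s = np.cumsum(w) - 0.5 * w  # midpoint cumulative weights
        return float(np.interp(0.5, s, theta))

    def fit(self, X, y, exposure_se=None, outcome_se=None):
        g = np.asarray(X, dtype=float).reshape(-1)
        G = np.asarray(y, dtype=float).reshape(-1)
        if exposure_se is None or outcome_se is None:
            raise ValueError("exposure_se and outcome_se are required")
        gs = np.asarray(exposure_se, dtype=float).reshape(-1)
        Gs = np.asarray(outcome_se, dtype=float).reshape(-1)
        J = g.size
        if J < 3:
            raise MethodInapplicableError("weighted median requires at least 3 instruments")
        if np.any(g == 0):
            raise DegenerateInstrumentError("zero exposure effect among instruments")

        theta = G / g
        w = g**2 / Gs**2
        slope = self._weighted_median(theta, w)

        rng = np.random.default_rng(self.seed)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            gb = rng.normal(g, gs)
            Gb = rng.normal(G, Gs)
            gb = np.where(gb == 0, np.finfo(float).tiny, gb)
            boots[b] = self._weighted_median(Gb / gb, gb**2 / Gs**2)
        se = float(np.std(boots, ddof=1))
        se = max(se, np.finfo(float).tiny)

        self.slope_ = slope
        self.se_ = se
        self.ci_low_ = slope - Z95 * se
        self.ci_high_ = slope + Z95 * se
        self.p_value_ = _normal_p(slope / se)
        self.n_snps_ = J
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        return np.asarray(X, dtype=float).reshape(-1) * self.slope_

    def estimate(self) -> MREstimate:
        check_is_fitted(self, "slope_")
        return MREstimate("weighted_median", self.slope_, self.se_, self.ci_low_,
                          self.ci_high_, self.p_value_, self.n_snps_)


# ---------------------------------------------------------------------------
# function layer over the estimator classes

def ivw(instruments: Sequence[HarmonizedInstrument],
        effects_model: str = "auto") -> MREstimate:
    """IVW estimate assuming independent instruments."""
    g, _, G, Gs = _unpack(instruments)
    return IVWEstimator(effects_model).fit(g, G, outcome_se=Gs).estimate()


def ivw_correlated(instruments: Sequence[HarmonizedInstrument], ld: LDMatrix | np.ndarray,
                   effects_model: str = "auto") -> MREstimate:
    """IVW by generalized weighted least squares under an LD weighting matrix."""
    g, _, G, Gs = _unpack(instruments)
    rho = ld.submatrix([i.variant_id for i in instruments]) if isinstance(ld, LDMatrix) else ld
    return IVWEstimator(effects_model).fit(g, G, outcome_se=Gs, ld=rho).estimate()


def weighted_median(instruments: Sequence[HarmonizedInstrument],
                    n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    g, gs, G, Gs = _unpack(instruments)
    est = WeightedMedianEstimator(n_boot=n_boot, seed=seed)
    return est.fit(g, G, exposure_se=gs, outcome_se=Gs).estimate()


def egger(instruments: Sequence[HarmonizedInstrument],
          ld: LDMatrix | np.ndarray | None = None,
          effects_model: str = "auto") -> MREstimate:
    g, _, G, Gs = _unpack(instruments)
    rho = None
    if ld is not None:
        rho = ld.submatrix([i.variant_id for i in instruments]) if isinstance(ld, LDMatrix) else ld
    return EggerEstimator(effects_model).fit(g, G, outcome_se=Gs, ld=rho).estimate()


def lowering_orientation(e: MREstimate) -> MREstimate:
    """Re-express an estimate per 1-SD *reduction* in the exposure.

    Negates the slope and swaps/negates the CI; p-values, Q and the Egger
    intercept test are unchanged. Applying twice restores the original.
    """
    if e.orientation == "lowering":
        return replace(e, slope=-e.slope, ci_low=-e.ci_high, ci_high=-e.ci_low,
                       orientation="raising")
    return replace(e, slope=-e.slope, ci_low=-e.ci_high, ci_high=-e.ci_low,
                   orientation="lowering")
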