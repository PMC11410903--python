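"""Mixture-model clustering of variant-level causal estimates (clustered MR).

Variant-level Wald ratios theta_j with standard errors sigma_j are modelled
as a finite Gaussian mixture with three kinds of components:

* K substantive clusters: theta_j ~ N(mu_k, sigma_j^2) — variants whose
  causal estimates agree up to their own sampling error, suggesting a shared
  mechanism;
* a null cluster: theta_j ~ N(0, sigma_j^2) — variants with no effect on the
  outcome;
* a junk cluster: theta_j ~ N(theta_bar, sigma_j^2 + psi^2), with theta_bar
  and psi^2 the unweighted mean and variance of all ratios, held fixed —
  a broad component absorbing dispersed outliers.

The null and junk components demand substantial evidence of similarity
before a substantive cluster forms, which suppresses spurious clusters.
Component means and mixing proportions are fitted by EM; the number of
substantive clusters is chosen by BIC over K = 0..k_max with multiple
seeded restarts. Clusters are reported only when at least ``min_size``
variants exceed the ``min_inclusion`` membership probability, and per-cluster
IVW / weighted-median / Egger estimates are recomputed on the members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .estimators import (MethodInapplicableError, MREstimate, RatioEstimate,
                         egger, ivw, weighted_median)
from .sumstats import HarmonizedInstrument

logger = logging.getLogger(__name__)

_LOG_2PI = np.log(2 * np.pi)


@dataclass
class ClusterSolution:
    """A fitted mixture over {substantive clusters..., null, junk}."""

    k_substantive: int
    means: np.ndarray  # length k_substantive
    proportions: np.ndarray  # length k_substantive + 2, order [clusters..., null, junk]
    junk_scale: float
    inclusion: np.ndarray  # (J, k_substantive + 2) membership probabilities
    variant_ids: list[str]
    bic: float
    loglik: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")
        if self.inclusion.size and np.max(np.abs(self.inclusion.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("per-variant inclusion probabilities must sum to 1")

    @property
    def null_index(self) -> int:
        return self.k_substantive

    @property
    def junk_index(self) -> int:
        return self.k_substantive + 1

    def assignments(self) -> np.ndarray:
        """Index of each variant's maximum-probability component."""
        return np.argmax(self.inclusion, axis=1)


@dataclass
class ReportedCluster:
    cluster_id: int
    member_variant_ids: list[str]
    mean: float
    estimates: dict[str, MREstimate | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.member_variant_ids) < 4:
            raise ValueError("a reported cluster needs at least four members")


class MRClustMixture(BaseEstimator):
    """EM-fitted Gaussian mixture over Wald ratios with null and junk components.

    Parameters
    ----------
    k_max : maximum number of substantive clusters tried (BIC selects).
    n_restarts : EM restarts per K; initial means drawn from random
        quantiles of the observed ratios.
    junk_multiplier : scales the fixed junk dispersion psi.
    tol, max_iter : EM convergence (log-likelihood gain) and iteration cap.
    random_state : seed for restart initialisation.
    """

    def __init__(self, k_max: int = 10, n_restarts: int = 20,
                 junk_multiplier: float = 1.0, tol: float = 1e-8,
                 max_iter: int = 500, random_state: int | None = None):
        self.k_max = k_max
        self.n_restarts = n_restarts
        self.junk_multiplier = junk_multiplier
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _log_normal(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
        return -0.5 * (_LOG_2PI + np.log(var) + (x - mean) ** 2 / var)

    def _em(self, theta, var_obs, mu0, fixed_logdens):
        """Run EM from initial means mu0; returns (mu, pi, resp, loglik, path).

        ``fixed_logdens`` holds the (J, 2) null and junk log densities, which
        do not change across iterations.
        """
        K = mu0.size
        J = theta.size
        mu = mu0.copy()
        pi = np.full(K + 2, 1.0 / (K + 2))
        prev = -np.inf
        path = []
        resp = None
        prec = 1.0 / var_obs
        half_const = -0.5 * (_LOG_2PI + np.log(var_obs))
        logdens = np.empty((J, K + 2))
        logdens[:, K:] = fixed_logdens
        theta_prec = theta * prec
        for _ in range(self.max_iter):
            if K:
                logdens[:, :K] = (half_const[:, None]
                                  - 0.5 * (theta[:, None] - mu[None, :]) ** 2
                                  * prec[:, None])
            weighted = logdens + np.log(pi)[None, :]
            # inline log-sum-exp with max shift (hot loop)
            m = weighted.max(axis=1)
            resp = np.exp(weighted - m[:, None])
            total = resp.sum(axis=1)
            loglik = float(np.sum(m + np.log(total)))
            path.append(loglik)
            resp /= total[:, None]
            if loglik - prev < self.tol and np.isfinite(prev):
                break
            prev = loglik
            pi = resp.mean(axis=0)
            pi = np.maximum(pi, 1e-300)
            pi = pi / pi.sum()
            if K:
                num = resp[:, :K].T @ theta_prec
                den = resp[:, :K].T @ prec
                keep = den > 0
                mu[keep] = num[keep] / den[keep]
        return mu, pi, resp, path[-1], path

    def fit(self, X, y=None):
        """Fit the mixture.

        Parameters
        ----------
        X : array-like, shape (J, 2) — columns (theta, theta_se); or a
            sequence of :class:`RatioEstimate`.
        """
        if len(X) and isinstance(X[0], RatioEstimate):
            ids = [r.variant_id for r in X]
            theta = np.array([r.theta for r in X], dtype=float)
            sigma = np.array([r.theta_se for r in X], dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            theta, sigma = arr[:, 0], arr[:, 1]
            ids = [f"v{i}" for i in range(len(theta))]
        J = theta.size
        if J < 5:
            raise MethodInapplicableError("mixture clustering requires at least 5 ratios")
        if np.any(sigma <= 0):
            raise ValueError("all ratio standard errors must be positive")

        var_obs = sigma**2
        theta_bar = float(np.mean(theta))
        # junk dispersion: the sample spread of the ratios, floored so the
        # junk component stays broader than the per-variant sampling noise
        psi2 = max(float(np.var(theta)), 4.0 * float(np.median(var_obs)))
        psi2 *= self.junk_multiplier**2

        fixed_logdens = np.column_stack([
            self._log_normal(theta, 0.0, var_obs),
            self._log_normal(theta, theta_bar, var_obs + psi2),
        ])

        ss = np.random.SeedSequence(self.random_state)
        best = None  # (bic, K_eff, loglik, mu, pi, resp, path, seed)
        for K in range(self.k_max + 1):
            restarts = self.n_restarts if K > 0 else 1
            children = ss.spawn(restarts)
            best_k = None
            for child in children:
                rng = np.random.default_rng(child)
                mu0 = (np.quantile(theta, rng.uniform(size=K))
                       if K else np.empty(0))
                mu, pi, resp, loglik, path = self._em(theta, var_obs, mu0,
                                                      fixed_logdens)
                if best_k is None or loglik > best_k[0]:
                    best_k = (loglik, mu, pi, resp, path)
            loglik, mu, pi, resp, path = best_k

            # drop substantive components the data abandoned, and merge
            # non-identifiable duplicates (EM symmetric splits onto one mean)
            merge_tol = 1e-3 * np.sqrt(psi2)
            while K and mu.size:
                alive = pi[:mu.size] > 1e-6
                order = np.argsort(mu)
                dup = None
                if alive.all() and mu.size > 1:
                    gaps = np.diff(mu[order])
                    close = np.flatnonzero(gaps < merge_tol)
                    if close.size:
                        dup = (order[close[0]], order[close[0] + 1])
                if alive.all() and dup is None:
                    break
                if dup is not None:
                    a, b = dup
                    w = pi[a] + pi[b]
                    merged = (pi[a] * mu[a] + pi[b] * mu[b]) / w
                    logger.info("merging duplicate components at %.4f/%.4f",
                                mu[a], mu[b])
                    rest = [i for i in range(mu.size) if i not in (a, b)]
                    mu = np.append(mu[rest], merged)
                    pi = np.concatenate([pi[rest], [w], pi[-2:]])
                else:
                    logger.info("removing %d empty substantive component(s)",
                                int((~alive).sum()))
                    rest = np.flatnonzero(alive)
                    mu = mu[rest]
                    pi = np.concatenate([pi[rest], pi[-2:]])
                pi = pi / pi.sum()
                mu, pi, resp, loglik, path = self._em(theta, var_obs, mu,
                                                      fixed_logdens)
            k_eff = mu.size
            n_params = k_eff + (k_eff + 2 - 1)  # means + free mixing weights
            bic = -2.0 * loglik + n_params * np.log(J)
            if best is None or bic < best[0] - 1e-12 or (
                    abs(bic - best[0]) <= 1e-12 and k_eff < best[1]):
                best = (bic, k_eff, loglik, mu, pi, resp, path)

        bic, k_eff, loglik, mu, pi, resp, path = best
        order = np.argsort(mu)
        mu = mu[order]
        col_order = np.concatenate([order, [k_eff, k_eff + 1]]).astype(int)
        pi = pi[col_order]
        resp = resp[:, col_order]

        self.k_substantive_ = int(k_eff)
        self.means_ = mu
        self.weights_ = pi
        self.responsibilities_ = resp
        self.loglik_ = loglik
        self.loglik_path_ = path
        self.bic_ = bic
        self.junk_scale_ = float(np.sqrt(psi2))
        self.junk_mean_ = theta_bar
        self.variant_ids_ = ids
        return self

    def predict_proba(self, X=None) -> np.ndarray:
        return self.responsibilities_

    def predict(self, X=None) -> np.ndarray:
        return np.argmax(self.responsibilities_, axis=1)

    def solution(self) -> ClusterSolution:
        return ClusterSolution(
            self.k_substantive_, self.means_, self.weights_, self.junk_scale_,
            self.responsibilities_, self.variant_ids_, self.bic_, self.loglik_,
            self.random_state)


def fit_mixture(ratios: Sequence[RatioEstimate], k_max: int = 10,
                n_restarts: int = 20, seed: int | None = None,
                junk_multiplier: float = 1.0) -> ClusterSolution:
    """Fit the clustered-MR mixture and return the BIC-best solution."""
    model = MRClustMixture(k_max=k_max, n_restarts=n_restarts,
                           junk_multiplier=junk_multiplier, random_state=seed)
    return model.fit(list(ratios)).solution()


def report_clusters(sol: ClusterSolution,
                    instruments: Sequence[HarmonizedInstrument] | None = None,
                    min_inclusion: float = 0.80, min_size: int = 4,
                    n_boot: int = 1000, seed: int | None = None,
                    ) -> list[ReportedCluster]:
    """Substantive clusters passing the inclusion-probability and size rules.

    A variant is a member when the cluster is its maximum-probability
    component and the probability strictly exceeds ``min_inclusion``.
    Clusters with fewer than ``min_size`` members are suppressed. When the
    harmonized instruments are supplied, per-cluster IVW, weighted-median
    and Egger estimates are recomputed on the members.
    """
    by_id = {i.variant_id: i for i in instruments} if instruments else {}
    assign = sol.assignments()
    out: list[ReportedCluster] = []
    for k in range(sol.k_substantive):
        probs = sol.inclusion[:, k]
        members = [sol.variant_ids[j] for j in range(len(sol.variant_ids))
                   if assign[j] == k and probs[j] > min_inclusion]
        if len(members) < min_size:
            if members:
                logger.info("cluster %d suppressed: %d qualifying member(s) < %d",
                            k, len(members), min_size)
            continue
        ests: dict[str, MREstimate | None] = {}
        member_insts = [by_id[v] for v in members if v in by_id]
        if len(member_insts) == len(members) and members:
            ests["ivw"] = ivw(member_insts)
            try:
                ests["weighted_median"] = weighted_median(member_insts,
                                                          n_boot=n_boot, seed=seed)
                ests["egger"] = egger(member_insts)
            except MethodInapplicableError:
                ests["weighted_median"] = ests["egger"] = None
        out.append(ReportedCluster(k, members, float(sol.means[k]), ests))
    return out
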