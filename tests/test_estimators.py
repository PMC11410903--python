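"""Wald ratios, IVW (independent and correlated), weighted median, Egger."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit.estimators import (DegenerateInstrumentError, IVWEstimator,
                              MethodInapplicableError, egger, ivw,
                              ivw_correlated, lowering_orientation,
                              wald_ratio, weighted_median)
from mrkit.simulate import ar1_correlation
from mrkit.sumstats import HarmonizedInstrument
from tests.conftest import make_instruments


def _random_instruments(rng, n, slope=0.5, se_lo=0.02, se_hi=0.2):
    gamma = rng.uniform(0.05, 0.5, size=n) * rng.choice([-1, 1], size=n)
    Gs = rng.uniform(se_lo, se_hi, size=n)
    Gamma = slope * gamma + rng.normal(0, Gs)
    return make_instruments(gamma, Gamma, Gamma_se=Gs)


class TestWaldRatio:
    def test_direct_formula(self):
        (inst,) = make_instruments([0.4], [0.2], Gamma_se=[0.05])
        r = wald_ratio(inst)
        assert r.theta == pytest.approx(0.5)
        assert r.theta_se == pytest.approx(0.125)

    def test_unit_exposure_is_identity(self):
        (inst,) = make_instruments([1.0], [0.3], Gamma_se=[0.07])
        r = wald_ratio(inst)
        assert r.theta == pytest.approx(0.3)
        assert r.theta_se == pytest.approx(0.07)

    def test_allele_flip_symmetry(self):
        (a,) = make_instruments([0.4], [0.2])
        (b,) = make_instruments([-0.4], [-0.2])
        assert wald_ratio(a).theta == pytest.approx(wald_ratio(b).theta)

    def test_zero_exposure_effect_is_degenerate(self):
        (inst,) = make_instruments([0.0], [0.2])
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(inst)


class TestIVW:
    def test_single_instrument_reduces_to_wald_ratio(self):
        (inst,) = make_instruments([0.4], [0.2], Gamma_se=[0.05])
        e = ivw([inst])
        r = wald_ratio(inst)
        assert e.slope == pytest.approx(r.theta)
        assert e.se == pytest.approx(r.theta_se)
        assert e.method == "wald"

    def test_homogeneous_instruments(self):
        insts = make_instruments([0.2, 0.4], [0.1, 0.2], Gamma_se=[0.05, 0.05])
        e = ivw(insts, effects_model="random")
        assert e.slope == pytest.approx(0.5)
        assert e.q_statistic == pytest.approx(0.0, abs=1e-12)
        # random-effects inflation floored at 1: se equals the fixed se
        assert e.se == pytest.approx(ivw(insts, effects_model="fixed").se)

    def test_matches_weighted_least_squares_oracle(self):
        """Slope and fixed se equal an explicit normal-equations solve."""
        rng = np.random.default_rng(123)
        for _ in range(20):
            insts = _random_instruments(rng, rng.integers(3, 12))
            g = np.array([i.exposure_beta for i in insts])
            G = np.array([i.outcome_beta for i in insts])
            Gs = np.array([i.outcome_se for i in insts])
            # oracle: WLS through the origin via lstsq on rescaled data
            slope_or = np.linalg.lstsq((g / Gs)[:, None], G / Gs, rcond=None)[0][0]
            se_or = 1.0 / np.linalg.norm(g / Gs)
            e = ivw(insts, effects_model="fixed")
            assert e.slope == pytest.approx(slope_or, rel=1e-10)
            assert e.se == pytest.approx(se_or, rel=1e-10)

    def test_auto_rule_switches_at_four_instruments(self):
        rng = np.random.default_rng(5)
        i3 = _random_instruments(rng, 3)
        i4 = _random_instruments(rng, 4)
        assert ivw(i3).method == "ivw_fixed"
        assert ivw(i4).method == "ivw_random"

    def test_random_se_never_below_fixed(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            insts = _random_instruments(rng, 8, slope=rng.uniform(-1, 1))
            assert ivw(insts, "random").se >= ivw(insts, "fixed").se - 1e-15


class TestIVWCorrelated:
    def test_identity_ld_equals_independent_ivw(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            insts = _random_instruments(rng, rng.integers(2, 10))
            e0 = ivw(insts, "fixed")
            e1 = ivw_correlated(insts, np.eye(len(insts)), "fixed")
            assert e1.slope == pytest.approx(e0.slope, abs=1e-10)
            assert e1.se == pytest.approx(e0.se, rel=1e-6)
            assert e1.q_statistic == pytest.approx(e0.q_statistic, abs=1e-8)

    def test_duplicate_instrument_limit(self):
        """Two near-perfectly correlated copies collapse to one Wald ratio;
        the se is not deflated below the single-instrument se."""
        (single,) = make_instruments([0.4], [0.2], Gamma_se=[0.05])
        dup = make_instruments([0.4, 0.4], [0.2, 0.2], Gamma_se=[0.05, 0.05])
        eps = 1e-6
        rho = np.array([[1.0, 1.0 - eps], [1.0 - eps, 1.0]])
        e = ivw_correlated(dup, rho, "fixed")
        w = wald_ratio(single)
        assert e.slope == pytest.approx(w.theta, rel=1e-6)
        assert e.se >= w.theta_se * (1 - 1e-3)

    def test_matches_generic_gls_oracle(self):
        """AR(1) correlation: compare against an explicit GLS solve."""
        rng = np.random.default_rng(7)
        insts = _random_instruments(rng, 5)
        g = np.array([i.exposure_beta for i in insts])
        G = np.array([i.outcome_beta for i in insts])
        Gs = np.array([i.outcome_se for i in insts])
        rho = ar1_correlation(5, 0.5)
        omega = np.outer(Gs, Gs) * rho
        # oracle: whitened least squares via Cholesky
        L = np.linalg.cholesky(omega)
        Xw = np.linalg.solve(L, g[:, None])
        yw = np.linalg.solve(L, G)
        slope_or, res, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        se_or = float(np.sqrt(np.linalg.inv(Xw.T @ Xw)[0, 0]))
        e = ivw_correlated(insts, rho, "fixed")
        assert e.slope == pytest.approx(float(slope_or[0]), rel=1e-6)
        assert e.se == pytest.approx(se_or, rel=1e-6)

    def test_singular_ld_raises_named_eigenvalue_error(self):
        dup = make_instruments([0.4, 0.4], [0.2, 0.2])
        # min eigenvalue well below zero, beyond what the ridge can condition
        rho_bad = np.array([[1.0, 1.01], [1.01, 1.0]])
        with pytest.raises(np.linalg.LinAlgError, match="eigenvalue"):
            ivw_correlated(dup, rho_bad)


class TestWeightedMedian:
    def test_equal_weights_symmetric_median(self):
        insts = make_instruments([0.1, 0.1, 0.1], [0.1, 0.2, 0.3],
                                 Gamma_se=[0.05, 0.05, 0.05])
        e = weighted_median(insts, n_boot=50, seed=0)
        assert e.slope == pytest.approx(2.0)

    def test_degenerate_identical_ratios(self):
        insts = make_instruments([0.2, 0.3, 0.4], [0.1, 0.15, 0.2],
                                 gamma_se=[1e-6] * 3, Gamma_se=[1e-6] * 3)
        e = weighted_median(insts, n_boot=100, seed=1)
        assert e.slope == pytest.approx(0.5, abs=1e-4)
        assert e.se < 1e-4

    def test_requires_three_instruments(self):
        with pytest.raises(MethodInapplicableError):
            weighted_median(make_instruments([0.1, 0.2], [0.05, 0.1]), seed=0)

    def test_robust_to_minority_outliers(self):
        """10/50 pleiotropic instruments at slope 5: the median stays near the
        majority slope 0.5 while IVW is pulled upward."""
        rng = np.random.default_rng(99)
        n, n_out = 50, 10
        gamma = rng.uniform(0.1, 0.5, size=n)
        Gs = np.full(n, 0.02)
        slopes = np.array([5.0] * n_out + [0.5] * (n - n_out))
        Gamma = slopes * gamma + rng.normal(0, Gs)
        insts = make_instruments(gamma, Gamma, gamma_se=np.full(n, 0.001), Gamma_se=Gs)
        wm = weighted_median(insts, n_boot=200, seed=3)
        iv = ivw(insts)
        assert wm.ci_low <= 0.5 <= wm.ci_high
        assert iv.slope > wm.slope + 0.2


class TestEgger:
    def test_constant_pleiotropy_moves_intercept_not_slope(self):
        rng = np.random.default_rng(31)
        gamma = rng.uniform(0.1, 0.6, size=8)  # already positive: orientation no-op
        Gs = rng.uniform(0.02, 0.08, size=8)
        Gamma = 0.4 * gamma + rng.normal(0, Gs)
        base = egger(make_instruments(gamma, Gamma, Gamma_se=Gs))
        c = 0.123
        shifted = egger(make_instruments(gamma, Gamma + c, Gamma_se=Gs))
        assert shifted.slope == pytest.approx(base.slope, rel=1e-9)
        assert shifted.egger_intercept == pytest.approx(base.egger_intercept + c, rel=1e-9)

    def test_identity_ld_equals_weighted_fit(self):
        rng = np.random.default_rng(13)
        insts = _random_instruments(rng, 6)
        e0 = egger(insts)
        e1 = egger(insts, ld=np.eye(6))
        assert e1.slope == pytest.approx(e0.slope, abs=1e-10)
        assert e1.egger_intercept == pytest.approx(e0.egger_intercept, abs=1e-10)
        assert e1.se == pytest.approx(e0.se, rel=1e-6)

    def test_orientation_invariance(self):
        """Flipping the allele coding of any instrument leaves Egger unchanged."""
        rng = np.random.default_rng(8)
        insts = _random_instruments(rng, 6)
        flipped = [HarmonizedInstrument(i.variant_id, -i.exposure_beta, i.exposure_se,
                                        -i.outcome_beta, i.outcome_se,
                                        i.other_allele, i.effect_allele)
                   for i in insts]
        e0, e1 = egger(insts), egger(flipped)
        assert e1.slope == pytest.approx(e0.slope)
        assert e1.egger_intercept == pytest.approx(e0.egger_intercept)

    def test_requires_three_instruments(self):
        with pytest.raises(MethodInapplicableError):
            egger(make_instruments([0.1, 0.2], [0.05, 0.1]))


class TestOrientationAndInvariants:
    def test_lowering_orientation_flips_slope_and_ci(self):
        rng = np.random.default_rng(2)
        e = ivw(_random_instruments(rng, 5, slope=-0.3))
        low = lowering_orientation(e)
        assert low.orientation == "lowering"
        assert low.slope == -e.slope
        assert (low.ci_low, low.ci_high) == (-e.ci_high, -e.ci_low)
        assert low.p_value == e.p_value
        assert low.q_statistic == e.q_statistic  # Q invariant to orientation

    def test_lowering_is_involution(self):
        rng = np.random.default_rng(4)
        e = ivw(_random_instruments(rng, 5))
        assert lowering_orientation(lowering_orientation(e)) == e

    def test_zero_slope_fixed_point(self):
        insts = make_instruments([0.2, 0.3], [0.0, 0.0])
        e = ivw(insts)
        assert lowering_orientation(e).slope == 0.0

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_estimators_equivariant_to_relabeling(self, seed):
        """Permuting instruments leaves every estimate unchanged."""
        rng = np.random.default_rng(seed)
        insts = _random_instruments(rng, 6)
        perm = list(rng.permutation(6))
        shuffled = [insts[i] for i in perm]
        assert ivw(shuffled).slope == pytest.approx(ivw(insts).slope)
        assert egger(shuffled).slope == pytest.approx(egger(insts).slope)
        assert (weighted_median(shuffled, n_boot=10, seed=0).slope
                == pytest.approx(weighted_median(insts, n_boot=10, seed=0).slope))

    def test_sklearn_protocol(self):
        est = IVWEstimator(effects_model="fixed")
        assert est.get_params() == {"effects_model": "fixed"}
        est.set_params(effects_model="random")
        g = np.array([0.2, 0.3, 0.4, 0.5])
        est.fit(g, 0.5 * g, outcome_se=np.full(4, 0.05))
        np.testing.assert_allclose(est.predict(g), 0.5 * g)
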