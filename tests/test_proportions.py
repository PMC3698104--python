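"""Proportion-below-threshold estimators and their uncertainty."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import hmbmtc as h
from hmbmtc.proportions import (
    DistributionAssumption,
    Family,
    Provenance,
    arm_to_observation,
    prop_from_counts,
    prop_from_mean_sd,
    prop_from_median_iqr,
    prop_from_median_range,
    to_effective_counts,
)

NORMAL80 = DistributionAssumption(Family.NORMAL, 80.0)
LOGN80 = DistributionAssumption(Family.LOGNORMAL, 80.0)


class TestCounts:
    def test_interior_counts_closed_form(self):
        o = prop_from_counts(5, 10)
        assert o.p_hat == 0.5
        assert o.se == pytest.approx(math.sqrt(0.025))
        assert (o.y_eff, o.n_eff) == (5.0, 10.0)

    def test_boundary_continuity_correction(self):
        o = prop_from_counts(0, 20)
        assert o.p_hat == pytest.approx(0.5 / 21)
        o = prop_from_counts(20, 20)
        assert o.p_hat == pytest.approx(20.5 / 21)

    def test_se_matches_bootstrap(self, rng):
        o = prop_from_counts(7, 10)
        boot = rng.binomial(10, 0.7, 10**6) / 10
        assert o.se == pytest.approx(boot.std(), rel=0.02)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            prop_from_counts(0, 0)


class TestMeanSd:
    def test_symmetry_at_threshold_normal(self):
        o = prop_from_mean_sd(80.0, 40.0, 30, NORMAL80)
        assert o.p_hat == pytest.approx(0.5, abs=1e-12)

    def test_normal_matches_phi(self):
        o = prop_from_mean_sd(170.0, 60.0, 30, NORMAL80)
        assert o.p_hat == pytest.approx(stats.norm.cdf(-1.5), rel=1e-9)

    @pytest.mark.parametrize("family", [Family.NORMAL, Family.LOGNORMAL])
    def test_monte_carlo_oracle(self, family, rng):
        assume = DistributionAssumption(family, 80.0)
        o = prop_from_mean_sd(170.0, 60.0, 30, assume)
        N = 10**6
        if family is Family.NORMAL:
            draws = rng.normal(170.0, 60.0, N)
        else:
            s2 = math.log1p((60.0 / 170.0) ** 2)
            draws = rng.lognormal(math.log(170.0) - s2 / 2, math.sqrt(s2), N)
        emp = (draws < 80.0).mean()
        mcse = math.sqrt(o.p_hat * (1 - o.p_hat) / N)
        assert abs(o.p_hat - emp) < 3 * mcse

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            prop_from_mean_sd(100.0, 0.0, 30, NORMAL80)
        with pytest.raises(ValueError):
            prop_from_mean_sd(-5.0, 10.0, 30, LOGN80)


class TestMedianRange:
    def test_symmetric_at_threshold(self):
        o = prop_from_median_range(80.0, 30.0, 130.0, 25, NORMAL80)
        assert o.p_hat == pytest.approx(0.5, abs=1e-12)

    def test_consistency_with_simulated_normal_summaries(self, rng):
        # average (median, min, max) over many samples of size 25, then the
        # estimate should land near the generating below-threshold probability
        mu, sig, n = 150.0, 90.0, 25
        samp = rng.normal(mu, sig, (10**5, n))
        med = float(np.median(samp, axis=1).mean())
        mn = float(samp.min(axis=1).mean())
        mx = float(samp.max(axis=1).mean())
        o = prop_from_median_range(med, mn, mx, n, NORMAL80)
        true_p = stats.norm.cdf((80.0 - mu) / sig)
        assert abs(o.p_hat - true_p) < 0.02

    def test_large_n_matches_fixed_divisor_closed_form(self):
        med, mn, mx = 150.0, 40.0, 400.0
        o = prop_from_median_range(med, mn, mx, 10**6, NORMAL80)
        mean = (mn + 2 * med + mx) / 4.0
        sd = (mx - mn) / 6.0
        assert o.p_hat == pytest.approx(stats.norm.cdf((80.0 - mean) / sd), rel=1e-9)

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ValueError):
            prop_from_median_range(5.0, 5.0, 5.0, 10, NORMAL80)


class TestMedianIqr:
    def test_symmetric_quartiles_give_half(self):
        assume = DistributionAssumption(Family.NORMAL, 100.0)
        o = prop_from_median_iqr(100.0, 60.0, 140.0, 40, assume)
        assert o.p_hat == pytest.approx(0.5, abs=1e-12)

    def test_lognormal_simulation_oracle(self, rng):
        # quartile matching on the log scale is exact for lognormal data
        mu_l, s_l = math.log(130.0), 0.5
        q1, med, q3 = [float(math.exp(mu_l + z * s_l)) for z in
                       (stats.norm.ppf(0.25), 0.0, stats.norm.ppf(0.75))]
        assume = DistributionAssumption(Family.LOGNORMAL, 100.0)
        o = prop_from_median_iqr(med, q1, q3, 40, assume)
        N = 10**5
        draws = rng.lognormal(mu_l, s_l, N)
        emp = (draws < 100.0).mean()
        mcse = math.sqrt(o.p_hat * (1 - o.p_hat) / N)
        assert abs(o.p_hat - emp) < 3 * mcse

    def test_widening_iqr_below_threshold_pulls_toward_half(self):
        assume = DistributionAssumption(Family.NORMAL, 100.0)
        narrow = prop_from_median_iqr(150.0, 130.0, 170.0, 40, assume)
        wide = prop_from_median_iqr(150.0, 110.0, 190.0, 40, assume)
        assert narrow.p_hat < wide.p_hat < 0.5

    def test_degenerate_quartiles_rejected(self):
        with pytest.raises(ValueError):
            prop_from_median_iqr(7.0, 7.0, 7.0, 10, NORMAL80)


class TestEffectiveCounts:
    def test_direct_counts_pass_through(self):
        o = prop_from_counts(5, 10)
        assert to_effective_counts(o) == (5.0, 10.0)

    def test_inverts_binomial_se(self):
        # choose var(mean) so the delta-method SE is exactly sqrt(0.025)
        var_mean = 0.025 * (40.0 / stats.norm.pdf(0.0)) ** 2
        o = prop_from_mean_sd(80.0, 40.0, 50, NORMAL80,
                              _var_mean=var_mean, _var_sd=0.0)
        # se = 0.1581 at p = 0.5 corresponds to n_eff = 10
        assert o.se == pytest.approx(math.sqrt(0.025), rel=1e-6)
        assert o.n_eff == pytest.approx(10.0, rel=1e-6)
        assert o.y_eff == pytest.approx(5.0, rel=1e-6)

    def test_halving_se_quadruples_n_eff(self):
        p = 0.4
        n1 = p * (1 - p) / 0.1**2
        n2 = p * (1 - p) / 0.05**2
        assert n2 == pytest.approx(4 * n1)

    def test_roundtrip_counts(self):
        for y, n in [(3, 12), (1, 9), (40, 55)]:
            o = prop_from_counts(y, n)
            y2, n2 = to_effective_counts(o)
            assert y2 == pytest.approx(y, abs=0.5)
            assert n2 == pytest.approx(n, abs=1.0)


@st.composite
def _mean_sd_params(draw):
    family = draw(st.sampled_from([Family.NORMAL, Family.LOGNORMAL]))
    mean = draw(st.floats(40.0, 400.0))
    sd = draw(st.floats(5.0, 150.0))
    n = draw(st.integers(5, 200))
    return family, mean, sd, n


class TestEstimatorProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(_mean_sd_params())
    def test_bounds_and_positive_se(self, params):
        family, mean, sd, n = params
        o = prop_from_mean_sd(mean, sd, n, DistributionAssumption(family, 80.0))
        assert 0.0 < o.p_hat < 1.0
        assert o.se > 0.0
        assert o.n_eff > 0.0
        assert o.y_eff == pytest.approx(o.p_hat * o.n_eff)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(_mean_sd_params(), st.floats(1.0, 40.0))
    def test_p_hat_decreasing_in_mean(self, params, shift):
        family, mean, sd, n = params
        assume = DistributionAssumption(family, 80.0)
        lo = prop_from_mean_sd(mean, sd, n, assume)
        hi = prop_from_mean_sd(mean + shift, sd, n, assume)
        assert hi.p_hat <= lo.p_hat

    def test_pbac_and_mbl_paths_identical_up_to_threshold(self):
        # same summary relative to threshold -> identical estimate
        mbl = prop_from_mean_sd(170.0, 60.0, 30, DistributionAssumption(Family.NORMAL, 80.0))
        pbac = prop_from_mean_sd(170.0 * 100 / 80, 60.0 * 100 / 80, 30,
                                 DistributionAssumption(Family.NORMAL, 100.0))
        assert pbac.p_hat == pytest.approx(mbl.p_hat, rel=1e-9)


class TestArmConversion:
    def test_provenance_recorded_per_form(self, small_synthetic):
        net, _ = small_synthetic
        obs = h.estimate_proportions(net)
        assert len(obs) == len(net)
        forms = {o.provenance for o in obs}
        assert Provenance.DIRECT_COUNTS in forms

    def test_counts_arm_keeps_exact_counts(self):
        arm = h.ArmOutcome("S", h.TreatmentClass.TXA, 3, h.OutcomeForm.COUNTS, n=40, y=22)
        o = arm_to_observation(arm, h.ProportionConfig())
        assert (o.y_eff, o.n_eff) == (22.0, 40.0)
        assert o.provenance is Provenance.DIRECT_COUNTS
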