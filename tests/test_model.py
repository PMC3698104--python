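"""Model density: likelihood, priors, standardization, pooling, symmetry."""

import math

import numpy as np
import pytest
from scipy import special, stats

import hmbmtc as h
from hmbmtc.model import (
    ALPHA1_BOUND,
    PRIOR_VAR_ALPHA0,
    PRIOR_VAR_DELTA,
    PRIOR_VAR_GAMMA,
    SIGMA_ETA_GAMMA_RATE,
    SIGMA_ETA_GAMMA_SHAPE,
    TAU_UPPER,
    ModelParameters,
    MTCModel,
    pool_same_class_arms,
    standardize_baselines,
)
from hmbmtc.proportions import prop_from_counts


def _toy_model(identifiability="faithful"):
    obs = [
        prop_from_counts(5, 10, study_id="S1", treatment=h.TreatmentClass.COC, time_months=3),
        prop_from_counts(8, 12, study_id="S1", treatment=h.TreatmentClass.LNG_IUS, time_months=3),
        prop_from_counts(3, 15, study_id="S2", treatment=h.TreatmentClass.COC, time_months=6,
                         baseline_mean=150.0),
        prop_from_counts(9, 15, study_id="S2", treatment=h.TreatmentClass.LNG_IUS, time_months=6,
                         baseline_mean=190.0),
    ]
    return MTCModel(obs, identifiability=identifiability)


def _zero_params(m, tau=1.0, sigma_eta=1.0):
    return ModelParameters(
        alpha0=0.0, alpha1=0.0,
        eta=np.zeros(m.n_studies), theta=np.zeros(m.n_arms),
        gamma=np.zeros(m.n_gamma), delta=np.zeros(m.n_classes),
        tau=np.full(m.n_classes, tau), sigma_eta=sigma_eta,
        x_missing=np.zeros(m.n_missing),
    )


class TestStandardization:
    def test_value_at_center_maps_to_zero(self):
        cov = standardize_baselines([100.0, 200.0, 300.0])
        assert cov.standardize(200.0) == 0.0

    def test_center_is_mean_of_nonmissing(self):
        raw = [90.3, 300.0, 120.0, 140.0, 150.0, 160.0, 170.0, 180.0, 190.0, 196.1, None, None]
        cov = standardize_baselines(raw)
        assert cov.center == pytest.approx(169.64)
        assert cov.missing_mask.sum() == 2

    def test_observed_entries_have_mean_zero(self, table1_net):
        m = MTCModel.from_network(table1_net)
        obs_vals = m.covariate.values[~m.covariate.missing_mask]
        assert obs_vals.mean() == pytest.approx(0.0, abs=1e-12)
        assert np.isfinite(obs_vals).all()
        assert m.covariate.center == pytest.approx(169.64)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            standardize_baselines([None, 150.0])
        with pytest.raises(ValueError):
            standardize_baselines([150.0, 150.0, 150.0])


class TestLinearPredictor:
    def test_all_zero_gives_logit_zero(self):
        m = _toy_model()
        p = _zero_params(m)
        lp = m.linear_predictor(p, "S1", h.TreatmentClass.COC, 3)
        assert lp == 0.0
        assert special.expit(lp) == 0.5

    def test_additivity(self):
        m = _toy_model()
        p = _zero_params(m)
        p.alpha0 = 1.0
        p.eta[0] = -0.5
        arm = m.arm_index[("S1", h.TreatmentClass.COC)]
        g = m.gamma_index[(h.TreatmentClass.COC, 3)]
        p.theta[arm] = 0.25
        p.gamma[g] = 0.25
        assert m.linear_predictor(p, "S1", h.TreatmentClass.COC, 3) == pytest.approx(1.0)

    def test_shared_study_effects_across_times(self):
        m = _toy_model()
        rng = np.random.default_rng(0)
        p = _zero_params(m)
        p.alpha0 = rng.normal()
        p.eta = rng.normal(size=m.n_studies)
        p.theta = rng.normal(size=m.n_arms)
        p.gamma = rng.normal(size=m.n_gamma)
        # same (study, class) at two times differs only through gamma
        lp3 = m.linear_predictor(p, "S2", h.TreatmentClass.COC, 6)
        g6 = m.gamma_index[(h.TreatmentClass.COC, 6)]
        g3 = m.gamma_index[(h.TreatmentClass.COC, 3)]
        lp_other = lp3 - p.gamma[g6] + p.gamma[g3]
        arm = m.arm_index[("S2", h.TreatmentClass.COC)]
        expected = p.alpha0 + p.eta[1] + p.theta[arm] + p.gamma[g3]
        assert lp_other == pytest.approx(expected)

    def test_unindexed_combination_raises(self):
        m = _toy_model()
        with pytest.raises(KeyError):
            m.linear_predictor(_zero_params(m), "S1", h.TreatmentClass.TXA, 3)


class TestLikelihood:
    def test_single_obs_closed_form(self):
        obs = [prop_from_counts(5, 10, study_id="S", treatment=h.TreatmentClass.COC, time_months=3)]
        m = MTCModel(obs)
        ll = m.log_likelihood(_zero_params(m))
        assert ll == pytest.approx(math.log(math.comb(10, 5)) + 10 * math.log(0.5), abs=1e-12)

    def test_empty_data_zero(self):
        m = _toy_model()
        empty = MTCModel([], design={
            "studies": m.study_ids,
            "classes": [c.value for c in m.classes],
            "arms": [[s, c.value] for s, c in m.arm_labels],
            "gammas": [[c.value, t] for c, t in m.gamma_labels],
        })
        assert empty.log_likelihood(_zero_params(empty)) == 0.0

    def test_matches_independent_binomial_sum(self):
        m = _toy_model()
        rng = np.random.default_rng(3)
        p = _zero_params(m)
        p.alpha0 = rng.normal()
        p.eta = rng.normal(size=m.n_studies)
        p.theta = rng.normal(size=m.n_arms)
        p.gamma = rng.normal(size=m.n_gamma)
        # independent reimplementation straight from the binomial pmf
        expected = 0.0
        for o in m.observations:
            lp = m.linear_predictor(p, o.study_id, o.treatment, o.time_months)
            pr = 1.0 / (1.0 + math.exp(-lp))
            expected += float(stats.binom.logpmf(round(o.y_eff), round(o.n_eff), pr))
        assert m.log_likelihood(p) == pytest.approx(expected, abs=1e-10)


class TestPrior:
    def test_alpha1_outside_support_is_minus_inf(self):
        m = _toy_model()
        p = _zero_params(m)
        p.alpha1 = 6.0
        assert m.log_prior(p) == -math.inf

    def test_nonpositive_tau_is_minus_inf(self):
        m = _toy_model()
        p = _zero_params(m)
        p.tau[0] = 0.0
        assert m.log_prior(p) == -math.inf

    def test_term_by_term_oracle(self):
        m = _toy_model()
        rng = np.random.default_rng(11)
        p = _zero_params(m, tau=1.7, sigma_eta=0.8)
        p.alpha0 = 0.4
        p.alpha1 = -0.9
        p.eta = rng.normal(size=m.n_studies)
        p.theta = rng.normal(size=m.n_arms)
        p.gamma = rng.normal(size=m.n_gamma)
        p.delta = rng.normal(size=m.n_classes)
        p.x_missing = rng.normal(size=m.n_missing)

        expected = stats.norm.logpdf(p.alpha0, 0, math.sqrt(PRIOR_VAR_ALPHA0))
        expected += stats.norm.logpdf(p.delta, 0, math.sqrt(PRIOR_VAR_DELTA)).sum()
        expected += stats.norm.logpdf(p.gamma, 0, math.sqrt(PRIOR_VAR_GAMMA)).sum()
        expected += stats.uniform.logpdf(p.alpha1, -ALPHA1_BOUND, 2 * ALPHA1_BOUND)
        expected += stats.uniform.logpdf(p.tau, 0, TAU_UPPER).sum()
        expected += stats.gamma.logpdf(p.sigma_eta**-2, SIGMA_ETA_GAMMA_SHAPE,
                                       scale=1 / SIGMA_ETA_GAMMA_RATE)
        expected += stats.norm.logpdf(p.eta, 0, p.sigma_eta).sum()
        x = m.covariate_values(p)
        mu = p.delta[m.arm_class] + p.alpha1 * x
        expected += stats.norm.logpdf(p.theta, mu, p.tau[m.arm_class]).sum()
        expected += stats.norm.logpdf(p.x_missing, 0, 1).sum()
        assert m.log_prior(p) == pytest.approx(expected, abs=1e-10)

    def test_gaussian_kernel_in_eta(self):
        m = _toy_model()
        p = _zero_params(m)
        base = m.log_prior(p)
        p.eta[0] = 1.5
        assert m.log_prior(p) - base == pytest.approx(-1.5**2 / 2, abs=1e-10)


class TestSymmetryAndSupport:
    def test_translation_ridge_invariance(self):
        # (alpha0+c, theta-c, delta-c) leaves likelihood and theta-prior
        # kernel unchanged to machine precision
        m = _toy_model()
        rng = np.random.default_rng(5)
        p = _zero_params(m)
        p.alpha0 = rng.normal()
        p.eta = rng.normal(size=m.n_studies)
        p.theta = rng.normal(size=m.n_arms)
        p.gamma = rng.normal(size=m.n_gamma)
        p.delta = rng.normal(size=m.n_classes)
        c = 3.7
        q = p.copy()
        q.alpha0 += c
        q.theta = q.theta - c
        q.delta = q.delta - c
        assert m.log_likelihood(q) == pytest.approx(m.log_likelihood(p), abs=1e-10)
        # prior differs only through the vague alpha0/delta margins
        x = m.covariate_values(p)
        for params in (p, q):
            mu = params.delta[m.arm_class] + params.alpha1 * x
            kern = float(np.sum(-0.5 * (params.theta - mu) ** 2))
            if params is p:
                ref = kern
        assert kern == pytest.approx(ref, abs=1e-10)

    def test_covariate_irrelevant_when_alpha1_zero(self):
        m = _toy_model()
        p = _zero_params(m)
        base_lik = m.log_likelihood(p)
        base_pri = m.log_prior(p)
        p.x_missing = p.x_missing + 1.3
        assert m.log_likelihood(p) == base_lik
        # only the standard-normal imputation margin moves
        delta_pri = m.log_prior(p) - base_pri
        assert delta_pri == pytest.approx(-(1.3**2) / 2 * m.n_missing, abs=1e-10)

    def test_posterior_finite_inside_support(self):
        m = _toy_model()
        p = _zero_params(m)
        assert math.isfinite(m.log_posterior(p))
        p.sigma_eta = -1.0
        assert m.log_posterior(p) == -math.inf


class TestPooling:
    def _arm(self, y, n, cls=h.TreatmentClass.ABLATION, sid="S", t=6):
        return prop_from_counts(y, n, study_id=sid, treatment=cls, time_months=t)

    def test_same_class_arms_merge_counts(self):
        pooled = pool_same_class_arms([self._arm(3, 10), self._arm(4, 10)])
        assert len(pooled) == 1
        assert (pooled[0].y_eff, pooled[0].n_eff) == (7.0, 20.0)
        assert pooled[0].provenance.value == "POOLED"

    def test_different_classes_untouched(self):
        obs = [self._arm(3, 10), self._arm(4, 10, cls=h.TreatmentClass.LNG_IUS)]
        assert pool_same_class_arms(obs) == obs

    def test_pooled_p_between_constituents(self):
        for y1 in range(0, 11):
            for y2 in range(0, 11):
                a, b = self._arm(y1, 10), self._arm(y2, 10)
                pooled = pool_same_class_arms([a, b])[0]
                # exact weighted-mean property on the effective proportions
                lo, hi = sorted([a.y_eff / a.n_eff, b.y_eff / b.n_eff])
                assert lo - 1e-9 <= pooled.y_eff / pooled.n_eff <= hi + 1e-9
                if 0 < y1 < 10 and 0 < y2 < 10:
                    lo, hi = sorted([a.p_hat, b.p_hat])
                    assert lo - 1e-9 <= pooled.p_hat <= hi + 1e-9

    def test_corner_mode_pins_reference_and_earliest_gamma(self):
        m = _toy_model(identifiability="corner")
        # reference class absent here -> all deltas free; earliest gammas pinned
        assert m.gamma_free.sum() == m.n_gamma - m.n_classes


class TestSerialization:
    def test_json_round_trip_design(self):
        import json

        m = _toy_model()
        spec = json.loads(m.to_json())
        m2 = MTCModel(m.observations, design=spec)
        assert m2.gamma_labels == m.gamma_labels
        assert m2.arm_labels == m.arm_labels
        p = _zero_params(m)
        assert m2.log_likelihood(p) == m.log_likelihood(p)
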