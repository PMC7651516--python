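import numpy as np
import pytest
from scipy import stats

import foragerl as frl
from foragerl.models import (MODEL_SPECS, SessionArrays, choice_prob,
                             decision_rhos, modulated_rate, nll_and_grad,
                             nll_choices, rho_step, rho_trace, transform_rate)
from oracles import make_session, nll_brute_force


class TestTransformRate:
    def test_zero_maps_to_half(self):
        assert transform_rate(0.0) == pytest.approx(0.5, abs=1e-15)

    def test_matches_normal_cdf_oracle(self):
        for raw in (-2.49, -2.38, -2.17, -1.55, 0.3, 2.0):
            assert transform_rate(raw) == pytest.approx(
                stats.norm.cdf(raw), abs=1e-12)
        assert transform_rate(-2.17) == pytest.approx(0.0150, abs=5e-5)

    def test_monotone_and_limits(self):
        xs = np.linspace(-8, 8, 101)
        ys = transform_rate(xs)
        assert np.all(np.diff(ys) > 0)
        assert transform_rate(40.0) == pytest.approx(1.0)
        assert frl.inverse_transform_rate(0.06) == pytest.approx(
            stats.norm.ppf(0.06), abs=1e-10)


class TestRhoStep:
    def test_negative_prediction_error_uses_alpha_neg(self):
        assert rho_step(5.0, 0.0, 0.1, 0.1) == pytest.approx(4.5, abs=1e-12)

    def test_positive_prediction_error_uses_alpha_pos(self):
        assert rho_step(5.0, 80.0, 0.1, 0.02) == pytest.approx(12.5, abs=1e-12)

    def test_zero_learning_rates_freeze_rho(self):
        assert rho_step(5.0, 80.0, 0.0, 0.0) == 5.0

    def test_reward_branch_variant(self):
        # on a reward second the reward rule always applies alpha_pos,
        # even for a negative prediction error
        assert rho_step(100.0, 80.0, 0.1, 0.5, branch_on="reward") == \
            pytest.approx(98.0)
        assert rho_step(100.0, 80.0, 0.1, 0.5) == pytest.approx(90.0)


class TestModulatedRate:
    def test_zero_covariate(self):
        assert modulated_rate(0.0, 1.0, 0.0) == pytest.approx(0.5)

    def test_reduces_to_plain_rate_when_slope_zero(self):
        phys = np.linspace(-3, 3, 7)
        assert np.allclose(modulated_rate(-2.2, 0.0, phys),
                           transform_rate(-2.2))

    def test_negative_slope_lowers_rate_at_high_drive(self):
        assert modulated_rate(-2.11, -0.007, 2.0) < modulated_rate(
            -2.11, -0.007, 0.0)


class TestChoiceProb:
    def test_indifference_point(self):
        assert choice_prob(80.0, 8.0, 10.0, 0.0, 0.13) == pytest.approx(0.5)

    def test_capture_bias_at_zero_value(self):
        # r - delay*rho = 0 with beta0 = -0.15
        p = choice_prob(24.0, 3.0, 8.0, -0.15, 0.13)
        assert p == pytest.approx(1.0 / (1.0 + np.exp(-0.15)), abs=1e-12)
        assert p == pytest.approx(0.5374, abs=1e-4)

    def test_value_blind_limit(self):
        p1 = choice_prob(80.0, 3.0, 1.0, 0.4, 0.0)
        p2 = choice_prob(30.0, 8.0, 20.0, 0.4, 0.0)
        assert p1 == p2 == pytest.approx(1.0 / (1.0 + np.exp(0.4)))

    def test_overflow_guarded(self):
        assert choice_prob(80.0, 3.0, 0.0, 0.0, 100.0) == pytest.approx(1.0)
        assert choice_prob(0.0, 8.0, 100.0, 0.0, 100.0) == pytest.approx(0.0)


def _constructed_sessions():
    rng = np.random.default_rng(17)
    s1 = make_session(reward=[80, 30, 80], delay=[3, 8, 8],
                      action=[1, 0, 1], pep=rng.normal(size=3),
                      hr=rng.normal(size=3))
    s2 = make_session(reward=[30, 30, 80, 80, 30], delay=[8, 3, 3, 8, 3],
                      action=[0, 1, 1, 1, 0], error=[0, 1, 0, 0, 0],
                      forced=[0, 0, 1, 0, 0], pep=rng.normal(size=5),
                      hr=rng.normal(size=5))
    s3 = make_session(reward=[80] * 6 + [30] * 6, delay=[3, 8] * 6,
                      action=[1, 0] * 6, pep=rng.normal(size=12),
                      hr=rng.normal(size=12))
    return [s1, s2, s3]


class TestLikelihoodEngine:
    def test_matches_brute_force_per_second_oracle(self):
        """Compiled closed-form engine equals a literal per-second loop."""
        rng = np.random.default_rng(11)
        for sess in _constructed_sessions():
            for name in ("symmetric", "asymmetric", "asym_phys_pos_pep",
                         "asym_phys_neg_hr"):
                spec = MODEL_SPECS[name]
                for _ in range(5):
                    p = rng.normal(0, 1, spec.n_params)
                    for branch in ("pe_sign", "reward"):
                        got = nll_choices(sess, p, spec, 7.97, branch_on=branch)
                        want = nll_brute_force(sess, p, spec, 7.97,
                                               branch_on=branch)
                        assert got == pytest.approx(want, abs=1e-8)

    def test_single_indifferent_trial_is_ln2(self):
        sess = make_session(reward=[80], delay=[3], action=[1])
        nll = nll_choices(sess, [0.0, 0.0, 0.0], MODEL_SPECS["symmetric"], 7.97)
        assert nll == pytest.approx(np.log(2.0), abs=1e-12)

    def test_deterministic_agreement_drives_nll_to_zero(self):
        # value-consistent choices + huge beta1 -> perfect prediction
        sess = make_session(reward=[80, 30], delay=[3, 8], action=[1, 0])
        nll = nll_choices(sess, [-3.0, 0.0, 50.0], MODEL_SPECS["symmetric"],
                          7.97)
        assert nll < 1e-6

    def test_forced_and_error_trials_excluded_from_likelihood(self):
        s_all = make_session(reward=[80, 80, 80], delay=[3, 3, 3],
                             action=[1, 1, 1])
        s_excl = make_session(reward=[80, 80, 80], delay=[3, 3, 3],
                              action=[1, 1, 1], forced=[0, 1, 0])
        p = [-1.5, 0.0, 0.1]
        assert nll_choices(s_excl, p, MODEL_SPECS["symmetric"], 7.97) < \
            nll_choices(s_all, p, MODEL_SPECS["symmetric"], 7.97)

    def test_nesting_identities_exact(self):
        """Asymmetric at α⁺=α⁻ equals symmetric; phys at b₁=0 equals asymmetric."""
        for sess in _constructed_sessions():
            sym = nll_choices(sess, [-1.7, -0.15, 0.13],
                              MODEL_SPECS["symmetric"], 7.97)
            asym = nll_choices(sess, [-1.7, -1.7, -0.15, 0.13],
                               MODEL_SPECS["asymmetric"], 7.97)
            assert asym == pytest.approx(sym, abs=1e-12)
            asym2 = nll_choices(sess, [-1.4, -2.2, -0.15, 0.13],
                                MODEL_SPECS["asymmetric"], 7.97)
            pos = nll_choices(sess, [-1.4, 0.0, -2.2, -0.15, 0.13],
                              MODEL_SPECS["asym_phys_pos_pep"], 7.97)
            neg = nll_choices(sess, [-1.4, -2.2, 0.0, -0.15, 0.13],
                              MODEL_SPECS["asym_phys_neg_hr"], 7.97)
            assert pos == pytest.approx(asym2, abs=1e-12)
            assert neg == pytest.approx(asym2, abs=1e-12)

    def test_rho_trace_agrees_with_kernel_decisions(self):
        for sess in _constructed_sessions():
            spec = MODEL_SPECS["asymmetric"]
            p = [-1.2, -2.0, -0.15, 0.13]
            tr = rho_trace(sess, p, spec, 7.97)
            dec = tr[tr["is_decision"]]["rho"].to_numpy()
            assert np.allclose(dec, decision_rhos(sess, p, spec, 7.97),
                               atol=1e-10)
            # full clock is accounted second by second
            assert len(tr) == 2 * sess.n_trials + sum(
                (int(d) if a and not e else 0) + (8 if e else 0)
                for d, a, e in zip(sess.delay, sess.action, sess.error))

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        sess = _constructed_sessions()[2]
        for name in ("symmetric", "asymmetric", "asym_phys_neg_pep"):
            spec = MODEL_SPECS[name]
            p = rng.normal(0, 0.8, spec.n_params)
            _, g = nll_and_grad(sess, p, spec, 7.97)
            for j in range(len(p)):
                e = np.zeros(len(p))
                e[j] = 1e-6
                num = (nll_choices(sess, p + e, spec, 7.97)
                       - nll_choices(sess, p - e, spec, 7.97)) / 2e-6
                assert g[j] == pytest.approx(num, rel=1e-4, abs=1e-7)

    def test_non_finite_parameters_rejected(self):
        sess = _constructed_sessions()[0]
        with pytest.raises(ValueError):
            nll_choices(sess, [np.nan, 0.0, 0.1], MODEL_SPECS["symmetric"], 7.97)

    def test_missing_phys_channel_rejected(self):
        sess = make_session(reward=[80], delay=[3], action=[1])
        with pytest.raises(ValueError, match="pep"):
            nll_choices(sess, [-1.4, 0.0, 0.1, -0.15, 0.13],
                        MODEL_SPECS["asym_phys_pos_pep"], 7.97)


class TestSimulateThenEvaluate:
    def test_nll_minimized_near_generating_parameters(self):
        """Coarse 3-point grid per axis: truth beats ±0.5 perturbations."""
        gen = frl.GeneratorParams(group_sd=np.zeros(4))
        cohort, truth = frl.simulate_cohort(8, gen, seed=21)
        ids, sessions, rate = frl.prepare_sessions(
            frl.preprocess_physiology(cohort))
        spec = MODEL_SPECS["asymmetric"]
        true_p = gen.group_mean

        def total(p):
            return sum(nll_choices(s, p, spec, rate) for s in sessions)

        base = total(true_p)
        for j in range(4):
            for sign in (-1, 1):
                p = true_p.copy()
                p[j] += 0.5 * sign
                assert total(p) > base
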