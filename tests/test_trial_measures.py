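import warnings

import numpy as np
import pandas as pd
import pytest

import foragerl as frl
from foragerl.measures import (add_objective_rates, db_drive, db_mid,
                               flip_pep_sign, objective_value,
                               preprocess_physiology, trial_derivative,
                               update_mu)


class TestUpdateMu:
    def test_capture_update(self):
        # (8*100 + 80)/110
        assert update_mu(8.0, 100.0, 110.0, 80.0, 1) == pytest.approx(8.0, abs=1e-12)

    def test_release_update(self):
        assert update_mu(8.0, 100.0, 105.0, 0.0, 0) == pytest.approx(800 / 105, abs=1e-12)

    def test_timing_bug_raises(self):
        with pytest.raises(ValueError):
            update_mu(8.0, 100.0, 0.0, 80.0, 1)
        with pytest.raises(ValueError):
            update_mu(8.0, 100.0, 100.0, 80.0, 1)


class TestObjectiveValue:
    def test_worked_examples(self):
        theta, value = objective_value(80.0, 3.0, 7.97)
        assert theta == pytest.approx(23.91, abs=1e-10)
        assert value == pytest.approx(56.09, abs=1e-10)
        theta, value = objective_value(30.0, 8.0, 7.97)
        assert theta == pytest.approx(63.76, abs=1e-10)
        assert value == pytest.approx(-33.76, abs=1e-10)

    def test_zero_rate_gives_full_reward(self):
        _, value = objective_value(55.0, 8.0, 0.0)
        assert value == 55.0

    def test_linear_in_mu_with_slope_minus_delay(self):
        mus = np.linspace(0, 20, 9)
        for delay in (3.0, 8.0):
            _, v = objective_value(80.0, delay, mus)
            slopes = np.diff(v) / np.diff(mus)
            assert np.allclose(slopes, -delay, atol=1e-12)

    def test_nonpositive_delay_rejected(self):
        with pytest.raises(ValueError):
            objective_value(80.0, 0.0, 7.97)


class TestTrialDerivative:
    def test_constant_series_zero(self):
        out = trial_derivative([2.0, 2.0, 2.0], [1, 1, 1])
        assert np.isnan(out[0]) and np.all(out[1:] == 0.0)

    def test_first_differences(self):
        out = trial_derivative([1.0, 3.0, 6.0], [1, 1, 1])
        assert np.isnan(out[0])
        assert list(out[1:]) == [2.0, 3.0]

    def test_block_boundary_missing(self):
        out = trial_derivative([1.0, 2.0, 10.0, 11.0], [1, 1, 2, 2])
        assert np.isnan(out[2]) and out[3] == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            trial_derivative([1.0, 2.0], [1])


class TestMuTelescoping:
    def test_identity_over_block_one(self, one_subject):
        """μ_t·s_t telescopes to the cumulative harvested reward."""
        df = add_objective_rates(one_subject)
        b1 = df[df["block"] == 1]
        cum = np.concatenate([[0.0], np.cumsum(
            b1["reward_harvested"].to_numpy())[:-1]])
        prod = b1["mu"].to_numpy() * b1["onset_s"].to_numpy()
        # s1 = 0 erases the prior, so mu_t * s_t = sum of earlier harvests
        assert np.allclose(prod[1:], cum[1:], rtol=1e-12, atol=1e-9)

    def test_identity_whole_session_without_reinit(self, one_subject):
        df = add_objective_rates(one_subject, block2_init="continue")
        cum = np.concatenate([[0.0], np.cumsum(
            df["reward_harvested"].to_numpy())[:-1]])
        prod = df["mu"].to_numpy() * df["onset_s"].to_numpy()
        assert np.allclose(prod[1:], cum[1:], rtol=1e-12, atol=1e-9)

    def test_block2_reinitialized_to_block1_mean(self, one_subject):
        df = add_objective_rates(one_subject)
        b1_mean = df[df["block"] == 1]["mu"].mean()
        first_b2 = df[df["block"] == 2]["mu"].iloc[0]
        assert first_b2 == pytest.approx(b1_mean, rel=1e-12)

    def test_prior_weight_keeps_initialization(self, one_subject):
        df = add_objective_rates(one_subject, prior_weight_s=300.0)
        # with pseudo-elapsed time behind the prior, trial 2's mu stays near it
        assert abs(df["mu"].iloc[1] - 7.97) < abs(
            add_objective_rates(one_subject)["mu"].iloc[1] - 7.97)

    def test_rate_columns_idempotent(self, small_cohort):
        """Recomputing μ/θ/value from the exported table reproduces itself."""
        cohort, _ = small_cohort
        recomputed = add_objective_rates(cohort.drop(
            columns=["mu", "theta", "value", "dmu_dt"]))
        for col in ("mu", "theta", "value"):
            assert np.allclose(recomputed[col], cohort[col], rtol=1e-12)


def _phys_frame(n, pep, hr, resp, subject_id=0):
    return pd.DataFrame({
        "subject_id": subject_id, "t": np.arange(1, n + 1), "block": 1,
        "pep": pep, "hr": hr, "respiration": resp,
    })


class TestPreprocessPhysiology:
    def test_uncorrelated_respiration_gives_centered_channel(self):
        rng = np.random.default_rng(0)
        n = 4000
        pep = rng.normal(2.0, 1.0, n)
        resp = rng.normal(size=n)
        df = _phys_frame(n, pep, pep, resp)
        df.attrs["pep_drive_signed"] = True
        out = preprocess_physiology(df)
        # slope ~0 so residuals are the centered, standardized channel
        expected = (pep - pep.mean())
        expected /= expected.std()
        assert np.corrcoef(out["pep_corrected"], expected)[0, 1] > 0.999

    def test_perfectly_collinear_channel_residuals_vanish(self):
        resp = np.linspace(-2, 2, 500)
        df = _phys_frame(500, 2.0 * resp, resp, resp)
        df.attrs["pep_drive_signed"] = True
        out = preprocess_physiology(df)
        # residuals of an exact fit are ~0 before standardization
        raw_resid = 2.0 * resp - np.poly1d(
            np.polyfit(resp, 2.0 * resp, 1))(resp)
        assert np.abs(raw_resid).max() < 1e-9

    def test_generator_leak_slope_recovered(self):
        """Fitted pep~respiration slope matches the generating leak."""
        gen = frl.GeneratorParams(resp_leak_pep=0.5, phys_ar1=0.0,
                                  pep_deterioration_gain=0.0,
                                  pep_gain_subject_sd=0.0)
        rng = np.random.default_rng(3)
        state = (0.0, 0.0, 0.0, 0.0)
        peps, resps = [], []
        n = 5000
        for _ in range(n):
            pep, hr, resp, state = frl.gen_trial_physiology(
                state, 0.0, 10.0, False, gen, rng)
            peps.append(pep)
            resps.append(resp)
        slope = np.polyfit(resps, peps, 1)[0]
        se = gen.phys_noise_sd / np.sqrt(n)
        assert abs(slope - 0.5) < 3 * se

    def test_constant_respiration_warns_and_skips(self):
        df = _phys_frame(50, np.random.default_rng(0).normal(size=50),
                         np.zeros(50), np.ones(50))
        df.attrs["pep_drive_signed"] = True
        with pytest.warns(UserWarning, match="constant respiration"):
            preprocess_physiology(df)

    def test_sign_flip_guard(self):
        df = _phys_frame(10, np.ones(10), np.ones(10), np.ones(10))
        flipped = flip_pep_sign(df)
        assert (flipped["pep"] == -1.0).all()
        with pytest.raises(ValueError, match="already drive-signed"):
            flip_pep_sign(flipped)

    def test_preprocess_requires_drive_signed_pep(self):
        df = _phys_frame(10, np.ones(10), np.ones(10), np.ones(10))
        with pytest.raises(ValueError, match="drive-signed"):
            preprocess_physiology(df)


def _session_frame(rows):
    return pd.DataFrame(rows, columns=[
        "subject_id", "env", "rank", "action", "forced", "error", "onset_s",
        "pep_corrected", "hr_corrected"])


def _mk_rows(env, rank, n_cap, n_rel, onset=0.0):
    rows = []
    for k in range(n_cap):
        rows.append((0, env, rank, "capture", False, False, onset + k, 0.0, 0.0))
    for k in range(n_rel):
        rows.append((0, env, rank, "release", False, False, onset + k, 0.0, 0.0))
    return rows


class TestDBMetrics:
    def test_db_mid_worked_example(self):
        rows = _mk_rows("downturn", "mid", 10, 6) + _mk_rows("boom", "mid", 4, 12)
        assert db_mid(_session_frame(rows)) == pytest.approx(0.375)

    def test_db_mid_extremes_and_symmetry(self):
        rows = _mk_rows("downturn", "mid", 5, 0) + _mk_rows("boom", "mid", 0, 5)
        assert db_mid(_session_frame(rows)) == 1.0
        rows = _mk_rows("downturn", "mid", 3, 3) + _mk_rows("boom", "mid", 3, 3)
        assert db_mid(_session_frame(rows)) == 0.0

    def test_db_mid_undefined_without_mid_encounters(self):
        rows = _mk_rows("downturn", "mid", 3, 3) + _mk_rows("boom", "high", 3, 3)
        with pytest.warns(UserWarning):
            assert np.isnan(db_mid(_session_frame(rows)))

    def test_db_mid_excludes_forced_and_error_trials(self):
        rows = _mk_rows("downturn", "mid", 2, 2) + _mk_rows("boom", "mid", 2, 2)
        df = _session_frame(rows)
        extra = _session_frame(_mk_rows("downturn", "mid", 4, 0))
        extra["forced"] = True
        assert db_mid(pd.concat([df, extra])) == 0.0

    def test_db_drive_constant_channel_is_zero(self):
        rows = _mk_rows("downturn", "mid", 3, 3) + _mk_rows("boom", "mid", 3, 3)
        df = _session_frame(rows)
        df["pep_corrected"] = 1.5
        assert db_drive(df, "pep", "early") == 0.0

    def test_db_drive_worked_example(self):
        rows = _mk_rows("downturn", "mid", 4, 0) + _mk_rows("boom", "mid", 4, 0)
        df = _session_frame(rows)
        df.loc[df["env"] == "downturn", "pep_corrected"] = 0.5
        df.loc[df["env"] == "boom", "pep_corrected"] = -0.5
        assert db_drive(df, "pep", "early") == pytest.approx(1.0)

    def test_window_boundary_trial_is_late(self):
        rows = []
        for env in ("downturn", "boom"):
            rows += [(0, env, "mid", "capture", False, False, o, p, 0.0)
                     for o, p in [(0.0, 1.0), (359.0, 1.0), (360.0, 9.0),
                                  (500.0, 9.0)]]
        df = _session_frame(rows)
        df.loc[df["env"] == "boom", "pep_corrected"] = 0.0
        # early window: onsets 0 and 359 only -> mean 1.0 in downturn
        assert db_drive(df, "pep", "early") == pytest.approx(1.0)
        assert db_drive(df, "pep", "late") == pytest.approx(9.0)
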