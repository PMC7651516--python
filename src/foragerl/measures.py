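"""Objective reward-rate quantities, physiology preprocessing, and
downturn-minus-boom summary metrics.

The objective reward rate μ_t (points per second harvested through the
beginning of trial t) defines, for each offer, an opportunity cost
θ_t = delay_t·μ_t and a net value value_t = reward_t − θ_t: the yardstick
an ideal observer with full knowledge of its own harvest history would use.
Trial-wise first differences of μ, PEP and HR quantify moment-to-moment
environmental and autonomic perturbations.  D−B metrics summarize, per
subject, how behavior (mid-rank capture rate) and physiology shift from the
rich (boom) to the poor (downturn) environment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "update_mu",
    "objective_value",
    "trial_derivative",
    "add_objective_rates",
    "flip_pep_sign",
    "preprocess_physiology",
    "db_mid",
    "db_drive",
    "db_table",
]

MU_INIT_DEFAULT = 7.97  # points/s: cohort-average harvest rate used as the t=1 prior


def update_mu(mu_prev: float, s_prev: float, s_curr: float,
              reward_prev: float, captured_prev: int) -> float:
    """Advance the objective reward rate by one trial.

    μ_t = (μ_{t−1}·s_{t−1} + r_{t−1}·c_{t−1}) / s_t, where s are trial-onset
    times in seconds from experiment start, r the reward on offer and c the
    binary capture indicator of the previous trial.
    """
    if s_curr <= 0:
        raise ValueError("s_curr must be positive (timing bug upstream)")
    if s_curr <= s_prev:
        raise ValueError("trial onsets must be strictly increasing")
    return (mu_prev * s_prev + reward_prev * captured_prev) / s_curr


def objective_value(reward: float, delay: float, mu: float):
    """Opportunity cost θ = delay·μ and net value = reward − θ of an offer."""
    if np.any(np.asarray(delay) <= 0):
        raise ValueError("delay must be positive")
    theta = np.multiply(delay, mu)
    return theta, np.subtract(reward, theta)


def trial_derivative(series, block_ids) -> np.ndarray:
    """Consecutive-trial first differences, reset (NaN) at block starts."""
    series = np.asarray(series, dtype=float)
    block_ids = np.asarray(block_ids)
    if series.shape != block_ids.shape:
        raise ValueError("series and block_ids must be aligned")
    out = np.full_like(series, np.nan)
    out[1:] = series[1:] - series[:-1]
    out[np.r_[True, block_ids[1:] != block_ids[:-1]]] = np.nan
    return out


def _mu_for_subject(df: pd.DataFrame, mu_init: float, block2_init: str,
                    prior_weight_s: float) -> np.ndarray:
    """Recompute the μ trajectory for one subject's ordered trials.

    ``block2_init`` controls re-initialization at the second block:
    ``"block1_mean"`` (default: the subject's average μ over block-1
    trials), ``"block1_final"``, or ``"continue"`` (no re-initialization,
    which preserves the telescoping identity μ_T·s_T = Σ r·c across the
    whole session).  ``prior_weight_s`` adds pseudo-elapsed seconds behind
    the t=1 prior so it can persist past the literal s₁ = 0 formula.
    """
    onset = df["onset_s"].to_numpy(dtype=float)
    harvested = df["reward_harvested"].to_numpy(dtype=float)
    block = df["block"].to_numpy()
    n = len(df)
    mu = np.empty(n)
    mu[0] = mu_init
    w = float(prior_weight_s)
    block1 = block == block[0]
    for t in range(1, n):
        new_block = block[t] != block[t - 1]
        if new_block and block2_init == "block1_mean":
            mu[t] = mu[:t][block1[:t]].mean()
        elif new_block and block2_init == "block1_final":
            mu[t] = mu[t - 1]
        else:
            mu[t] = update_mu(mu[t - 1], onset[t - 1] + w, onset[t] + w,
                              harvested[t - 1], 1)
    return mu


def add_objective_rates(cohort: pd.DataFrame, mu_init: float = MU_INIT_DEFAULT,
                        block2_init: str = "block1_mean",
                        prior_weight_s: float = 0.0) -> pd.DataFrame:
    """Add μ, θ, value and trial-derivative columns to a tidy cohort table.

    Adds ``mu``, ``theta``, ``value``, ``dmu_dt`` and — when preprocessed
    physiology columns are present — ``dpep_dt``/``dhr_dt``.  Derivatives
    are NaN on the first trial of each block.  μ updates on every trial
    (forced and error trials consume real time and harvest real reward).
    """
    if block2_init not in ("block1_mean", "block1_final", "continue"):
        raise ValueError(f"unknown block2_init: {block2_init!r}")
    out = cohort.copy()
    mu = np.empty(len(out))
    for _, idx in out.groupby("subject_id", sort=False).indices.items():
        sub = out.iloc[idx]
        mu[idx] = _mu_for_subject(sub, mu_init, block2_init, prior_weight_s)
    out["mu"] = mu
    theta, value = objective_value(out["reward"].to_numpy(),
                                   out["delay"].to_numpy(), mu)
    out["theta"] = theta
    out["value"] = value
    key = out["subject_id"].astype(str) + "/" + out["block"].astype(str)
    out["dmu_dt"] = trial_derivative(mu, key.to_numpy())
    for chan in ("pep", "hr"):
        col = f"{chan}_corrected"
        if col in out:
            out[f"d{chan}_dt"] = trial_derivative(out[col].to_numpy(),
                                                  key.to_numpy())
    return out


def flip_pep_sign(cohort: pd.DataFrame) -> pd.DataFrame:
    """Negate raw PEP once so that higher values mean more sympathetic drive.

    Raw pre-ejection periods shrink as beta-adrenergic contractility rises;
    the analysis convention negates them at ingestion.  Applying the flip a
    second time raises instead of silently double-flipping.
    """
    if cohort.attrs.get("pep_drive_signed", False):
        raise ValueError("PEP is already drive-signed; refusing to flip twice")
    out = cohort.copy()
    out["pep"] = -out["pep"].to_numpy(dtype=float)
    out.attrs["pep_drive_signed"] = True
    return out


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of a simple linear regression of y on x (with intercept)."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def preprocess_physiology(cohort: pd.DataFrame,
                          channels=("pep", "hr")) -> pd.DataFrame:
    """Respiration-correct and standardize trial-wise physiology per subject.

    Each channel is replaced by the residuals of a per-subject simple linear
    regression on the trial-wise respiratory state, then z-scored within
    subject; results land in ``pep_corrected``/``hr_corrected``.  Requires
    drive-signed PEP (see :func:`flip_pep_sign`); synthetic cohorts are
    generated drive-signed already.  Constant respiration makes the
    regression undefined: residualization is skipped with a warning.
    """
    if not cohort.attrs.get("pep_drive_signed", False) and "pep" in channels:
        raise ValueError(
            "PEP must be drive-signed before preprocessing; call flip_pep_sign "
            "on raw-convention data (synthetic cohorts are already drive-signed)")
    out = cohort.copy()
    for chan in channels:
        out[f"{chan}_corrected"] = np.nan
    for sid, idx in out.groupby("subject_id", sort=False).indices.items():
        resp = out["respiration"].to_numpy(dtype=float)[idx]
        for chan in channels:
            y = out[chan].to_numpy(dtype=float)[idx]
            if np.ptp(resp) == 0.0:
                warnings.warn(
                    f"subject {sid}: constant respiration, skipping "
                    "residualization", stacklevel=2)
                resid = y - y.mean()
            else:
                resid = _residualize(y, resp)
            sd = resid.std()
            out.loc[out.index[idx], f"{chan}_corrected"] = (
                resid / sd if sd > 0 else resid)
    out.attrs.update(cohort.attrs)
    return out


def _free_ok(df: pd.DataFrame) -> pd.DataFrame:
    return df[(~df["forced"].astype(bool)) & (~df["error"].astype(bool))]


def db_mid(session: pd.DataFrame) -> float:
    """Downturn-minus-boom difference in mid-rank capture proportion.

    Only free-choice, error-free trials count.  Returns NaN (with a
    warning) when either environment offers no mid-rank encounters.
    """
    free = _free_ok(session)
    mid = free[free["rank"] == "mid"]
    props = {}
    for env in ("downturn", "boom"):
        sub = mid[mid["env"] == env]
        if len(sub) == 0:
            warnings.warn(f"no mid-rank encounters in {env}; D-B Mid undefined",
                          stacklevel=2)
            return float("nan")
        props[env] = (sub["action"] == "capture").mean() \
            if sub["action"].dtype == object else sub["action"].mean()
    return float(props["downturn"] - props["boom"])


def db_drive(session: pd.DataFrame, channel: str, window: str,
             split_s: float = 360.0) -> float:
    """Downturn-minus-boom mean of a physiology channel within a time window.

    Windows split each environment's time in half at ``split_s`` seconds
    from block start (360 s at the default 720-s blocks): ``early`` is
    onset < split_s, ``late`` is onset ≥ split_s (half-open; a trial
    starting exactly at the boundary is late).
    """
    col = f"{channel}_corrected"
    if col not in session:
        raise ValueError(f"missing column {col}; run preprocess_physiology first")
    if window not in ("early", "late"):
        raise ValueError(f"unknown window: {window!r}")
    means = {}
    for env in ("downturn", "boom"):
        sub = session[session["env"] == env]
        if len(sub) == 0:
            raise ValueError(f"no trials in environment {env}")
        rel = sub["onset_s"].to_numpy(dtype=float) - sub["onset_s"].min()
        half = rel < split_s if window == "early" else rel >= split_s
        if not half.any():
            raise ValueError(f"empty {window} window in {env}")
        means[env] = float(sub[col].to_numpy(dtype=float)[half].mean())
    return means["downturn"] - means["boom"]


def db_table(cohort: pd.DataFrame, split_s: float = 360.0) -> pd.DataFrame:
    """Per-subject D−B metrics: mid-capture delta plus early/late PEP and HR
    drive deltas (one row per subject)."""
    rows = []
    for sid, sub in cohort.groupby("subject_id", sort=False):
        row = {"subject_id": sid, "order": sub["order"].iloc[0],
               "db_mid": db_mid(sub)}
        for chan in ("pep", "hr"):
            for window in ("early", "late"):
                row[f"db_drive_{chan}_{window}"] = db_drive(
                    sub, chan, window, split_s=split_s)
        rows.append(row)
    return pd.DataFrame(rows)
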