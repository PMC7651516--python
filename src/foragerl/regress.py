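"""Trial-wise choice and physiology regressions, and the optimality model.

Trial-wise models are maximum-likelihood logistic (choice) or linear
(reward-rate derivative) regressions with one intercept per subject and
shared slopes — the fixed-effects form of a random-intercept model, which
is identical in its slope contract and fully specifiable.  Continuous
predictors are z-scored across the pooled free-choice, error-free trials;
the reward-rate derivative model works in native units (points/s and
physiology-SD units per trial).  Coefficient stability is summarized by
leave-one-subject-out jackknife means and SDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "prepare_choice_frame",
    "logistic_trialwise",
    "choice_history_model",
    "phys_value_model",
    "mu_derivative_model",
    "db_optimality_model",
    "jackknife_coefficients",
]


@dataclass
class RegressionResult:
    """Coefficients with Wald/t standard errors and p-values.

    ``table`` has one row per term (subject intercepts prefixed ``subj:``);
    ``jackknife`` (when attached) adds β_μ/β_σ columns per slope term.
    """

    table: pd.DataFrame
    n_obs: int
    kind: str  # "logistic" | "ols"
    flags: dict = field(default_factory=dict)
    jackknife: pd.DataFrame | None = None

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "se"])

    def pvalue(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])

    @property
    def slope_terms(self) -> list[str]:
        return [t for t in self.table["term"] if not t.startswith("subj:")]


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = np.nanstd(x)
    return (x - np.nanmean(x)) / sd if sd > 0 else x - np.nanmean(x)


def prepare_choice_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Free-choice, error-free analysis frame with standardized predictors.

    Expects a cohort that has been through ``preprocess_physiology`` and
    ``add_objective_rates``.  Previous-trial reward/delay are taken from the
    immediately preceding encounter in the raw sequence (any trial type) and
    are missing at block starts.
    """
    df = cohort.copy()
    df["capture"] = (df["action"] == "capture").astype(int) \
        if df["action"].dtype == object else df["action"].astype(int)
    blockkey = df["subject_id"].astype(str) + "/" + df["block"].astype(str)
    same_block = blockkey.eq(blockkey.shift(1))
    df["reward_prev"] = df["reward"].shift(1).where(same_block)
    df["delay_prev"] = df["delay"].shift(1).where(same_block)
    free = df[(~df["forced"].astype(bool)) & (~df["error"].astype(bool))].copy()
    for col in ("reward", "delay", "reward_prev", "delay_prev", "value", "t"):
        if col in free:
            free[f"{col}_z"] = _zscore(free[col].to_numpy())
    free["order_db"] = (free["order"] == "DB").astype(float)
    free["env_down"] = (free["env"] == "downturn").astype(float)
    return free


def _build_design(df: pd.DataFrame, terms: list[str]):
    """Design matrix: per-subject intercept dummies plus the listed terms.

    A term ``"a:b"`` is the elementwise product of columns a and b (their
    marginals must be listed separately; the model builders do so).
    Between-subject terms (constant within every subject, e.g. the block
    order) are perfectly collinear with the intercepts and are absorbed by
    them: they are dropped and reported in the ``absorbed`` list.
    """
    subj = pd.get_dummies(df["subject_id"], prefix="subj", prefix_sep=":",
                          dtype=float)
    cols = {}
    absorbed = []
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            col = df[a].to_numpy(float) * df[b].to_numpy(float)
        else:
            col = df[term].to_numpy(float)
        if len(subj.columns) > 1 and pd.Series(col).groupby(
                df["subject_id"].to_numpy()).nunique().le(1).all():
            absorbed.append(term)
        else:
            cols[term] = col
    X = pd.concat([subj, pd.DataFrame(cols, index=df.index)], axis=1)
    return X, absorbed


def _fit_table(y, X, kind: str) -> RegressionResult:
    mask = ~(np.isnan(np.asarray(X, dtype=float)).any(axis=1)
             | np.isnan(np.asarray(y, dtype=float)))
    Xc, yc = X[mask], np.asarray(y, dtype=float)[mask]
    flags = {}
    rank = np.linalg.matrix_rank(np.asarray(Xc, dtype=float))
    if rank < Xc.shape[1]:
        flags["rank_deficient"] = True
        warnings.warn("rank-deficient design matrix", stacklevel=3)
    if kind == "logistic":
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                res = sm.Logit(yc, Xc).fit(disp=0, maxiter=200)
            params, bse, pvals = res.params, res.bse, res.pvalues
            if any("PerfectSeparation" in type(w.message).__name__
                   for w in caught) \
                    or not res.mle_retvals.get("converged", True) \
                    or np.any(np.abs(params) > 50):
                flags["separation"] = True
        except Exception:
            flags["separation"] = True
            params = pd.Series(np.nan, index=Xc.columns)
            bse = pd.Series(np.inf, index=Xc.columns)
            pvals = pd.Series(np.nan, index=Xc.columns)
    else:
        res = sm.OLS(yc, Xc).fit()
        params, bse, pvals = res.params, res.bse, res.pvalues
    if flags.get("separation"):
        # unidentified coefficients get an explicit infinite-SE marker
        bse = pd.Series(np.where((np.abs(params) > 50) | (np.asarray(bse) > 1e3),
                                 np.inf, bse), index=params.index)
    table = pd.DataFrame({"term": params.index, "estimate": params.values,
                          "se": np.asarray(bse), "p": np.asarray(pvals)})
    return RegressionResult(table=table, n_obs=int(mask.sum()), kind=kind,
                            flags=flags)


def logistic_trialwise(data: pd.DataFrame, response: str,
                       terms: list[str]) -> RegressionResult:
    """ML logistic regression with per-subject intercepts and shared slopes."""
    X, absorbed = _build_design(data, terms)
    res = _fit_table(data[response].to_numpy(), X, "logistic")
    if absorbed:
        res.flags["absorbed"] = absorbed
    return res


def choice_history_model(cohort: pd.DataFrame) -> RegressionResult:
    """Capture probability from the current and previous offer.

    choice_t ~ reward_t + delay_t + reward_{t−1} + delay_{t−1} with subject
    intercepts.  A negative previous-reward coefficient is the marginal-
    value signature: a high harvested reward raises the believed reward
    rate, raising the opportunity cost of future captures.
    """
    free = prepare_choice_frame(cohort)
    return logistic_trialwise(
        free, "capture", ["reward_z", "delay_z", "reward_prev_z",
                          "delay_prev_z"])


def phys_value_model(cohort: pd.DataFrame, mode: str = "combined_value"):
    """Choice models linking trial-wise physiology to offer value.

    ``two_channel_split`` fits one model per channel with physiology ×
    reward and physiology × delay interactions; ``combined_value`` fits a
    single model with PEP × value and HR × value.  Both include nuisance
    covariates order, environment and trial index, plus all marginal terms.
    Returns a dict of results for the split mode, one result otherwise.
    """
    free = prepare_choice_frame(cohort)
    nuisance = ["order_db", "env_down", "t_z"]
    if mode == "two_channel_split":
        out = {}
        for chan in ("pep", "hr"):
            c = f"{chan}_corrected"
            terms = [c, "reward_z", "delay_z", f"{c}:reward_z",
                     f"{c}:delay_z"] + nuisance
            out[chan] = logistic_trialwise(free, "capture", terms)
        return out
    if mode != "combined_value":
        raise ValueError(f"unknown mode: {mode!r}")
    terms = ["pep_corrected", "hr_corrected", "value_z",
             "pep_corrected:value_z", "hr_corrected:value_z"] + nuisance
    return logistic_trialwise(free, "capture", terms)


def mu_derivative_model(cohort: pd.DataFrame,
                        subset: str = "all") -> RegressionResult:
    """Trial-wise reward-rate perturbations against physiology perturbations.

    dμ/dt ~ dPEP/dt + dHR/dt with subject intercepts and nuisance terms
    env, choice, order and trial index, in native units.  ``subset``
    restricts to trials where dμ/dt is negative (``"deterioration"``) or
    positive (``"improvement"``).
    """
    free = prepare_choice_frame(cohort)
    for col in ("dmu_dt", "dpep_dt", "dhr_dt"):
        if col not in free:
            raise ValueError(f"missing column {col}; run add_objective_rates "
                             "after preprocess_physiology")
    if subset == "deterioration":
        free = free[free["dmu_dt"] < 0]
    elif subset == "improvement":
        free = free[free["dmu_dt"] > 0]
    elif subset != "all":
        raise ValueError(f"unknown subset: {subset!r}")
    if len(free) == 0:
        raise ValueError(f"empty subset: {subset!r}")
    X, absorbed = _build_design(free, ["dpep_dt", "dhr_dt", "env_down",
                                       "capture", "order_db", "t_z"])
    res = _fit_table(free["dmu_dt"].to_numpy(), X, "ols")
    if absorbed:
        res.flags["absorbed"] = absorbed
    return res


def db_optimality_model(db_table: pd.DataFrame,
                        window: str = "early") -> RegressionResult:
    """Across-subject OLS of D−B Mid on the two D−B Drive deltas.

    One row per subject: db_mid ~ 1 + db_drive_pep_<window> +
    db_drive_hr_<window>.  A positive PEP coefficient links early
    sympathetic engagement in the poor environment to optimal adjustment of
    mid-rank captures.
    """
    if window not in ("early", "late"):
        raise ValueError(f"unknown window: {window!r}")
    if len(db_table) < 4:
        raise ValueError("optimality model needs at least 4 subjects")
    X = pd.DataFrame({
        "const": 1.0,
        "db_drive_pep": db_table[f"db_drive_pep_{window}"].to_numpy(float),
        "db_drive_hr": db_table[f"db_drive_hr_{window}"].to_numpy(float),
    }, index=db_table.index)
    return _fit_table(db_table["db_mid"].to_numpy(), X, "ols")


def jackknife_coefficients(model_fn, cohort: pd.DataFrame,
                           subject_col: str = "subject_id"):
    """Leave-one-subject-out refits summarizing coefficient stability.

    ``model_fn`` maps a cohort table to a RegressionResult.  Returns the
    full-cohort result with a ``jackknife`` table (β_μ = mean, β_σ = SD of
    each non-intercept coefficient across refits) attached; refit failures
    are counted in ``flags['jackknife_failures']``.
    """
    full = model_fn(cohort)
    subjects = list(pd.unique(cohort[subject_col]))
    if len(subjects) < 3:
        raise ValueError("jackknife needs at least 3 subjects")
    rows = {}
    failures = 0
    for sid in subjects:
        sub = cohort[cohort[subject_col] != sid]
        try:
            res = model_fn(sub)
            tab = res.table.set_index("term")["estimate"]
            for term in full.slope_terms:
                rows.setdefault(term, []).append(float(tab.get(term, np.nan)))
        except Exception:
            failures += 1
    jk = pd.DataFrame({
        "term": list(rows),
        "beta_mu": [np.nanmean(v) for v in rows.values()],
        "beta_sigma": [np.nanstd(v, ddof=1) if len(v) > 1 else 0.0
                       for v in rows.values()],
        "n_refits": [np.sum(~np.isnan(v)) for v in rows.values()],
    })
    full.jackknife = jk
    if failures:
        full.flags["jackknife_failures"] = failures
    return full
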