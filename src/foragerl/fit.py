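"""Hierarchical model fitting: EM with Gaussian group priors, Laplace
marginal likelihoods, subject-level leave-one-out cross-validation, and the
group-level learning-rate contrast test.

Each subject's parameters θᵢ (unconstrained scale) are treated as draws
from a diagonal Gaussian group prior N(m, V).  EM alternates:

* E-step — per-subject MAP estimates θᵢ* of log p(choicesᵢ|θ) + log N(θ; m, V)
  by multi-start quasi-Newton optimization, with a Laplace (Gaussian)
  approximation of each subject posterior at the MAP giving the marginal
  likelihood  log p(choicesᵢ|m, V) ≈ log p(choicesᵢ|θᵢ*) + log N(θᵢ*; m, V)
  + (d/2)·log 2π − ½·log det Hᵢ  (Hᵢ the negative Hessian of the log
  posterior);
* M-step — m ← mean of MAPs, V ← mean of (squared deviations + Laplace
  posterior variances), the posterior-variance term guarding against
  group-variance collapse.

Models are compared by per-subject LOOcv scores: the group prior is refit
without each subject, who is then scored by their negative Laplace log
marginal likelihood under that prior; paired t-tests compare summed scores.
The α⁺ − α⁻ contrast uses the covariance of the group means obtained from
the Hessian of the summed marginal likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import (ModelSpec, SessionArrays, nll_and_grad, nll_choices,
                     transform_rate)

__all__ = [
    "GroupPrior",
    "MapFit",
    "FitResult",
    "LooScores",
    "prepare_sessions",
    "realized_rate",
    "fit_map_subject",
    "em_fit",
    "loocv",
    "compare_models",
    "group_covariance",
    "rate_difference_test",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class GroupPrior:
    """Diagonal Gaussian over unconstrained subject parameters."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.mean.shape != self.variance.shape:
            raise ValueError("prior mean/variance shape mismatch")
        if np.any(self.variance <= 0):
            raise ValueError("prior variances must be positive")

    def neg_log_pdf(self, x: np.ndarray) -> float:
        d = (x - self.mean)
        return float(0.5 * np.sum(d * d / self.variance
                                  + np.log(self.variance) + _LOG_2PI))

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mean, np.sqrt(self.variance))


@dataclass
class MapFit:
    """One subject's MAP fit with its Laplace approximation."""

    params: np.ndarray
    hessian: np.ndarray          # negative Hessian of log posterior at MAP
    log_evidence: float          # Laplace log marginal likelihood
    posterior_var: np.ndarray    # diag of inverse Hessian
    converged: bool
    psd_adjusted: bool = False


@dataclass
class FitResult:
    """Hierarchical fit of one model over a cohort."""

    spec: ModelSpec
    prior: GroupPrior
    subject_ids: list
    subject_maps: np.ndarray     # (n_subjects, d)
    subject_hessians: list
    subject_evidences: np.ndarray
    iterations: int
    converged: bool
    evidence_trajectory: list
    rho0: float
    group_cov: np.ndarray | None = None

    @property
    def summed_evidence(self) -> float:
        return float(self.subject_evidences.sum())

    def params_table(self) -> pd.DataFrame:
        """Per-subject parameters, raw and (for learning rates) transformed."""
        cols = {}
        for j, name in enumerate(self.spec.param_names):
            cols[name] = self.subject_maps[:, j]
            if "alpha" in name:
                cols[name.replace("_raw", "") + "_transformed"] = \
                    transform_rate(self.subject_maps[:, j])
        out = pd.DataFrame(cols)
        out.insert(0, "subject_id", self.subject_ids)
        return out


@dataclass
class LooScores:
    """Per-subject held-out negative log marginal likelihoods (lower = better)."""

    model: str
    subject_ids: list
    scores: np.ndarray
    failed: np.ndarray = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.failed is None:
            self.failed = np.zeros(len(self.scores), dtype=bool)

    @property
    def summed(self) -> float:
        return float(self.scores.sum())


def realized_rate(df: pd.DataFrame, approach_s: float = 2.0,
                  penalty_s: float = 8.0) -> float:
    """Realized average reward rate (points/s) of one subject's session."""
    harvested = df["reward_harvested"].sum()
    captures = (df["action"] == "capture") & (~df["error"].astype(bool))
    elapsed = (len(df) * approach_s
               + df.loc[captures, "delay"].sum()
               + df["error"].astype(bool).sum() * penalty_s)
    return float(harvested / elapsed)


def prepare_sessions(cohort: pd.DataFrame):
    """Split a tidy cohort table into per-subject SessionArrays.

    Returns ``(subject_ids, sessions, rho0)`` where ρ₀ is the cohort's
    realized mean reward per second (the fitting analogue of initializing ρ
    to the experiment-wide average reward rate).
    """
    ids, sessions, rates = [], [], []
    for sid, sub in cohort.groupby("subject_id", sort=False):
        ids.append(sid)
        sessions.append(SessionArrays.from_frame(sub))
        rates.append(realized_rate(sub))
    return ids, sessions, float(np.mean(rates))


def _numerical_hessian(f, x, step=1e-3):
    d = len(x)
    H = np.empty((d, d))
    h = step * (1.0 + np.abs(x))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)) / (4.0 * h[i] * h[j])
    return H


def _nearest_psd(H, floor=1e-8):
    w, v = np.linalg.eigh(0.5 * (H + H.T))
    adjusted = bool(np.any(w < floor))
    w = np.clip(w, floor, None)
    return (v * w) @ v.T, adjusted


def _hessian_from_grad(grad_fn, x, step=1e-4):
    """Central-difference Hessian from an analytic gradient."""
    d = len(x)
    H = np.empty((d, d))
    h = step * (1.0 + np.abs(x))
    for j in range(d):
        ej = np.zeros(d); ej[j] = h[j]
        H[:, j] = (grad_fn(x + ej) - grad_fn(x - ej)) / (2.0 * h[j])
    return 0.5 * (H + H.T)


def map_laplace(neg_log_post, x0s, bounds=None, jac=False,
                min_curvature=None):
    """Multi-start MAP of a negative log posterior plus its Laplace integral.

    ``neg_log_post`` returns a scalar, or ``(value, gradient)`` when
    ``jac=True``.  Returns a :class:`MapFit` whose ``log_evidence``
    approximates log ∫ exp(−neg_log_post(θ)) dθ = −nlp(θ*) + (d/2)·log 2π
    − ½·log det H.  On a quadratic (Gaussian) posterior the approximation
    is exact.

    ``min_curvature`` (a diagonal, typically the prior precision when the
    posterior is likelihood + Gaussian prior) declares curvature the
    Hessian is known to contain: the numeric Hessian minus that diagonal is
    floored at PSD before the diagonal is restored, which keeps posterior
    variances finite when the likelihood is locally flat or kinked.
    """
    best = None
    any_converged = False
    for x0 in x0s:
        res = optimize.minimize(neg_log_post, np.asarray(x0, dtype=float),
                                method="L-BFGS-B", bounds=bounds, jac=jac)
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimization starts failed")
    x = best.x
    d = len(x)
    if jac:
        H = _hessian_from_grad(lambda z: neg_log_post(z)[1], x)
    else:
        H = _numerical_hessian(neg_log_post, x)
    if min_curvature is not None:
        Hlik, adjusted = _nearest_psd(H - np.diag(min_curvature), floor=0.0)
        H = Hlik + np.diag(min_curvature)
    else:
        H, adjusted = _nearest_psd(H)
        if adjusted:
            warnings.warn("non-PSD Hessian at MAP; projected to nearest PSD",
                          stacklevel=2)
    sign, logdet = np.linalg.slogdet(H)
    log_ev = -best.fun + 0.5 * d * _LOG_2PI - 0.5 * logdet
    post_var = np.diag(np.linalg.inv(H)).copy()
    return MapFit(params=x, hessian=H, log_evidence=float(log_ev),
                  posterior_var=post_var, converged=any_converged,
                  psd_adjusted=adjusted)


def fit_map_subject(session: SessionArrays, spec: ModelSpec,
                    prior: GroupPrior, rho0: float, starts: int = 5,
                    rng: np.random.Generator | None = None,
                    warm_start: np.ndarray | None = None,
                    branch_on: str = "pe_sign") -> MapFit:
    """MAP-fit one subject under a group prior; Laplace evidence included."""
    rng = rng if rng is not None else np.random.default_rng(0)

    def obj(x):
        f, g = nll_and_grad(session, x, spec, rho0, branch_on=branch_on)
        return (f + prior.neg_log_pdf(x),
                g + (x - prior.mean) / prior.variance)

    x0s = [prior.mean if warm_start is None else np.asarray(warm_start)]
    x0s += [prior.sample(rng) for _ in range(max(0, starts - 1))]
    return map_laplace(obj, x0s, jac=True, min_curvature=1.0 / prior.variance)


_INIT_MEANS = {
    "symmetric": np.array([-1.5, 0.0, 0.1]),
    "asymmetric": np.array([-1.5, -1.5, 0.0, 0.1]),
    "asym_phys_pos": np.array([-1.5, 0.0, -1.5, 0.0, 0.1]),
    "asym_phys_neg": np.array([-1.5, -1.5, 0.0, 0.0, 0.1]),
}


def em_fit(cohort, spec: ModelSpec, tol: float = 1e-3, max_iter: int = 200,
           starts: int = 5, seed: int = 0, rho0: float | None = None,
           init_prior: GroupPrior | None = None,
           warm_maps: np.ndarray | None = None,
           branch_on: str = "pe_sign",
           variance_floor: float = 1e-4) -> FitResult:
    """Fit the hierarchical model to a cohort by EM.

    ``cohort`` is either a tidy trial table or a pre-built
    ``(subject_ids, sessions, rho0)`` triple from :func:`prepare_sessions`.
    Iterations are accepted only if they do not lower the summed Laplace
    evidence by more than ``tol`` (Laplace/optimizer noise can produce tiny
    dips): a lowering candidate E-step is retried with extra restarts and,
    if still worse, rejected — the fit stops at the best accepted state.
    ``evidence_trajectory`` records accepted iterations and is therefore
    non-decreasing within ``tol`` by construction; rejected attempts are
    counted in ``FitResult.iterations`` all the same.
    """
    if isinstance(cohort, pd.DataFrame):
        ids, sessions, rate = prepare_sessions(cohort)
    else:
        ids, sessions, rate = cohort
    if len(sessions) < 2:
        raise ValueError("EM needs at least 2 subjects")
    rho0 = rate if rho0 is None else float(rho0)
    d = spec.n_params
    prior = init_prior if init_prior is not None else GroupPrior(
        _INIT_MEANS[spec.name].copy(), np.full(d, 4.0))
    rng = np.random.default_rng(seed)
    maps = warm_maps.copy() if warm_maps is not None else None

    def e_step(pr, warm, n_starts):
        fits = []
        for i, sess in enumerate(sessions):
            fits.append(fit_map_subject(
                sess, spec, pr, rho0, starts=n_starts, rng=rng,
                warm_start=None if warm is None else warm[i],
                branch_on=branch_on))
        return fits, float(sum(f.log_evidence for f in fits))

    trajectory = []
    best = None  # (evid, maps, fits, prior)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # multi-start only while cold; warm-started E-steps are deterministic
        n_starts = starts if it == 1 and warm_maps is None else 1
        fits, evid = e_step(prior, maps, n_starts)
        if best is not None and evid < best[0] - tol:
            fits2, evid2 = e_step(prior, maps, 3)
            if evid2 > evid:
                fits, evid = fits2, evid2
            if evid < best[0] - tol:
                converged = True  # no acceptable progress; settle at best
                break
        trajectory.append(evid)
        maps = np.array([f.params for f in fits])
        if best is None or evid >= best[0]:
            best = (evid, maps.copy(), fits,
                    GroupPrior(prior.mean.copy(), prior.variance.copy()))
        if len(trajectory) > 1 and abs(evid - trajectory[-2]) < tol:
            converged = True
            break
        post_var = np.array([f.posterior_var for f in fits])
        new_mean = maps.mean(axis=0)
        new_var = np.maximum(
            ((maps - new_mean) ** 2 + post_var).mean(axis=0), variance_floor)
        prior = GroupPrior(new_mean, new_var)
    evid, maps, fits, prior = best
    return FitResult(
        spec=spec, prior=prior, subject_ids=list(ids), subject_maps=maps,
        subject_hessians=[f.hessian for f in fits],
        subject_evidences=np.array([f.log_evidence for f in fits]),
        iterations=it, converged=converged,
        evidence_trajectory=trajectory, rho0=rho0)


def loocv(cohort, spec: ModelSpec, tol: float = 1e-3, max_iter: int = 200,
          inner_max_iter: int = 6, starts: int = 5, seed: int = 0,
          full_fit: FitResult | None = None, refit_per_fold: bool = True,
          branch_on: str = "pe_sign") -> LooScores:
    """Subject-level leave-one-out cross-validation scores for one model.

    For each subject the group prior is refit by EM on the remaining
    subjects (warm-started from the full-cohort fit to bound runtime), and
    the held-out subject is scored by their negative Laplace log marginal
    likelihood under that prior.  ``refit_per_fold=False`` scores everyone
    under the full-cohort prior instead (cheaper, slightly biased).
    """
    if isinstance(cohort, pd.DataFrame):
        ids, sessions, rate = prepare_sessions(cohort)
    else:
        ids, sessions, rate = cohort
    if len(sessions) < 3:
        raise ValueError("LOOcv needs at least 3 subjects")
    if full_fit is None:
        full_fit = em_fit((ids, sessions, rate), spec, tol=tol,
                          max_iter=max_iter, starts=starts, seed=seed,
                          branch_on=branch_on)
    rho0 = full_fit.rho0
    rng = np.random.default_rng(seed + 1)
    scores = np.empty(len(sessions))
    failed = np.zeros(len(sessions), dtype=bool)
    for i, sess in enumerate(sessions):
        rest_idx = [j for j in range(len(sessions)) if j != i]
        try:
            if refit_per_fold:
                fold = em_fit(
                    ([ids[j] for j in rest_idx],
                     [sessions[j] for j in rest_idx], rate),
                    spec, tol=tol, max_iter=inner_max_iter, starts=starts,
                    seed=seed, init_prior=full_fit.prior,
                    warm_maps=full_fit.subject_maps[rest_idx],
                    branch_on=branch_on)
                prior = fold.prior
            else:
                prior = full_fit.prior
            held = fit_map_subject(sess, spec, prior, rho0, starts=3,
                                   rng=rng,
                                   warm_start=full_fit.subject_maps[i],
                                   branch_on=branch_on)
            scores[i] = -held.log_evidence
        except RuntimeError:
            scores[i] = np.nan
            failed[i] = True
    return LooScores(model=spec.name, subject_ids=list(ids), scores=scores,
                     failed=failed)


def compare_models(scores_a: LooScores, scores_b: LooScores):
    """Paired-sample t-test on per-subject LOOcv score differences (a − b).

    Returns ``(t, df, p)`` with df = n − 1; positive t means model b fits
    better (its scores are lower).  Zero variance of the differences leaves
    t undefined (NaN) with a warning.
    """
    if list(scores_a.subject_ids) != list(scores_b.subject_ids):
        raise ValueError("LOOcv scores cover different subjects")
    diffs = scores_a.scores - scores_b.scores
    n = len(diffs)
    if np.all(diffs == 0.0):
        return 0.0, n - 1, 1.0
    if np.allclose(diffs.std(ddof=1), 0.0):
        warnings.warn("zero variance of score differences; t undefined",
                      stacklevel=2)
        return float("nan"), n - 1, float("nan")
    t, p = stats.ttest_rel(scores_a.scores, scores_b.scores)
    return float(t), n - 1, float(p)


def group_covariance(fit: FitResult, cohort=None) -> np.ndarray:
    """Covariance Σ̂ of the group-mean estimates from the marginal likelihood.

    Under the Laplace approximation each subject's marginal likelihood in
    the group mean m (variance V̂ fixed) is Gaussian with information
    V̂⁻¹ − V̂⁻¹ Hᵢ⁻¹ V̂⁻¹, Hᵢ the posterior Hessian at that subject's MAP —
    a flat-likelihood subject contributes nothing, a sharply identified one
    the full prior precision.  Σ̂ is the inverse of the summed information,
    PSD by construction, stored on ``fit.group_cov``.  The ``cohort``
    argument is accepted for interface symmetry but unused: everything
    needed is already in the fit.
    """
    vinv = np.diag(1.0 / fit.prior.variance)
    info = np.zeros((len(fit.prior.mean),) * 2)
    for H in fit.subject_hessians:
        info += vinv - vinv @ np.linalg.inv(H) @ vinv
    info, _ = _nearest_psd(info)
    fit.group_cov = np.linalg.inv(info)
    return fit.group_cov


def rate_difference_test(fit: FitResult, contrast):
    """Test a linear contrast of the group means (e.g. α⁺ − α⁻ > 0).

    Returns ``(estimate, se, z, one_tailed_p)`` with se = √(cᵀ Σ̂ c) and the
    one-tailed p from the upper normal tail.  Requires ``fit.group_cov``
    (see :func:`group_covariance`).
    """
    c = np.asarray(contrast, dtype=float)
    if fit.group_cov is None:
        raise ValueError("fit has no group covariance; call group_covariance")
    if c.shape != fit.prior.mean.shape:
        raise ValueError("contrast dimension mismatch")
    est = float(c @ fit.prior.mean)
    se = float(np.sqrt(c @ fit.group_cov @ c))
    if se == 0:
        raise ValueError("zero standard error for contrast")
    z = est / se
    return est, se, z, float(stats.norm.sf(z))
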