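"""Subjective reward-rate learning models and the softmax choice likelihood.

An agent tracks a scalar estimate ρ of the environment's reward rate
(points per second) with a delta rule applied at every second of the
session clock:

    δ(s) = r(s) − ρ(s)
    ρ(s+1) = ρ(s) + α⁺·δ(s)  if δ(s) > 0   else   ρ(s) + α⁻·δ(s)

where r(s) is 0 on every second without a reward (approach, capture time,
penalties) and equals the invader reward on the feedback second of a
capture.  The symmetric model uses a single rate α = α⁺ = α⁻; the
physiology-modulated variants let α⁺ or α⁻ follow a trial-wise covariate
through α(t) = Φ(b₀ + b₁·phys(t)).  Raw learning-rate parameters live on an
unconstrained scale and are mapped into (0, 1) by the standard-normal CDF
Φ(x) = 0.5 + 0.5·erf(x/√2).

At the end of each 2-s approach the agent chooses capture/release via

    P(capture) = 1 / (1 + exp(β₀ − β₁·(rᵢ − delayᵢ·ρ)))

Because r(s) = 0 on every non-feedback second and ρ stays positive, the
per-second recursion has an exact per-trial closed form — a run of k
reward-free seconds multiplies ρ by (1 − α⁻)^k — which the compiled
likelihood kernel uses.  :func:`rho_trace` runs the literal per-second loop
and is guaranteed (and tested) to agree with the kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import _kernels

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "transform_rate",
    "inverse_transform_rate",
    "rho_step",
    "modulated_rate",
    "choice_prob",
    "SessionArrays",
    "nll_choices",
    "decision_rhos",
    "rho_trace",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which learning model, and which physiology channel modulates it."""

    name: str  # symmetric | asymmetric | asym_phys_pos | asym_phys_neg
    phys_channel: str = "none"  # pep | hr | none

    _NAMES = ("symmetric", "asymmetric", "asym_phys_pos", "asym_phys_neg")
    _PARAM_NAMES = {
        "symmetric": ("alpha_raw", "beta0", "beta1"),
        "asymmetric": ("alpha_pos_raw", "alpha_neg_raw", "beta0", "beta1"),
        "asym_phys_pos": ("b0", "b1", "alpha_neg_raw", "beta0", "beta1"),
        "asym_phys_neg": ("alpha_pos_raw", "b0", "b1", "beta0", "beta1"),
    }

    def __post_init__(self):
        if self.name not in self._NAMES:
            raise ValueError(f"unknown model name: {self.name!r}")
        needs_phys = self.name in ("asym_phys_pos", "asym_phys_neg")
        if needs_phys and self.phys_channel not in ("pep", "hr"):
            raise ValueError(f"{self.name} requires phys_channel 'pep' or 'hr'")
        if not needs_phys and self.phys_channel != "none":
            raise ValueError(f"{self.name} takes no physiology channel")

    @property
    def param_names(self) -> tuple[str, ...]:
        return self._PARAM_NAMES[self.name]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def trial_rates(self, params: np.ndarray,
                    phys: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
        """Per-trial (α⁺, α⁻) arrays implied by ``params``.

        ``phys`` is the trial-wise covariate (required for the modulated
        variants, ignored otherwise).
        """
        params = np.asarray(params, dtype=float)
        if self.name == "symmetric":
            a = transform_rate(params[0])
            n = len(phys) if phys is not None else 1
            return np.full(n, a), np.full(n, a)
        if self.name == "asymmetric":
            n = len(phys) if phys is not None else 1
            return (np.full(n, transform_rate(params[0])),
                    np.full(n, transform_rate(params[1])))
        if phys is None:
            raise ValueError(f"{self.name} needs the '{self.phys_channel}' covariate")
        phys = np.asarray(phys, dtype=float)
        if self.name == "asym_phys_pos":
            ap = modulated_rate(params[0], params[1], phys)
            an = np.full(len(phys), transform_rate(params[2]))
            return ap, an
        ap = np.full(len(phys), transform_rate(params[0]))
        an = modulated_rate(params[1], params[2], phys)
        return ap, an

    def betas(self, params: np.ndarray) -> tuple[float, float]:
        return float(params[-2]), float(params[-1])

    def trial_rate_grads(self, params: np.ndarray, phys: np.ndarray | None,
                         n: int) -> tuple[np.ndarray, np.ndarray]:
        """Jacobians (n × d) of the per-trial (α⁺, α⁻) w.r.t. the parameters.

        dΦ(u)/du is the standard-normal density φ(u).
        """
        params = np.asarray(params, dtype=float)
        d = self.n_params
        dap = np.zeros((n, d))
        dan = np.zeros((n, d))
        if self.name == "symmetric":
            pdf = _npdf(params[0])
            dap[:, 0] = pdf
            dan[:, 0] = pdf
        elif self.name == "asymmetric":
            dap[:, 0] = _npdf(params[0])
            dan[:, 1] = _npdf(params[1])
        elif self.name == "asym_phys_pos":
            u = params[0] + params[1] * phys
            pdf = _npdf(u)
            dap[:, 0] = pdf
            dap[:, 1] = pdf * phys
            dan[:, 2] = _npdf(params[2])
        else:  # asym_phys_neg
            dap[:, 0] = _npdf(params[0])
            u = params[1] + params[2] * phys
            pdf = _npdf(u)
            dan[:, 1] = pdf
            dan[:, 2] = pdf * phys
        return dap, dan


MODEL_SPECS = {
    "symmetric": ModelSpec("symmetric"),
    "asymmetric": ModelSpec("asymmetric"),
    "asym_phys_pos_pep": ModelSpec("asym_phys_pos", "pep"),
    "asym_phys_neg_pep": ModelSpec("asym_phys_neg", "pep"),
    "asym_phys_pos_hr": ModelSpec("asym_phys_pos", "hr"),
    "asym_phys_neg_hr": ModelSpec("asym_phys_neg", "hr"),
}


def _npdf(u):
    return np.exp(-0.5 * np.square(u)) / np.sqrt(2.0 * np.pi)


def transform_rate(raw):
    """Map an unconstrained learning-rate parameter into (0, 1).

    The transform is the standard-normal CDF, Φ(x) = 0.5 + 0.5·erf(x/√2);
    it is monotone increasing with Φ(0) = 0.5.
    """
    return ndtr(raw)


def inverse_transform_rate(rate):
    """Unconstrained parameter whose transformed learning rate is ``rate``."""
    from scipy.special import ndtri

    return ndtri(rate)


def modulated_rate(b0, b1, phys):
    """Trial-wise learning rate Φ(b₀ + b₁·phys(t)) in (0, 1)."""
    return ndtr(b0 + b1 * np.asarray(phys, dtype=float))


def rho_step(rho: float, r_s: float, alpha_pos: float, alpha_neg: float,
             branch_on: str = "pe_sign") -> float:
    """One second of the delta rule: ρ ← ρ + α·δ with δ = r(s) − ρ.

    ``branch_on="pe_sign"`` (default) picks α⁺ when δ > 0 and α⁻ when δ < 0
    (no update at δ = 0).  ``branch_on="reward"`` picks α⁺ on reward seconds
    (r(s) > 0) and α⁻ otherwise; the two rules coincide whenever ρ stays
    below the smallest reward.
    """
    delta = r_s - rho
    if branch_on == "reward":
        alpha = alpha_pos if r_s > 0 else alpha_neg
    elif branch_on == "pe_sign":
        if delta == 0.0:
            return rho
        alpha = alpha_pos if delta > 0 else alpha_neg
    else:
        raise ValueError(f"unknown branch rule: {branch_on!r}")
    return rho + alpha * delta


def choice_prob(reward, delay, rho, beta0, beta1):
    """Softmax probability of capture given the subjective opportunity cost.

    P(capture) = 1 / (1 + exp(β₀ − β₁·(r − delay·ρ))), evaluated in a
    numerically stable form.
    """
    x = beta0 - beta1 * (np.asarray(reward, float) - np.asarray(delay, float) * rho)
    # 1/(1+e^x) = e^{-x}/(1+e^{-x}); stable via logaddexp
    return np.exp(-np.logaddexp(0.0, x))


@dataclass
class SessionArrays:
    """One subject's trials flattened into the arrays the likelihood consumes.

    ``pre_zero`` counts reward-free seconds before the decision (the 2-s
    approach); ``capture_zero`` the reward-free capture seconds that follow a
    (non-error) capture, i.e. capture cost − 1, with the final feedback
    second carrying the reward.  Error trials append ``penalty`` reward-free
    seconds and never deliver reward.
    """

    reward: np.ndarray        # invader reward on offer, points
    delay: np.ndarray         # invader capture cost, seconds
    action: np.ndarray        # 1 = capture, 0 = release (int8)
    error: np.ndarray         # 1 = error trial (int8)
    include: np.ndarray       # 1 = enters the likelihood sum (int8)
    pep: np.ndarray | None = None
    hr: np.ndarray | None = None
    approach_s: int = 2
    penalty_s: int = 8

    @classmethod
    def from_frame(cls, df: pd.DataFrame, pep_col: str = "pep_corrected",
                   hr_col: str = "hr_corrected") -> "SessionArrays":
        """Build from one subject's tidy trial table (in trial order)."""
        forced = df["forced"].to_numpy().astype(bool)
        error = df["error"].to_numpy().astype(bool)
        return cls(
            reward=df["reward"].to_numpy(dtype=float),
            delay=df["delay"].to_numpy(dtype=float),
            action=(df["action"].to_numpy() == "capture").astype(np.int8)
            if df["action"].dtype == object else df["action"].to_numpy(np.int8),
            error=error.astype(np.int8),
            include=(~forced & ~error).astype(np.int8),
            pep=df[pep_col].to_numpy(dtype=float) if pep_col in df else None,
            hr=df[hr_col].to_numpy(dtype=float) if hr_col in df else None,
        )

    @property
    def n_trials(self) -> int:
        return len(self.reward)

    def phys(self, channel: str) -> np.ndarray | None:
        if channel == "none":
            return None
        arr = getattr(self, channel)
        if arr is None:
            raise ValueError(f"session is missing the '{channel}' covariate")
        return arr


def _check_params(params) -> np.ndarray:
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite model parameters")
    return params


def nll_choices(session: SessionArrays, params, spec: ModelSpec,
                rho0: float, branch_on: str = "pe_sign") -> float:
    """Negative log-likelihood of the observed choice sequence.

    Runs the per-second ρ engine over the full session clock (approach,
    capture time carrying the reward on its final second, error penalties)
    and sums −log P(observed action) over free-choice, error-free trials.
    ρ is initialized at ``rho0`` — the realized experiment-wide average
    reward rate — and carried across the block break.
    """
    params = _check_params(params)
    phys = session.phys(spec.phys_channel)
    n = session.n_trials
    ap, an = spec.trial_rates(params, phys if phys is not None
                              else np.zeros(n))
    if len(ap) == 1 and n > 1:
        ap = np.full(n, ap[0])
        an = np.full(n, an[0])
    beta0, beta1 = spec.betas(params)
    nll, _ = _kernels.nll_kernel(
        session.reward, session.delay, session.action, session.error,
        session.include, ap, an, float(beta0), float(beta1), float(rho0),
        int(session.approach_s), int(session.penalty_s),
        branch_on == "reward")
    return float(nll)


def nll_and_grad(session: SessionArrays, params, spec: ModelSpec,
                 rho0: float, branch_on: str = "pe_sign"):
    """Negative log-likelihood and its analytic gradient (unconstrained scale).

    Same engine as :func:`nll_choices`, propagating ∂ρ/∂θ through the
    recursion; verified against finite differences in the test suite.
    """
    params = _check_params(params)
    phys = session.phys(spec.phys_channel)
    n = session.n_trials
    phys_arr = phys if phys is not None else np.zeros(n)
    ap, an = spec.trial_rates(params, phys_arr)
    if len(ap) == 1 and n > 1:
        ap = np.full(n, ap[0])
        an = np.full(n, an[0])
    dap, dan = spec.trial_rate_grads(params, phys_arr, n)
    beta0, beta1 = spec.betas(params)
    d = spec.n_params
    nll, grad = _kernels.nll_grad_kernel(
        session.reward, session.delay, session.action, session.error,
        session.include, ap, an, dap, dan, d - 2, d - 1,
        float(beta0), float(beta1), float(rho0),
        int(session.approach_s), int(session.penalty_s),
        branch_on == "reward")
    return float(nll), grad


def decision_rhos(session: SessionArrays, params, spec: ModelSpec,
                  rho0: float, branch_on: str = "pe_sign") -> np.ndarray:
    """Per-trial decision-time ρ (after the final approach-second update)."""
    params = _check_params(params)
    phys = session.phys(spec.phys_channel)
    n = session.n_trials
    ap, an = spec.trial_rates(params, phys if phys is not None else np.zeros(n))
    beta0, beta1 = spec.betas(params)
    _, rhos = _kernels.nll_kernel(
        session.reward, session.delay, session.action, session.error,
        session.include, ap, an, float(beta0), float(beta1), float(rho0),
        int(session.approach_s), int(session.penalty_s),
        branch_on == "reward")
    return rhos


def rho_trace(session: SessionArrays, params, spec: ModelSpec, rho0: float,
              branch_on: str = "pe_sign") -> pd.DataFrame:
    """Literal per-second ρ trajectory, one row per second of the session.

    Columns: ``trial`` (0-based), ``second`` (within the session clock),
    ``r_s`` (reward delivered that second), ``rho`` (value after the
    update), ``is_decision`` (final approach second of the trial).  The
    decision-time ρ values equal :func:`decision_rhos` exactly; the compiled
    likelihood kernel is tested against this loop.
    """
    params = _check_params(params)
    phys = session.phys(spec.phys_channel)
    n = session.n_trials
    ap, an = spec.trial_rates(params, phys if phys is not None else np.zeros(n))
    rows = []
    rho = float(rho0)
    sec = 0
    for t in range(n):
        r_i = session.reward[t]
        cost = int(session.delay[t])
        # seconds of this trial, each (r_s, is_decision)
        seconds: list[tuple[float, bool]] = []
        for a in range(session.approach_s):
            seconds.append((0.0, a == session.approach_s - 1))
        if session.error[t]:
            seconds += [(0.0, False)] * session.penalty_s
        elif session.action[t] == 1:
            seconds += [(0.0, False)] * (cost - 1) + [(float(r_i), False)]
        for r_s, is_dec in seconds:
            rho = rho_step(rho, r_s, ap[t], an[t], branch_on=branch_on)
            rows.append((t, sec, r_s, rho, is_dec))
            sec += 1
    return pd.DataFrame(rows, columns=["trial", "second", "r_s", "rho",
                                       "is_decision"])
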