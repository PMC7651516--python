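"""Independent brute-force oracles used by the test suite.

Deliberately written as a literal second-by-second loop over an explicit
reward schedule, sharing no code with the package's likelihood engine.
"""

import math

import numpy as np

from foragerl.models import ModelSpec, SessionArrays, transform_rate


def reward_schedule(session: SessionArrays):
    """Explicit per-trial list of (r(s) for every second, decision index)."""
    trials = []
    for t in range(session.n_trials):
        secs = [0.0] * int(session.approach_s)
        decision_idx = len(secs) - 1
        if session.error[t]:
            secs += [0.0] * int(session.penalty_s)
        elif session.action[t] == 1:
            cost = int(session.delay[t])
            secs += [0.0] * (cost - 1) + [float(session.reward[t])]
        trials.append((secs, decision_idx))
    return trials


def trial_alphas(spec: ModelSpec, params, phys, t):
    p = np.asarray(params, dtype=float)
    if spec.name == "symmetric":
        a = float(transform_rate(p[0]))
        return a, a
    if spec.name == "asymmetric":
        return float(transform_rate(p[0])), float(transform_rate(p[1]))
    if spec.name == "asym_phys_pos":
        return (float(transform_rate(p[0] + p[1] * phys[t])),
                float(transform_rate(p[2])))
    return (float(transform_rate(p[0])),
            float(transform_rate(p[1] + p[2] * phys[t])))


def nll_brute_force(session: SessionArrays, params, spec: ModelSpec,
                    rho0: float, branch_on: str = "pe_sign") -> float:
    """Literal per-second evaluation of the choice NLL."""
    p = np.asarray(params, dtype=float)
    beta0, beta1 = float(p[-2]), float(p[-1])
    phys = session.phys(spec.phys_channel)
    rho = float(rho0)
    nll = 0.0
    for t, (secs, dec_idx) in enumerate(reward_schedule(session)):
        ap, an = trial_alphas(spec, params, phys, t)
        for s_idx, r_s in enumerate(secs):
            delta = r_s - rho
            if branch_on == "reward":
                alpha = ap if r_s > 0 else an
                rho = rho + alpha * delta
            else:
                if delta > 0:
                    rho = rho + ap * delta
                elif delta < 0:
                    rho = rho + an * delta
            if s_idx == dec_idx and session.include[t] == 1:
                v = session.reward[t] - session.delay[t] * rho
                x = beta0 - beta1 * v
                # -log P(capture) = log(1+e^x); -log P(release) = log(1+e^-x)
                z = x if session.action[t] == 1 else -x
                nll += np.logaddexp(0.0, z)
    return nll


def make_session(reward, delay, action, error=None, forced=None,
                 pep=None, hr=None) -> SessionArrays:
    """Hand-construct a SessionArrays from plain lists."""
    n = len(reward)
    z = np.zeros(n, dtype=np.int8)
    error = z if error is None else np.asarray(error, dtype=np.int8)
    forced = z if forced is None else np.asarray(forced, dtype=np.int8)
    include = ((error == 0) & (forced == 0)).astype(np.int8)
    return SessionArrays(
        reward=np.asarray(reward, dtype=float),
        delay=np.asarray(delay, dtype=float),
        action=np.asarray(action, dtype=np.int8),
        error=error, include=include,
        pep=None if pep is None else np.asarray(pep, dtype=float),
        hr=None if hr is None else np.asarray(hr, dtype=float))
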