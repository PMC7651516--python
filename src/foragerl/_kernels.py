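"""Compiled likelihood kernel for the per-second reward-rate engine.

The delta rule runs on a one-second clock, but every reward-free second
updates ρ by ρ ← ρ(1−α⁻) (the prediction error is −ρ, which is negative
because ρ stays positive), so a run of k such seconds multiplies ρ by
(1−α⁻)^k.  Learning rates are constant within a trial, so the whole
per-second trajectory collapses to a handful of closed-form updates per
trial.  This file holds that exact collapsed recursion, compiled with
numba; the pure-Python per-second loop in :mod:`foragerl.models` is the
readable reference it is tested against.
"""

import numba
import numpy as np


@numba.njit(cache=False)
def nll_grad_kernel(reward, delay, action, error, include, alpha_pos,
                    alpha_neg, dap, dan, ib0, ib1, beta0, beta1, rho0,
                    approach_s, penalty_s, branch_on_reward):
    """(nll, gradient) w.r.t. the unconstrained parameter vector.

    ``dap``/``dan`` are (n_trials, d) Jacobians of the per-trial learning
    rates w.r.t. the parameters; ``ib0``/``ib1`` index β₀ and β₁.  The
    gradient propagates ∂ρ/∂θ through the same collapsed recursion as the
    value: decay steps ρ←ρc^k give g←gc^k − ρkc^{k−1}·∂α⁻/∂θ, reward steps
    ρ←ρ+α·δ give g←g(1−α)+δ·∂α/∂θ.
    """
    n = reward.shape[0]
    d = dap.shape[1]
    rho = rho0
    g = np.zeros(d)
    nll = 0.0
    grad = np.zeros(d)
    for t in range(n):
        an = alpha_neg[t]
        ap = alpha_pos[t]
        c = 1.0 - an
        fac = c ** approach_s
        dfac = approach_s * c ** (approach_s - 1)
        for j in range(d):
            g[j] = g[j] * fac - rho * dfac * dan[t, j]
        rho = rho * fac
        if include[t] == 1:
            v = reward[t] - delay[t] * rho
            x = beta0 - beta1 * v
            # stable sigmoid of x
            if x >= 0.0:
                ex = np.exp(-x) if x < 35.0 else 0.0
                sig = 1.0 / (1.0 + ex)
            else:
                ex = np.exp(x) if x > -35.0 else 0.0
                sig = ex / (1.0 + ex)
            if action[t] == 1:
                z = x
                w = sig            # d log(1+e^x)/dx
            else:
                z = -x
                w = sig - 1.0      # -d log(1+e^-x)/dx applied to dx
            if z > 35.0:
                nll += z
            else:
                nll += np.log1p(np.exp(z))
            for j in range(d):
                dx = beta1 * delay[t] * g[j]
                if j == ib0:
                    dx += 1.0
                if j == ib1:
                    dx -= v
                grad[j] += w * dx
        if error[t] == 1:
            fac = c ** penalty_s
            dfac = penalty_s * c ** (penalty_s - 1)
            for j in range(d):
                g[j] = g[j] * fac - rho * dfac * dan[t, j]
            rho = rho * fac
        elif action[t] == 1:
            k = int(delay[t]) - 1
            if k > 0:
                fac = c ** k
                dfac = k * c ** (k - 1)
                for j in range(d):
                    g[j] = g[j] * fac - rho * dfac * dan[t, j]
                rho = rho * fac
            dlt = reward[t] - rho
            use_pos = branch_on_reward or dlt > 0.0
            if use_pos:
                for j in range(d):
                    g[j] = g[j] * (1.0 - ap) + dlt * dap[t, j]
                rho = rho + ap * dlt
            elif dlt < 0.0:
                for j in range(d):
                    g[j] = g[j] * (1.0 - an) + dlt * dan[t, j]
                rho = rho + an * dlt
    return nll, grad


@numba.njit(cache=False)
def nll_kernel(reward, delay, action, error, include, alpha_pos, alpha_neg,
               beta0, beta1, rho0, approach_s, penalty_s, branch_on_reward):
    """Return (nll, decision_rho) for one subject's trial sequence.

    ``action``/``error``/``include`` are int8 arrays; ``alpha_pos``/
    ``alpha_neg`` are per-trial learning rates already mapped into (0, 1).
    """
    n = reward.shape[0]
    rho = rho0
    nll = 0.0
    rho_dec = np.empty(n)
    for t in range(n):
        an = alpha_neg[t]
        ap = alpha_pos[t]
        # reward-free approach seconds: delta = -rho uses the negative rate
        rho = rho * (1.0 - an) ** approach_s
        rho_dec[t] = rho
        if include[t] == 1:
            x = beta0 - beta1 * (reward[t] - delay[t] * rho)
            # -log P(capture) = log(1 + e^x); -log P(release) = log(1 + e^-x)
            if action[t] == 1:
                z = x
            else:
                z = -x
            if z > 35.0:
                nll += z
            else:
                nll += np.log1p(np.exp(z))
        if error[t] == 1:
            rho = rho * (1.0 - an) ** penalty_s
        elif action[t] == 1:
            k = int(delay[t]) - 1  # reward-free capture seconds
            if k > 0:
                rho = rho * (1.0 - an) ** k
            d = reward[t] - rho
            if branch_on_reward:
                rho = rho + ap * d
            elif d > 0.0:
                rho = rho + ap * d
            elif d < 0.0:
                rho = rho + an * d
    return nll, rho_dec
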