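"""Synthetic cohort generator: the study conditions as a simulator.

Simulates subjects playing the prey-selection task with choices produced by
the per-second delta-rule + softmax models, and emits trial-wise
physiological covariates (PEP, HR, respiration) with configurable
statistical couplings:

* a countercyclical PEP coupling — a habituating sympathetic-drive level
  recruited by novel deteriorations (and only deteriorations) of the
  reward rate, concentrating where richness is being (re)learned;
* an HR coupling — heart rate slows on captures of offers whose reward
  falls short of the current opportunity cost;
* an optional modulation of the negative learning rate by trial-wise PEP
  (use an ``asym_phys_neg`` generating model);
* a respiration leak into both channels, so that the respiration
  residualization step has something real to remove.

Physiology is generated at trial resolution (every in-scope analysis
consumes trial-window averages) on an arbitrary standardized scale; PEP is
emitted drive-signed (higher = more sympathetic drive).  All couplings act
on latent standardized deviations, which is what the within-subject
residualize-and-z-score preprocessing recovers up to noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measures import MU_INIT_DEFAULT, update_mu
from .models import ModelSpec, transform_rate
from .task import SessionPlan, draw_invader, make_session_plan

__all__ = [
    "GeneratorParams",
    "DEFAULT_GROUP_MEANS",
    "DEFAULT_GROUP_SDS",
    "gen_trial_physiology",
    "simulate_subject",
    "simulate_cohort",
]

# Group-level generating parameters (unconstrained scale).  Learning-rate
# means correspond to transformed rates alpha+ = 0.06, alpha- = 0.015 for the
# asymmetric family (norm.ppf of the rates) with softmax (beta0, beta1) =
# (-0.15, 0.13); the symmetric row uses its own fitted-scale convention
# (alpha = -2.49 -> 0.0064, beta0 = 1.80, beta1 = 0.15).  The modulation
# slope b1 = 0.5 raw-units per SD of drive is the package's documented
# choice for a behaviorally meaningful coupling.
DEFAULT_GROUP_MEANS = {
    "symmetric": np.array([-2.49, 1.80, 0.15]),
    "asymmetric": np.array([-1.5548, -2.1701, -0.15, 0.13]),
    "asym_phys_pos": np.array([-1.5548, 0.5, -2.1701, -0.15, 0.13]),
    "asym_phys_neg": np.array([-1.5548, -2.1701, 0.5, -0.15, 0.13]),
}
DEFAULT_GROUP_SDS = {
    "symmetric": np.array([0.5, 0.5, 0.04]),
    "asymmetric": np.array([0.5, 0.5, 0.5, 0.04]),
    "asym_phys_pos": np.array([0.5, 0.1, 0.5, 0.5, 0.04]),
    "asym_phys_neg": np.array([0.5, 0.5, 0.1, 0.5, 0.04]),
}


@dataclass
class GeneratorParams:
    """Cohort-level generating configuration.

    ``pep_deterioration_gain`` is the mean sympathetic reactivity (PEP
    units per unit of novelty-drive, see :func:`gen_trial_physiology`);
    ``pep_gain_subject_sd`` spreads that reactivity across subjects (draws
    are floored at zero).  ``hr_value_gain`` is the HR slowing (in HR
    units) on low-value captures.  ``error_rate`` of ``None`` defers to
    the session plan (default 0.018).
    """

    model: ModelSpec = field(default_factory=lambda: ModelSpec("asymmetric"))
    group_mean: np.ndarray | None = None
    group_sd: np.ndarray | None = None
    pep_deterioration_gain: float = 0.25
    pep_gain_subject_sd: float = 0.1875
    pep_phasic_decay: float = 0.93
    pep_objective_weight: float = 0.35
    pep_novelty_threshold: float = 1.0
    pep_novelty_cap: float = 5.0
    pep_adapt_decay: float = 0.98
    hr_value_gain: float = 0.5
    resp_leak_pep: float = 0.3
    resp_leak_hr: float = 0.3
    phys_noise_sd: float = 1.0
    phys_ar1: float = 0.3
    error_rate: float | None = None
    rho_init: float = MU_INIT_DEFAULT
    branch_on: str = "pe_sign"
    pep_drive_source: str = "subjective"  # or "objective" (couple to mu)

    def __post_init__(self):
        if self.group_mean is None:
            self.group_mean = DEFAULT_GROUP_MEANS[self.model.name].copy()
        if self.group_sd is None:
            self.group_sd = DEFAULT_GROUP_SDS[self.model.name].copy()
        self.group_mean = np.asarray(self.group_mean, dtype=float)
        self.group_sd = np.asarray(self.group_sd, dtype=float)
        if len(self.group_mean) != self.model.n_params:
            raise ValueError("group_mean length does not match model")
        if len(self.group_sd) != self.model.n_params:
            raise ValueError("group_sd length does not match model")
        if np.any(self.group_sd < 0):
            raise ValueError("group_sd must be non-negative")
        if not abs(self.phys_ar1) < 1:
            raise ValueError("phys_ar1 must lie in (-1, 1)")
        if self.phys_noise_sd <= 0:
            raise ValueError("phys_noise_sd must be positive")

    @property
    def phys_latent_sd(self) -> float:
        """Stationary SD of the latent AR(1)+leak physiology deviation."""
        ar_var = self.phys_noise_sd ** 2 / (1.0 - self.phys_ar1 ** 2)
        return math.sqrt(ar_var + self.resp_leak_pep ** 2)


def _relative_deterioration(drate, level):
    """max(0, −Δrate), Weber-scaled by the rate level when one is given."""
    if drate is None or not np.isfinite(drate):
        return 0.0
    det = max(0.0, -float(drate))
    if level is not None and level > 0:
        det /= level
    return det


def gen_trial_physiology(prev_state, dmu_dt, trial_value, captured,
                         gen: GeneratorParams, rng: np.random.Generator,
                         pep_gain: float | None = None,
                         mu: float | None = None, drive_input=None):
    """Emit one trial's (pep, hr, respiration) and the new latent state.

    ``prev_state`` is ``(pep_ar, hr_ar, drive, det_bar)`` — two AR(1)
    noise components, a sympathetic-drive level (decay
    ``pep_phasic_decay`` per trial), and a slow running average of the
    deterioration signal (decay ``pep_adapt_decay``).  Deteriorations are
    Weber-scaled (relative): ``max(0, -dmu_dt)/mu``, proportional losses
    of richness; NaN derivatives at block starts contribute nothing.
    When the cohort simulator supplies ``drive_input`` — the deterioration
    of the agent's *subjective* rate — the signal mixes the objective and
    subjective components with weight ``pep_objective_weight``.

    The drive is a habituating novelty response, scale-invariant by
    construction: it integrates the deterioration signal *relative to its
    own running average* — max(0, signal/det_bar − pep_novelty_threshold),
    capped at ``pep_novelty_cap`` — so a subject's overall deterioration
    scale (which depends on how fast they learn and where they are in the
    session) cancels out.  Richness collapses (an environment turning
    poor, the start of a session) recruit drive, while the steady trickle
    of reward-free seconds in a learned environment adapts away.
    Trial-to-trial PEP changes consequently track current (novel)
    deteriorations and are near-orthogonal to improvements.  The drive
    gain (``pep_gain``, the subject's sympathetic reactivity) varies
    across the cohort, and the drive is the component that modulates
    learning in the physiology-coupled models.

    Use ``(0.0, 0.0, 0.0, 0.0)`` at session start.  The HR coupling fires
    when a captured offer's objective value is negative.
    """
    pep_ar, hr_ar, drive, det_bar = prev_state
    gain = gen.pep_deterioration_gain if pep_gain is None else pep_gain
    resp = rng.normal(0.0, 1.0)
    pep_ar = gen.phys_ar1 * pep_ar + rng.normal(0.0, gen.phys_noise_sd)
    hr_ar = gen.phys_ar1 * hr_ar + rng.normal(0.0, gen.phys_noise_sd)
    det_now = _relative_deterioration(dmu_dt, mu)
    if drive_input is None:
        signal = det_now
    else:
        w = gen.pep_objective_weight
        signal = w * det_now \
            + (1.0 - w) * _relative_deterioration(*drive_input)
    novel = min(gen.pep_novelty_cap,
                max(0.0, signal / max(det_bar, 1e-4)
                    - gen.pep_novelty_threshold))
    det_bar = gen.pep_adapt_decay * det_bar \
        + (1.0 - gen.pep_adapt_decay) * signal
    drive = gen.pep_phasic_decay * drive + novel
    low_value_capture = bool(captured) and trial_value is not None \
        and trial_value < 0
    pep = pep_ar + gain * drive + gen.resp_leak_pep * resp
    hr = hr_ar - gen.hr_value_gain * float(low_value_capture) \
        + gen.resp_leak_hr * resp
    return pep, hr, resp, (pep_ar, hr_ar, drive, det_bar)


def simulate_subject(params, spec: ModelSpec, gen: GeneratorParams,
                     plan: SessionPlan, rng: np.random.Generator,
                     subject_id: int = 0,
                     pep_gain: float | None = None) -> pd.DataFrame:
    """Simulate one subject's full session as a tidy trial table.

    The per-second clock advances through the 2-s approach, capture time
    (with the reward on the final feedback second), and 8-s penalties on
    injected errors; ρ updates every second via the generating model and
    the choice is sampled from the softmax at the end of the approach.
    Forced trials sample the forced action uniformly and are flagged.  The
    objective rate μ updates on all trials (time and harvested reward are
    real).  Returns a DataFrame with ``attrs['pep_drive_signed'] = True``
    and ``attrs['realized_avg_reward_rate']``.
    """
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite generating parameters")
    if len(params) != spec.n_params:
        raise ValueError("parameter vector does not match model spec")
    beta0, beta1 = spec.betas(params)
    err_rate = plan.error_rate if gen.error_rate is None else gen.error_rate
    approach = int(plan.approach_s)
    penalty = int(plan.penalty_s)
    latent_sd = gen.phys_latent_sd

    rho = float(gen.rho_init)
    rho_onset_prev = None
    clock = 0.0
    total_reward = 0.0
    mu_prev = None
    onset_prev = None
    harvested_prev = 0.0
    phys_state = (0.0, 0.0, 0.0, 0.0)
    block1_mus: list[float] = []
    rows = []
    t = 0
    for b, env in enumerate(plan.blocks, start=1):
        block_start = clock
        first_of_block = True
        while clock - block_start < env.duration_s:
            t += 1
            onset = clock
            inv = draw_invader(env, rng)
            forced = rng.random() < plan.forced_fraction
            error = rng.random() < err_rate
            # objective reward rate at this trial's onset
            if t == 1:
                mu = float(gen.rho_init)
            elif first_of_block:
                mu = float(np.mean(block1_mus))
            else:
                mu = update_mu(mu_prev, onset_prev, onset, harvested_prev, 1)
            if b == 1:
                block1_mus.append(mu)
            dmu = np.nan if first_of_block else mu - mu_prev
            theta = inv.capture_cost_s * mu
            obj_value = inv.reward_points - theta

            # the integrated drive tracks deteriorations of the agent's own
            # (subjective) reward-rate estimate by default: it converges
            # within each environment, so drive transients concentrate where
            # learning happens; "objective" feeds it mu's deteriorations
            if gen.pep_drive_source == "subjective":
                drive_input = ((np.nan, None) if rho_onset_prev is None
                               else (rho - rho_onset_prev, rho_onset_prev))
            else:
                drive_input = (dmu, mu)
            rho_onset_prev = rho
            # learning rates for this trial (pep modulation uses the latent
            # standardized deviation, which preprocessing recovers)
            pep_pre, hr_pre, resp, new_state = gen_trial_physiology(
                phys_state, dmu, obj_value, False, gen, rng, pep_gain,
                mu=mu, drive_input=drive_input)
            if spec.phys_channel == "pep":
                phys_z = pep_pre / latent_sd
            elif spec.phys_channel == "hr":
                phys_z = hr_pre / latent_sd
            else:
                phys_z = 0.0
            ap, an = spec.trial_rates(params, np.array([phys_z]))
            ap, an = float(ap[0]), float(an[0])

            # approach seconds: reward-free, negative prediction errors
            rho *= (1.0 - an) ** approach
            p_capture = 1.0 / (1.0 + np.exp(
                np.clip(beta0 - beta1 * (inv.reward_points
                                         - inv.capture_cost_s * rho),
                        -500, 500)))
            if forced:
                capture = rng.random() < 0.5
            else:
                capture = rng.random() < p_capture

            if error:
                harvested = 0.0
                duration = approach + penalty
                rho *= (1.0 - an) ** penalty
            elif capture:
                harvested = inv.reward_points
                duration = approach + inv.capture_cost_s
                k = int(inv.capture_cost_s) - 1
                rho *= (1.0 - an) ** k
                delta = inv.reward_points - rho
                if gen.branch_on == "reward" or delta > 0:
                    rho += ap * delta
                elif delta < 0:
                    rho += an * delta
            else:
                harvested = 0.0
                duration = approach

            # HR's low-value coupling needs the realized action
            low_cap = capture and not error and obj_value < 0
            pep = pep_pre
            hr = hr_pre - gen.hr_value_gain * float(low_cap)
            phys_state = new_state

            rows.append({
                "subject_id": subject_id, "order": plan.order, "t": t,
                "block": b, "env": env.label, "type_id": inv.type_id,
                "reward": inv.reward_points, "delay": inv.capture_cost_s,
                "rank": inv.rank, "onset_s": onset, "forced": forced,
                "error": error,
                "action": "capture" if capture else "release",
                "reward_harvested": harvested, "pep": pep, "hr": hr,
                "respiration": resp,
            })
            total_reward += harvested
            clock = onset + duration
            mu_prev, onset_prev, harvested_prev = mu, onset, harvested
            first_of_block = False

    df = pd.DataFrame(rows)
    df.attrs["pep_drive_signed"] = True
    df.attrs["realized_avg_reward_rate"] = total_reward / clock
    df.attrs["total_elapsed_s"] = clock
    return df


def simulate_cohort(n_subjects: int, gen: GeneratorParams,
                    seed: int | np.random.SeedSequence,
                    plan_overrides: dict | None = None):
    """Simulate a cohort; returns ``(cohort_table, truth)``.

    Half the subjects forage boom-to-downturn (BD) and half downturn-to-boom
    (DB); odd counts round toward BD.  Subject parameters are drawn from the
    diagonal group Gaussian on the unconstrained scale.  ``truth`` records
    the seed, generating model, group parameters, and each subject's true
    parameter vector, sympathetic reactivity gain and realized reward rate —
    everything parameter-recovery tests need.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_subjects + 1)
    param_rng = np.random.Generator(np.random.PCG64(child_seeds[0]))
    n_bd = (n_subjects + 1) // 2
    frames = []
    truth_subjects = []
    for i in range(n_subjects):
        order = "BD" if i < n_bd else "DB"
        plan = make_session_plan(order, plan_overrides)
        params = param_rng.normal(gen.group_mean, gen.group_sd)
        pep_gain = max(0.0, param_rng.normal(gen.pep_deterioration_gain,
                                             gen.pep_gain_subject_sd))
        rng = np.random.Generator(np.random.PCG64(child_seeds[i + 1]))
        df = simulate_subject(params, gen.model, gen, plan, rng,
                              subject_id=i, pep_gain=pep_gain)
        frames.append(df)
        truth_subjects.append({
            "subject_id": i, "order": order,
            "params": params.tolist(), "pep_gain": pep_gain,
            "realized_avg_reward_rate": df.attrs["realized_avg_reward_rate"],
            "n_trials": len(df),
        })
    cohort = pd.concat(frames, ignore_index=True)
    cohort.attrs["pep_drive_signed"] = True
    truth = {
        "seed": ss.entropy, "model": gen.model.name,
        "phys_channel": gen.model.phys_channel,
        "group_mean": gen.group_mean.tolist(),
        "group_sd": gen.group_sd.tolist(),
        "param_names": list(gen.model.param_names),
        "transformed_group_rates": {
            name: float(transform_rate(m))
            for name, m in zip(gen.model.param_names, gen.group_mean)
            if "alpha" in name},
        "realized_cohort_rate": float(np.mean(
            [s["realized_avg_reward_rate"] for s in truth_subjects])),
        "subjects": truth_subjects,
    }
    return cohort, truth
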