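# Methods

`foragerl` implements a complete, simulation-backed analysis pipeline for a
time-constrained sequential prey-selection task: task design and synthetic
cohorts, objective reward-rate accounting, delta-rule learning models of the
subjective reward rate with a softmax choice policy, hierarchical EM fitting
with Laplace marginal likelihoods and subject-level LOOcv, and the
regression analyses that relate trial-wise cardiac state (PEP, HR) to
choices, reward-rate dynamics and optimal adaptation.

## The task

Subjects forage for 24 minutes split into two 720-s environments with
different mixtures of invader profitability (high : mid : low = 4:2:1 in the
rich *boom*, 1:2:4 in the poor *downturn*; half the subjects play
boom→downturn, half the reverse). Each invader offers 80 or 30 points at an
8-s or 3-s capture cost; the four reward×cost combinations collapse onto
three profitability ranks, with the two mixed combinations both *mid*.
Every trial begins with a 2-s approach during which the subject decides;
releases cost only those 2 s, captures add the capture cost (whose final
second is the 1-s reward feedback, so an "8-s cost" is 2 s approach + 7 s
capture + 1 s feedback). 25 % of trials are forced-choice, and errors
(rate 0.018) incur an 8-s timeout with no reward. Forced and error trials
are excluded from all likelihoods and regressions but still consume time
and harvest (or forfeit) reward.

## Objective reward-rate accounting

The objective reward rate at trial *t* is the running harvest average

  μ_t = (μ_{t−1}·s_{t−1} + r_{t−1}·c_{t−1}) / s_t,

with s_t the trial-onset time from session start, r the reward on offer and
c the capture indicator. Each offer's opportunity cost is θ_t = delay_t·μ_t
and its net value is value_t = reward_t − θ_t: the marginal-value rule says
capture exactly when value_t > 0. μ₁ is initialized at 7.97 points/s (a
cohort-scale average harvest rate); at the second block μ restarts at the
subject's block-1 mean.

Numerical conventions worth knowing:

* Because s₁ = 0, the literal update erases the initialization at trial 2
  (μ₂ = r₁c₁/s₂). The initialization is stated to prevent early trials
  from dominating, which the literal formula contradicts; both readings are
  supported via `prior_weight_s` (pseudo-elapsed seconds behind the prior),
  default 0 = the literal formula.
* Block-2 re-initialization options: `block1_mean` (default), `block1_final`,
  or `continue` (no re-init). Under `continue` the exact telescoping
  identity μ_T·s_T = Σ_{t<T} r_t·c_t holds to machine precision over the
  whole session; under the default it holds within block 1.
* Trial derivatives (dμ/dt, dPEP/dt, dHR/dt) are consecutive-trial first
  differences, reset (missing) at block starts.
* μ updates on forced and error trials too — their time and harvest are
  real.

## Learning models

The agent tracks a subjective rate ρ (points/s) with a delta rule applied
at every second of the session clock: δ(s) = r(s) − ρ(s), and
ρ ← ρ + α⁺δ for positive prediction errors, ρ ← ρ + α⁻δ for negative ones.
r(s) is zero on every second without reward — approach, capture time,
penalties — and equals the invader reward on the feedback second. ρ is
initialized at the realized session-average reward rate and carried across
the block break. Choices follow a softmax on the subjective net value,
P(capture) = 1/(1 + exp(β₀ − β₁(r − delay·ρ))), evaluated at the end of
the approach (after that second's update); negative β₀ biases toward
capture.

Four model variants: *symmetric* (α⁺ = α⁻ = α), *asymmetric* (separate
α⁺, α⁻), and two physiology-modulated forms where α⁺ or α⁻ follows the
trial's standardized cardiac covariate through α(t) = Φ(b₀ + b₁·phys(t)).
Raw learning-rate parameters are unconstrained; the transform to (0, 1) is
the standard-normal CDF Φ. The printed form of the asymmetric update
branches on the sign of r(s), which is never negative; we branch on the
sign of δ(s) (the reading consistent with "negative prediction errors every
second without reward"), with `branch_on="reward"` restoring the
r(s)-based rule (α⁺ on reward seconds); the two coincide while ρ stays
below the smallest reward.

Because every reward-free second multiplies ρ by (1 − α⁻) and rates are
constant within a trial, the per-second recursion collapses exactly to a
handful of per-trial updates; the compiled likelihood kernel uses this
closed form (with an analytic parameter gradient) and is tested against a
literal per-second loop to 1e−10. Nesting is exact: the asymmetric NLL at
α⁺ = α⁻ equals the symmetric NLL, and either modulated model at b₁ = 0
equals the asymmetric NLL.

## Hierarchical fitting, LOOcv, and the rate contrast

Subject parameters are draws from a diagonal Gaussian group prior on the
unconstrained scale. EM alternates per-subject MAP fits (multi-start
L-BFGS, 5 starts cold / warm-started thereafter) with moment-matching
M-steps whose variances include the Laplace posterior variances (guarding
against collapse; floor 1e−4). Subject evidence is the Laplace marginal
likelihood; subject Hessians are computed as PSD-floored likelihood
curvature plus the exact prior precision, which keeps posterior variances
finite at likelihood kinks. Because the Laplace approximation can produce
small evidence dips, iterations are accepted only if they do not lower the
summed evidence by more than the tolerance (1e−3): lowering E-steps are
retried with extra restarts and otherwise rejected, so the accepted
trajectory is non-decreasing by construction. Convergence: |Δevidence| <
1e−3, max 200 iterations.

LOOcv refits the group prior without each subject (warm-started from the
full fit, up to 6 inner iterations — enough because removing 1 of 20
subjects barely moves the prior) and scores the held-out subject by their
negative Laplace log marginal likelihood; summed scores compare models via
paired t-tests. The α⁺ − α⁻ contrast uses the covariance of the group
means Σ̂ = [Σᵢ (V̂⁻¹ − V̂⁻¹Hᵢ⁻¹V̂⁻¹)]⁻¹ — the Laplace information, in which a
flat-likelihood subject contributes nothing — with a one-tailed normal
test on cᵀm/√(cᵀΣ̂c).

## Regressions

Trial-wise models are ML logistic (choice) or linear (dμ/dt) regressions
with one fixed intercept per subject and shared slopes — the identifiable
fixed-effects form of a random-intercept model. Continuous predictors are
z-scored over the pooled free-choice, error-free trials; the dμ/dt model
runs in native units so that exactly linear constructions are recovered
exactly. Between-subject covariates (the block order) are perfectly
collinear with subject intercepts and are absorbed by them (flagged);
order remains identifiable in the across-subject optimality model.
Interaction models include all marginal terms. Coefficient stability is
summarized by leave-one-subject-out jackknife means and SDs. p-values are
Wald (logistic) or t-based (OLS); no multiple-testing correction.

Per-subject optimality metrics: D−B Mid is the downturn-minus-boom
difference in mid-rank capture proportion (free-choice, error-free
trials); D−B Drive is the same difference in mean standardized PEP or HR,
computed in the early (first half) and late (second half) window of each
environment (split at 360 s for 720-s blocks; a trial starting exactly at
the boundary is late). The optimality model is across-subject OLS of D−B
Mid on the two D−B Drive values per window.

## The synthetic cohort generator

The generator *is* the study conditions: 20 subjects (half BD, half DB),
720-s blocks, 25 % forced trials, 1.8 % errors, subject parameters from a
Gaussian on the unconstrained scale. Default generating means put the
transformed learning rates at α⁺ = 0.06, α⁻ = 0.015 with softmax
(β₀, β₁) = (−0.15, 0.13) for the asymmetric family; the symmetric
generator uses (α, β₀, β₁) = (−2.49, 1.80, 0.15) raw. Group SDs (0.5 on
raw rates and β₀, 0.04 on β₁) are moderate dispersions chosen once;
reported between-subject confidence intervals for the softmax bias imply
an implausibly wide spread driven by weak identification, so they were not
copied literally. The modulated generator uses b₁ = +0.5 raw-units per
drive-SD (stronger sympathetic drive → faster bad-news learning), group
SD 0.1.

Physiology is generated at trial resolution on an arbitrary standardized
scale (all analyses consume trial-window summaries; no waveforms). PEP is
emitted drive-signed (higher = more sympathetic drive; the sign flip that
real recordings need at ingestion is a separate, guarded step). Channels:

* **Respiration** is unit white noise, leaking (weight 0.3) into both
  cardiac channels so the per-subject residualization step has something
  real to remove.
* **PEP** = AR(1) noise (ρ = 0.3, innovation SD 1) + gᵢ·drive + leak.
  The *drive* is a habituating novelty response to reward-rate
  deterioration: the deterioration signal is the relative loss
  max(0, −Δrate)/rate (Weber scaling), mixing the objective rate μ
  (weight 0.35) with the agent's subjective ρ (weight 0.65); the drive
  integrates (decay 0.93/trial) the part of that signal exceeding its own
  slow running average (ratio threshold 1.0, response cap 5, adaptation
  decay 0.98). Scale-invariance is the point: a subject's overall
  deterioration scale — set by how fast they learn and by where they are
  in the session — cancels, so drive rises on genuine richness collapses
  (entering a poorer environment, the start of the session) and adapts
  away in a learned environment. The gain gᵢ ~ N(0.25, 0.1875²) floored
  at zero is the subject's sympathetic reactivity. This construction
  yields, simultaneously: trial-to-trial PEP changes that track current
  deteriorations and only deteriorations; drive concentrated in the
  early, learning-relevant part of each environment; and late windows
  carrying no subject-level signal. Simpler couplings fail at least one
  of these — an instantaneous term is mechanically anti-correlated with
  next-trial rebounds (spurious improvement-subset effects), and any
  non-normalized integrator leaves late-window levels proportional to
  subject factors that also predict adaptation.
* **HR** = AR(1) noise − 0.5·(captured low-value offer) + leak: heart
  rate slows on captures whose objective value is negative, producing the
  positive HR×value choice interaction. The gain is deliberately modest
  so the behavioral correlate does not reappear in the late-window
  optimality model.

In the physiology-modulated generating models, α⁻(t) is driven by the
latent standardized PEP (deviation over its stationary SD) — the quantity
that within-subject residualize-and-z-score preprocessing recovers up to
noise.

What the generator does **not** emulate: beat-level cardiac events and
waveform morphology, reaction times and vigor, posture/preload artefacts,
non-stationary noise, and any direct physiological influence on choices
other than through the modulated learning rate. Passing tests therefore
show that the pipeline recovers the couplings it targets under these
idealized conditions; they do not certify performance on real cardiac
recordings.

## Problem sizes and numerical choices

Recovery and model-selection checks run 10 replicate cohorts of 20
subjects with full-length sessions (~410 trials each under the default
generating parameters — the per-second delta rule equilibrates ρ well
above the realized harvest rate, so capture rates and hence trial
durations come out lower than a naive 4–6 s/trial estimate). Type-I
calibration uses 200 null-coupling cohorts of 6 subjects with 240-s
blocks — small on purpose, since calibration is about the distribution of
p-values, not power. Degenerate inputs are handled explicitly: constant
respiration skips residualization with a warning; missing mid-rank
encounters make D−B Mid NaN with a warning; perfect separation in
logistic fits is flagged with infinite-SE markers; collinear designs are
flagged rank-deficient. Determinism: every stochastic component derives
from a single seed through numpy `SeedSequence` spawning, and the full
pipeline is byte-reproducible (the run log with wall times is the only
exception).

## Known limitations

* The Laplace approximation underlies both the evidence and the LOOcv
  scores; no MCMC cross-check is provided.
* The group prior is diagonal; correlations between parameters (e.g.
  between β₀ and β₁) are not modelled.
* The EM accept/reject rule guarantees monotone accepted evidence but can
  settle one E-step early when approximation noise is large relative to
  the tolerance.
* The objective μ is a lifetime average, so block-2 re-convergence is
  slow by construction (gain ∝ 1/elapsed-time); analyses that depend on
  late-session μ dynamics inherit this.
* Subject-level LOOcv with per-fold refits is the unbiased reading of
  cross-validated marginal likelihoods; the cheaper score-under-full-prior
  variant is available behind `refit_per_fold=False` and is slightly
  optimistic.
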