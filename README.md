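# foragerl

Reward-rate learning and sympathetic physiology in sequential foraging.

`foragerl` is a simulation-backed analysis library for the prey-selection
task: a time-constrained foraging game in which serially approaching prey
offer a reward (80 or 30 points) at a time cost (8 or 3 s), and the only
decision is capture or release. The Marginal Value Theorem prescribes the
optimal policy — capture item *i* exactly when its reward exceeds the
opportunity cost of its handling time,

    r_i  ≥  delay_i · ρ,

where ρ is the environment's reward rate (points per second). The library
is built for researchers in computational cognitive neuroscience and
psychophysiology who want to study how that rate is *learned* — and how
learning couples to trial-wise cardiac indices of autonomic state
(pre-ejection period, PEP, drive-signed so higher = more sympathetic
contractility; and heart rate, HR).

Its core is a per-second delta-rule model of the subjective reward rate,

    δ(s) = r(s) − ρ(s),      ρ(s+1) = ρ(s) + α⁺·δ(s)  if δ(s) > 0
                             ρ(s+1) = ρ(s) + α⁻·δ(s)  if δ(s) < 0,

with a softmax choice rule P(capture) = 1/(1 + exp(β₀ − β₁(r_i −
delay_i·ρ))). Separate learning rates for good and bad news (α⁺ ≠ α⁻)
express the optimism bias seen in this task; two further variants let a
trial-wise physiological covariate modulate α⁺ or α⁻ through
α(t) = Φ(b₀ + b₁·phys(t)). Models are fitted hierarchically (EM with a
Gaussian group prior and Laplace marginal likelihoods) and compared by
subject-level leave-one-out cross-validation.

The package covers the full analysis chain:

* **`foragerl.task`** — task design constants, environment schedules
  (boom 4:2:1 vs downturn 1:2:4 profitability mixtures, 720 s each).
* **`foragerl.generate`** — a synthetic cohort generator: delta-rule
  choosers on a per-second clock plus trial-wise PEP/HR/respiration with
  configurable couplings (deterioration-driven sympathetic drive, HR
  slowing on low-value captures, respiration leak, optional PEP
  modulation of α⁻).
* **`foragerl.measures`** — objective reward-rate accounting (μ, the
  opportunity cost θ = delay·μ, net value), trial derivatives, physiology
  preprocessing (respiration residualization, within-subject
  standardization), and the per-subject downturn-minus-boom (D−B)
  optimality metrics.
* **`foragerl.models`** — the learning models and the compiled choice
  likelihood with analytic gradients.
* **`foragerl.fit`** — hierarchical EM, LOOcv, paired model comparison,
  and the α⁺ − α⁻ contrast test.
* **`foragerl.regress`** — trial-wise choice and dμ/dt regressions with
  per-subject intercepts and jackknife stability summaries, and the
  across-subject optimality model.
* **`foragerl.pipeline`** — a seeded, hash-stamped, byte-reproducible
  pipeline (`simulate → measure → fit → loocv → regress → report`), also
  exposed as a thin CLI (`foragerl all --seed 1 --outdir runs/demo`).

## A worked example

`examples/03_fit_models.py` simulates 20 subjects from the asymmetric
model (transformed α⁺ = 0.06, α⁻ = 0.015), fits the symmetric and
asymmetric models by hierarchical EM, and compares them:

```text
symmetric: summed LOOcv = 1421.12
asymmetric: summed LOOcv = 1153.82
paired t(19) = 5.08, p = 6.7e-05  (positive t: asymmetric fits held-out subjects better)

recovered learning rates: alpha+ = 0.0570, alpha- = 0.0139
generating values:        alpha+ = 0.0600, alpha- = 0.0150
learning bias alpha+ - alpha- (raw scale): 0.62, z = 3.97, one-tailed p = 0.000
```

LOOcv scores are summed held-out negative log marginal likelihoods (lower
= better): the asymmetric model wins decisively on data that contain a
learning asymmetry, the fitted group-level rates land near the generating
values, and the contrast test confirms α⁺ > α⁻ — good news moves the
reward-rate belief faster than bad news. The other example scripts walk
through cohort simulation and the order effect (`01`), objective
reward-rate accounting (`02`), the physiology regressions
(`04` — countercyclical, deterioration-specific PEP coupling; HR slowing
on low-value captures), and the optimality analysis (`05` — early-window
sympathetic engagement predicts adaptive mid-rank capture).

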