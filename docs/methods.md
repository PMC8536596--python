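# Methods

This note documents the models, conventions and numerical choices behind
`nnsurv`, and what the test suite does and does not establish.

## Discrete-time likelihood and the three heads

Time is partitioned as `0 = τ₀ < τ₁ < … < τ_m`; interval *j* is the
half-open set `(τⱼ₋₁, τⱼ]`. This single coordinate convention is used
everywhere (interval assignment, label rounding, interpolation), which makes
the interval index κ(t) unique and the event-rounding rule consistent.

For an individual with covariates *x*, observed time *t* and indicator *d*,
the censored likelihood contribution is `f(t|x)^d · S(t|x)^(1−d)`. The
package implements both parameterizations of this likelihood and a
continuous-time variant:

- **Logistic-Hazard.** The discrete hazard is `h_j = σ(φ_j(x))` and the mean
  negative log-likelihood is a binary cross-entropy over intervals
  `j = 1..κ(t)` against targets `y_j = 1{j = κ(t), d = 1}`.
- **PMF.** `f(τ_j|x)` is a softmax over the logits with a fixed extra zero
  logit whose probability is the mass of surviving past `τ_m`; an event
  contributes `−log σ_κ`, a censoring the log of the tail sum
  `Σ_{k>κ} σ_k`. Keeping the last logit fixed at zero (rather than free)
  follows the statistical convention for multinomial models.
- **PC-Hazard.** The continuous-time hazard is constant within each
  interval. The network outputs `η̃_j = softplus(φ_j)`, interpreted as the
  hazard integrated over interval *j*, so the cuts never enter the loss;
  the censored likelihood uses the exact fractional exposure
  `ρ(t) = (t − τ_{κ−1}) / Δτ_κ`. The constant `d·log Δτ_κ` term is dropped,
  so reported losses are comparable only within a fixed grid and may be
  negative.

Equivalence of the two discrete forms is not assumed: a test recomputes the
f/S form of the likelihood through the hazard→PMF chain from identical
hazards and checks agreement with the cross-entropy form to 1e-10 on random
instances.

**Numerical policy.** Every loss is evaluated directly from logits with
log-sigmoid (`log σ(z) = min(z,0) − log1p(exp(−|z|))`) and log-sum-exp
identities; probabilities are never materialized inside a logarithm.
Survival products are computed as `exp(Σ log(1−h))`. Softplus uses the
overflow-safe branch `max(φ,0) + log1p(exp(−|φ|))`, and its logarithm falls
back to φ itself below φ = −30 where `softplus(φ) ≈ exp(φ)`. Analytic
gradients of all three losses are verified against central finite
differences.

## Labels and rounding

`discretize_labels` supports two schemes, because the discrete and
continuous likelihoods need different conventions:

- `rounded` (Logistic-Hazard, PMF): an event in `(τⱼ₋₁, τⱼ]` is recorded at
  `τⱼ` (index *j*), a censoring at `τⱼ₋₁` (index *j−1*) — a censored
  individual is last *known* alive at the previous grid point, while an
  event is first *recorded* at the next one. A censoring exactly at a cut
  stays there (no down-rounding is needed; the time is already a grid
  point). Censorings falling at or below τ₁ get index 0 and contribute
  nothing to the likelihood; they are retained with zero loss so batch
  sizes stay stable.
- `interval` (PC-Hazard): the label is κ(t) of the unrounded time for
  events and censorings alike, with `frac = ρ(t)`, because the
  continuous-time likelihood uses the exact exposure. Using the rounded
  index here would misalign the fractional-exposure term with its interval.

Durations beyond `τ_m` (possible on held-out data) are clipped to `τ_m`
with a logged warning, preserving the event indicator; the models only
describe `T ≤ τ_m`, and constant extension is the conservative monotone
choice. For the same reason, survival evaluation beyond `τ_m` returns
`S(τ_m)`.

## Grids

Equidistant grids partition `[0, t_max]` uniformly. Kaplan–Meier quantile
grids place `τ_j` at the smallest observed time with `Ŝ(t) ≤ ζ_j`, where the
levels `ζ_j` descend from 1 to `Ŝ(t_max)` in equal steps — each interval
then carries (as nearly as ties allow) the same survival drop. Duplicate
cuts from steep drops are collapsed (logged) rather than rejected, and the
final cut is forced to the largest observed duration. A 1e-9 tolerance is
applied to the level comparison to absorb float round-off in the
product-limit values. Grids are always fitted on the training split only
and stored with the model.

Kaplan–Meier itself is implemented as the classical product-limit estimator
with the event-before-censoring tie rule (tied censored individuals count
as at risk). The censoring-distribution estimator G is the same computation
on flipped indicators, and IPCW weights use the left limit `G(t−)` at event
times (the standard Graf convention).

## Interpolation

`step` is the raw right-continuous discrete estimate. `cdi`
(constant-density) draws the chord between adjacent grid survival values —
piecewise-linear survival; `chi` (constant-hazard) interpolates
geometrically, `s₀·(s₁/s₀)^ρ` — piecewise-exponential survival. Both agree
with the stored values exactly at the cuts. When `s₁ = 0` the implied CHI
hazard is infinite and the value is 0 for any ρ > 0 (evaluated in log
space); when `s₀ = 0` the whole interval is 0. CHI applied to PC-Hazard
curves reproduces the PC-Hazard model exactly, which the tests assert to
1e-12; CDI dominates CHI inside intervals (chord above a convex
exponential).

## Metrics

The time-dependent concordance counts ordered pairs (i, j) with
`T_i < T_j, D_i = 1` (plus `T_i = T_j, D_i = 1, D_j = 0`: the event
precedes a tied censoring), credits `Ŝ(T_i|x_i) < Ŝ(T_i|x_j)` with 1 and
prediction ties with 0.5. The implementation is validated against a literal
double loop.

The integrated Brier score is a trapezoidal integral over an evaluation
grid (default 100 equidistant points between the smallest and largest
observed times) divided by the grid's span. Whether to average point values
or integrate is a convention; trapezoid-over-span is this package's choice
and is asserted only against itself. Terms with a zero IPCW denominator are
dropped with a logged warning.

Hyperparameter search (`grid_search`) selects by validation likelihood when
all candidates share one grid, and by validation IBS otherwise — negative
log-likelihoods are not comparable across grids of different granularity.

## Training

The backbone is an MLP with ReLU activations; each hidden block is Linear →
ReLU → (BatchNorm) → (Dropout), with a final linear map to the m logits.
Optimization is minibatch Adam (default batch 256, learning rate 5e-3) with
validation-loss early stopping (default patience 15 epochs); the parameters
of the best validation epoch are restored. This deliberately replaces
cyclic warm-restart schedules and learning-rate range tests with the
simplest protocol that trains these small networks reliably; a cyclic
schedule would be a straightforward extension. Runs are deterministic given
`random_state` in single-threaded NumPy: data order, initialization
(He-normal) and dropout masks all flow from one generator.

Zero hidden layers give a linear model; combined with an empty covariate
matrix this is a bias-only model, used as the closed-form test vehicle: the
bias-only Logistic-Hazard MLE is `h_j = d_j / r_j` (so its survival curve is
the Kaplan–Meier curve of the discretized data) and the bias-only PC-Hazard
MLE is `η̃_j = events_j / exposure_j`. Both recoveries are asserted to 1e-3.

Batch normalization is implemented (training statistics with running-mean
inference) but disabled in the default protocol: with these small synthetic
tabular inputs, early stopping selects an epoch within the first handful of
passes, where the momentum-smoothed running statistics still lag the batch
statistics, and the mismatch measurably degrades the restored model. The
flag remains available for larger data.

## The synthetic-data generator

Event times are drawn from per-step discrete hazards on 1000 equidistant
points over (0, 100]. The logit hazard is a softmax-weighted mixture of a
periodic component `γ₁ sin(γ₂[t+γ₃]) + γ₄`, a constant component `γ₅`, and
an accelerating component `γ₆·t − 10`; each of the nine γ-functions is an
affine map of its own block of five covariates (45 covariates total, iid
uniform(−1,1)). The default coefficients are frozen constants chosen so the
population exhibits early constant-hazard deaths, late accelerating deaths
and periodic humps, with a wide covariate-driven spread (the 5th–95th
percentile of individual survival at t = 50 spans roughly 0.26–0.85) and
the bulk of events inside the grid (~15% reach the end uncensored).
Censoring is an independent per-step Bernoulli with constant hazard;
the default rate 6.09e-4 was calibrated once by bisection to give 37%
censored observations on a 100,000-sample draw and then frozen. Everyone
still at risk at the last grid point is administratively censored there.

Sampling uses inverse-transform draws on the analytic survival curve, which
is distributionally identical to the sequential per-step Bernoulli walk
(the curve *is* the running product of the per-step survival factors) and
vectorizes; ties between event and censoring steps resolve in favour of the
event. A Monte-Carlo test checks 100,000 draws against the analytic truth
within three binomial standard errors, and the truth computation is checked
against a literal per-step loop to 1e-12.

What the generator does **not** emulate: real covariate distributions
(correlated, mixed-type, missing), covariate-dependent or informative
censoring, and ties arising from coarse measurement. Passing tests
demonstrate that the estimators recover a known data-generating process of
moderate complexity — not performance on any real clinical data.

## Problem sizes in the tests

The default suite fits networks of 2×64 hidden units on training sets of
3000 (10 replications for the grid-size comparison, m = 25 vs 250) with a
2000-individual uncensored test set, and uses 100,000 draws for the
Monte-Carlo consistency check; the whole suite runs in about a minute on
one CPU. These sizes were chosen as the smallest at which the studied
effects (covariate learning beating the marginal baseline; fine-grid
overfitting at n = 3000) are stable across seeds.

## Known limitations

- No left truncation, interval censoring or competing risks.
- No data-driven choice of the grid size m; it is a hyperparameter.
- The PC-Hazard loss omits the `d·log Δτ` constant (values not comparable
  across grids).
- The optimizer is plain Adam with a fixed learning rate; no cyclic
  schedules or learning-rate finders.
- The CLI's `experiment` resume logic assumes the spec itself is unchanged
  between invocations; it keys runs by configuration hash only.
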