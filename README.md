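# nnsurv

Neural network time-to-event prediction from right-censored survival data,
built on the discrete-time survival likelihood and a piecewise-constant-hazard
continuous-time model.

## The problem

Given covariates *x*, an observed time *t = min(T\*, C\*)* and an event
indicator *d = 1{T\* ≤ C\*}* for each individual, the goal is to predict the
conditional survival function *S(t | x) = P(T\* > t | x)*. Neural networks
are fully parametric, which makes discrete-time survival models a natural
fit: discretize the time axis into intervals `0 = τ₀ < τ₁ < … < τ_m`, let a
multilayer perceptron map *x* to one output per interval, and maximize the
exact right-censored likelihood.

`nnsurv` implements three heads over a shared MLP backbone:

- **`LogisticHazard`** — models the discrete hazard
  `h(τⱼ|x) = P(T* = τⱼ | T* > τⱼ₋₁, x)` through a sigmoid link,
  `h(τⱼ|x) = σ(φⱼ(x))`. The censored negative log-likelihood reduces to a
  binary cross-entropy over the intervals up to each observation, and
  `S(τⱼ|x) = ∏_{k≤j} (1 − h(τ_k|x))`.
- **`PMF`** — models the event-time probability mass function directly with a
  softmax over `(φ₁, …, φ_m, 0)`; the fixed zero logit carries the mass of
  surviving past `τ_m`, so survival beyond the grid is allowed. Censored
  individuals contribute the log of a tail sum.
- **`PCHazard`** — a continuous-time model whose hazard is constant within
  each interval. The network outputs the integrated interval hazards
  `η̃ⱼ(x) = softplus(φⱼ(x))`, the loss is the exact censored likelihood with
  the fractional exposure `ρ(t)` in the last interval, and survival is the
  exponential of minus the piecewise-linear cumulative hazard, defined at
  *every* time point.

Around the heads the package provides the supporting machinery the approach
needs in practice:

- **Discretization** (`make_equidistant_grid`, `make_km_quantile_grid`,
  `SurvivalDiscretizer`): equidistant cuts, or cuts placed at Kaplan–Meier
  quantiles so every interval carries the same drop in marginal survival.
  Events round up to the end of their interval, censorings round down to the
  end of the previous one.
- **Interpolation** (`eval_survival`): step, constant-density (piecewise
  linear) and constant-hazard (piecewise exponential) evaluation of discrete
  survival curves at arbitrary times.
- **Metrics** (`concordance_td`, `brier_score`, `integrated_brier_score`,
  `mse_true_survival`): Antolini's time-dependent concordance, the Graf
  IPCW Brier score and its trapezoidal integral, and mean squared error
  against a known truth for simulations.
- **A synthetic-data generator** (`SurvivalSimulator`) with analytic true
  survival curves: per-step hazards on a 1000-point grid over (0, 100],
  specified through a covariate-dependent mixture of periodic, constant and
  accelerating logit-hazard components (45 covariates, 9 affine functions of
  5 covariates each), plus constant-hazard censoring calibrated to ~37%.
- **Estimator API**: scikit-learn conventions (`fit(X, y)`,
  `get_params`/`set_params`, trailing-underscore fitted attributes), a
  `grid_search` helper that selects by validation likelihood on a shared
  grid and by integrated Brier score across grids, JSON model
  serialization, and a `nnsurv` CLI (`simulate`, `fit`, `predict`,
  `evaluate`, `experiment`).

The MLP backbone, its batch-norm/dropout layers, Adam, and the analytic
gradients of all three losses are implemented in NumPy inside the package;
losses are computed from logits via log-sigmoid / log-sum-exp identities
throughout.

## Worked example

```python
import numpy as np
from nnsurv import (SurvivalSimulator, SimConfig, LogisticHazard,
                    mse_true_survival, kaplan_meier)

sim = SurvivalSimulator()                       # calibrated ~37% censoring
train, _ = sim.sample(3000, seed=1, return_truth=False)
test, truth = SurvivalSimulator(SimConfig(censor_rate=0.0)).sample(2000, seed=2)

model = LogisticHazard(n_intervals=25, grid="km", random_state=0)
model.fit(train.covariates, (train.durations, train.events))
print(f"grid: m={model.grid_.m}, stopped at epoch {model.best_epoch_}, "
      f"validation loss {model.best_val_loss_:.4f}")

t = sim.config.fine_grid                        # 1000 points on (0, 100]
mse = mse_true_survival(model.predict_surv(test.covariates, t, scheme="chi"), truth)
km = kaplan_meier(train.durations, train.events)
mse_km = mse_true_survival(np.tile(km(t), (test.n, 1)), truth)
print(f"true-survival MSE: model {mse:.4f} vs Kaplan-Meier baseline {mse_km:.4f}")
```

Output:

```
grid: m=25, stopped at epoch 7, validation loss 2.3666
true-survival MSE: model 0.0186 vs Kaplan-Meier baseline 0.0293
```

The fitted model's interpolated survival curves track the simulator's
analytic truth substantially better than the covariate-free Kaplan–Meier
estimate: the covariates carry real signal and the network recovers part
of it.

The same pipeline from the shell:

```sh
nnsurv simulate --n 3000 --seed 1 --out train.csv --truth truth.csv
nnsurv fit --data train.csv --head pc-hazard --m 25 --out model.json
nnsurv evaluate --model model.json --data train.csv --truth truth.csv
```

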