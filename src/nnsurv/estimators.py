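"""Scikit-learn style estimators for the three survival heads.

:class:`LogisticHazard`, :class:`PMF` and :class:`PCHazard` share one MLP
backbone and training loop (minibatch Adam, validation-loss early stopping)
and differ only in their loss and in how logits become survival curves.
They follow the scikit-learn contract: hyperparameters in ``__init__``,
``fit(X, y)``, fitted attributes with trailing underscores,
``get_params``/``set_params`` via :class:`sklearn.base.BaseEstimator`.

The target ``y`` may be

* a structured array with an event field and a time field (the
  scikit-survival convention),
* a ``(n, 2)`` array with columns ``(duration, event)``, or
* a ``(durations, events)`` tuple.

The time grid is always fitted on the training portion only and stored as
``grid_`` so held-out data are transformed consistently.
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import ParameterGrid
from sklearn.utils.validation import check_array, check_is_fitted

from . import heads
from .data import censoring_kaplan_meier, check_durations_events
from .discretization import SurvivalDiscretizer, TimeGrid, discretize_labels
from .exceptions import ConfigurationError, ValidationError
from .interpolation import eval_survival
from .metrics import integrated_brier_score
from .network import MLP, Adam

__all__ = ["LogisticHazard", "PMF", "PCHazard", "grid_search", "extract_survival_target"]


def extract_survival_target(y):
    """Coerce any supported target format to ``(durations, events)``."""
    if isinstance(y, tuple) or (isinstance(y, list) and len(y) == 2):
        durations, events = y
    elif hasattr(y, "dtype") and getattr(y.dtype, "names", None):
        names = list(y.dtype.names)
        ev_name = next((n for n in names if n.lower() in ("event", "events", "status", "d")), names[0])
        t_name = next((n for n in names if n.lower() in ("time", "duration", "durations", "t")), names[-1])
        durations, events = y[t_name], y[ev_name]
    else:
        arr = np.asarray(y, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValidationError(
                "y must be a structured array, an (n, 2) array of "
                "(duration, event), or a (durations, events) tuple"
            )
        durations, events = arr[:, 0], arr[:, 1]
    return check_durations_events(durations, events)


class _BaseSurvivalNet(BaseEstimator):
    """Shared backbone; subclasses set the head-specific pieces."""

    _label_scheme = "rounded"
    _default_scheme = "step"

    def __init__(
        self,
        n_intervals: int = 25,
        grid: str | TimeGrid = "km",
        hidden_layers: int = 2,
        hidden_nodes: int = 64,
        dropout: float = 0.0,
        batch_norm: bool = False,
        batch_size: int = 256,
        learning_rate: float = 5e-3,
        max_epochs: int = 100,
        patience: int = 15,
        val_fraction: float = 0.2,
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.n_intervals = n_intervals
        self.grid = grid
        self.hidden_layers = hidden_layers
        self.hidden_nodes = hidden_nodes
        self.dropout = dropout
        self.batch_norm = batch_norm
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state
        self.verbose = verbose

    # -- head contract (overridden) ---------------------------------------

    def _loss(self, phi, labels) -> float:
        raise NotImplementedError

    def _loss_grad(self, phi, labels) -> np.ndarray:
        raise NotImplementedError

    def _curves(self, phi) -> heads.SurvivalCurves:
        raise NotImplementedError

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, validation_data=None):
        """Fit the network.

        Parameters
        ----------
        X : array-like of shape (n, q)
            Covariates; ``q = 0`` is allowed (bias-only model).
        y : survival target (see module docstring).
        validation_data : optional ``(X_val, y_val)``
            Explicit early-stopping split; when omitted, ``val_fraction`` of
            the rows is held out internally.
        """
        X = check_array(X, ensure_min_features=0, ensure_2d=True, dtype=float)
        durations, events = extract_survival_target(y)
        if X.shape[0] != durations.shape[0]:
            raise ValidationError("X and y must have the same number of rows")
        rng = np.random.default_rng(self.random_state)

        if validation_data is not None:
            X_tr, dur_tr, ev_tr = X, durations, events
            X_val = check_array(
                validation_data[0], ensure_min_features=0, ensure_2d=True, dtype=float
            )
            dur_val, ev_val = extract_survival_target(validation_data[1])
        else:
            if not 0 < self.val_fraction < 1:
                raise ConfigurationError("val_fraction must lie in (0, 1)")
            perm = rng.permutation(X.shape[0])
            n_val = int(round(self.val_fraction * X.shape[0]))
            if n_val == 0 or n_val == X.shape[0]:
                raise ConfigurationError(
                    f"validation split of {n_val} rows out of {X.shape[0]} is empty"
                )
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_tr, dur_tr, ev_tr = X[tr_idx], durations[tr_idx], events[tr_idx]
            X_val, dur_val, ev_val = X[val_idx], durations[val_idx], events[val_idx]

        if isinstance(self.grid, TimeGrid):
            self.grid_ = self.grid
        else:
            disc = SurvivalDiscretizer(self.n_intervals, grid=self.grid)
            self.grid_ = disc.fit(dur_tr, ev_tr).grid_
        labels_tr = discretize_labels(dur_tr, ev_tr, self.grid_, scheme=self._label_scheme)
        labels_val = discretize_labels(dur_val, ev_val, self.grid_, scheme=self._label_scheme)

        self.n_features_in_ = X.shape[1]
        net = MLP(
            n_in=X.shape[1],
            n_out=self.grid_.m,
            hidden_layers=self.hidden_layers,
            hidden_nodes=self.hidden_nodes,
            dropout=self.dropout,
            batch_norm=self.batch_norm,
            rng=rng,
        )
        opt = Adam(net.parameters(), lr=self.learning_rate)

        n_tr = X_tr.shape[0]
        batch = min(self.batch_size, n_tr)
        history = {"epoch": [], "train_loss": [], "val_loss": []}
        best_loss, best_state, best_epoch = np.inf, net.get_state(), -1
        for epoch in range(self.max_epochs):
            order = rng.permutation(n_tr)
            epoch_losses = []
            for b, start in enumerate(range(0, n_tr, batch)):
                idx = order[start : start + batch]
                phi, cache = net.forward(X_tr[idx], training=True)
                lab_b = labels_tr.subset(idx)
                if not np.isfinite(phi).all():
                    raise RuntimeError(
                        f"non-finite network output at epoch {epoch}, batch {b}; "
                        "try a lower learning rate"
                    )
                loss_b = self._loss(phi, lab_b)
                if not np.isfinite(loss_b):
                    raise RuntimeError(
                        f"non-finite training loss {loss_b} at epoch {epoch}, "
                        f"batch {b}; try a lower learning rate"
                    )
                grads = net.backward(self._loss_grad(phi, lab_b), cache)
                opt.step(grads)
                epoch_losses.append(loss_b)
            phi_val, _ = net.forward(X_val, training=False)
            val_loss = self._loss(phi_val, labels_val)
            history["epoch"].append(epoch)
            history["train_loss"].append(float(np.mean(epoch_losses)))
            history["val_loss"].append(val_loss)
            if self.verbose:
                print(f"epoch {epoch}: train {np.mean(epoch_losses):.5f} val {val_loss:.5f}")
            if val_loss < best_loss:
                best_loss, best_state, best_epoch = val_loss, net.get_state(), epoch
            elif epoch - best_epoch >= self.patience:
                break
        net.set_state(best_state)
        self.net_ = net
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = float(best_loss)
        self.history_ = pd.DataFrame(history)
        return self

    # -- prediction --------------------------------------------------------

    def predict_logits(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = check_array(X, ensure_min_features=0, ensure_2d=True, dtype=float)
        phi, _ = self.net_.forward(X, training=False)
        return phi

    def predict_surv(self, X, times=None, scheme: str | None = None):
        """Survival predictions.

        With ``times=None`` returns the discrete :class:`SurvivalCurves`
        over the fitted grid; otherwise an ``(n, len(times))`` array under
        the requested interpolation scheme (default per head).
        """
        curves = self._curves(self.predict_logits(X))
        if times is None:
            return curves
        return eval_survival(curves, times, scheme=scheme or self._default_scheme)

    def score(self, X, y) -> float:
        """Negative mean loss on ``(X, y)`` (higher is better)."""
        check_is_fitted(self, "net_")
        durations, events = extract_survival_target(y)
        labels = discretize_labels(durations, events, self.grid_, scheme=self._label_scheme)
        return -self._loss(self.predict_logits(X), labels)


class LogisticHazard(_BaseSurvivalNet):
    """Discrete-time hazard head: ``h_j = sigmoid(phi_j)``, binary
    cross-entropy likelihood, ``S(tau_j) = prod (1 - h_k)``."""

    _label_scheme = "rounded"
    _default_scheme = "step"

    def _loss(self, phi, labels):
        return heads.logistic_hazard_loss(phi, labels)

    def _loss_grad(self, phi, labels):
        return heads.logistic_hazard_loss_grad(phi, labels)

    def _curves(self, phi):
        return heads.surv_from_hazard(heads.hazard_from_logits(phi), self.grid_)

    def predict_hazard(self, X) -> np.ndarray:
        return heads.hazard_from_logits(self.predict_logits(X))


class PMF(_BaseSurvivalNet):
    """Probability-mass-function head: softmax over ``(phi, 0)`` with the
    fixed zero logit carrying the mass of surviving past ``tau_m``."""

    _label_scheme = "rounded"
    _default_scheme = "step"

    def _loss(self, phi, labels):
        return heads.pmf_loss(phi, labels)

    def _loss_grad(self, phi, labels):
        return heads.pmf_loss_grad(phi, labels)

    def _curves(self, phi):
        pmf, tail = heads.pmf_from_logits(phi)
        return heads.surv_from_pmf(pmf, tail, self.grid_)

    def predict_pmf(self, X):
        return heads.pmf_from_logits(self.predict_logits(X))


class PCHazard(_BaseSurvivalNet):
    """Continuous-time piecewise-constant-hazard head:
    ``eta_j = softplus(phi_j)`` is the hazard integrated over interval ``j``
    and predictions are exact at any time (piecewise-exponential survival)."""

    _label_scheme = "interval"
    _default_scheme = "chi"

    def _loss(self, phi, labels):
        return heads.pc_hazard_loss(phi, labels)

    def _loss_grad(self, phi, labels):
        return heads.pc_hazard_loss_grad(phi, labels)

    def _curves(self, phi):
        eta = heads.softplus_rates(phi)
        surv = np.hstack(
            [np.ones((phi.shape[0], 1)), np.exp(-np.cumsum(eta, axis=1))]
        )
        return heads.SurvivalCurves(self.grid_, surv)

    def predict_rates(self, X) -> np.ndarray:
        return heads.softplus_rates(self.predict_logits(X))

    def predict_surv(self, X, times=None, scheme: str | None = None):
        if times is None or scheme not in (None, "chi"):
            return super().predict_surv(X, times, scheme)
        # exact model evaluation (identical to CHI of the grid curves)
        eta = self.predict_rates(X)
        return heads.surv_pc_hazard(eta, self.grid_, times)


def grid_search(
    estimator: _BaseSurvivalNet,
    X,
    y,
    param_grid,
    validation_data=None,
    random_state: int | None = None,
    n_ibs_points: int = 100,
):
    """Exhaustive hyperparameter search with a shared validation split.

    Candidates are scored on the validation set by their negative
    log-likelihood when they all share one discretization grid
    (``n_intervals`` and ``grid``); otherwise likelihoods are not comparable
    across grids and the integrated Brier score (over ``n_ibs_points``
    equidistant times between the smallest and largest observed validation
    time) is used instead.

    Returns ``(best_model, leaderboard)``; the leaderboard is a DataFrame
    with one row per candidate, its scores, and a ``selected`` flag, plus
    ``leaderboard.attrs["selection_metric"]``.
    """
    candidates = list(ParameterGrid(param_grid)) if not isinstance(param_grid, list) else [
        p for sub in (ParameterGrid(g) for g in [param_grid]) for p in sub
    ]
    if not candidates:
        raise ConfigurationError("param_grid expands to zero candidates")

    X = check_array(X, ensure_min_features=0, ensure_2d=True, dtype=float)
    durations, events = extract_survival_target(y)
    rng = np.random.default_rng(random_state)
    if validation_data is None:
        frac = estimator.val_fraction
        perm = rng.permutation(X.shape[0])
        n_val = int(round(frac * X.shape[0]))
        if n_val == 0 or n_val == X.shape[0]:
            raise ConfigurationError("validation split is empty")
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        X_tr, dur_tr, ev_tr = X[tr_idx], durations[tr_idx], events[tr_idx]
        X_val, dur_val, ev_val = X[val_idx], durations[val_idx], events[val_idx]
    else:
        X_tr, dur_tr, ev_tr = X, durations, events
        X_val = check_array(validation_data[0], ensure_min_features=0, dtype=float)
        dur_val, ev_val = extract_survival_target(validation_data[1])

    def grid_signature(params):
        return (
            params.get("n_intervals", estimator.n_intervals),
            str(params.get("grid", estimator.grid)),
        )

    same_grid = len({grid_signature(p) for p in candidates}) == 1
    metric = "val_nll" if same_grid else "val_ibs"

    eval_times = np.linspace(dur_val.min(), dur_val.max(), n_ibs_points)
    censor_G = censoring_kaplan_meier(dur_val, ev_val)

    rows = []
    models = []
    for params in candidates:
        model = copy.deepcopy(estimator).set_params(**params)
        model.fit(X_tr, (dur_tr, ev_tr), validation_data=(X_val, (dur_val, ev_val)))
        val_nll = -model.score(X_val, (dur_val, ev_val))
        surv = model.predict_surv(X_val, eval_times, scheme=model._default_scheme)
        val_ibs = integrated_brier_score(eval_times, dur_val, ev_val, surv, censor_G)
        rows.append({**params, "val_nll": val_nll, "val_ibs": val_ibs})
        models.append(model)

    leaderboard = pd.DataFrame(rows)
    best_i = int(np.argmin(leaderboard[metric].to_numpy()))
    leaderboard["selected"] = [i == best_i for i in range(len(models))]
    leaderboard.attrs["selection_metric"] = metric
    return models[best_i], leaderboard
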