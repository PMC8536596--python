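"""JSON (de)serialization of fitted models.

The whole model -- head kind, hyperparameters, the fitted time grid, every
network array (including batch-norm running statistics) and the training
log -- is written as a single human-readable JSON document, so predictions
are reproducible without pickling.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import estimators
from .discretization import TimeGrid
from .exceptions import ConfigurationError
from .network import MLP

__all__ = ["save_model", "load_model"]

_HEADS = {
    "LogisticHazard": estimators.LogisticHazard,
    "PMF": estimators.PMF,
    "PCHazard": estimators.PCHazard,
}


def save_model(model, path) -> None:
    """Serialize a fitted estimator to a JSON file."""
    if not hasattr(model, "net_"):
        raise ConfigurationError("cannot save an unfitted model")
    params = model.get_params()
    if isinstance(params.get("grid"), TimeGrid):
        params["grid"] = {"cuts": params["grid"].to_list()}
    doc = {
        "head": type(model).__name__,
        "params": params,
        "grid_cuts": model.grid_.to_list(),
        "n_features_in": int(model.n_features_in_),
        "network": {
            "state": [arr.tolist() for arr in model.net_.get_state()],
        },
        "best_epoch": int(model.best_epoch_),
        "best_val_loss": float(model.best_val_loss_),
        "history": model.history_.to_dict(orient="list"),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path):
    """Reconstruct a fitted estimator from :func:`save_model` output."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("head") not in _HEADS:
        raise ConfigurationError(f"unknown model head {doc.get('head')!r} in {path!r}")
    params = doc["params"]
    if isinstance(params.get("grid"), dict):
        params["grid"] = TimeGrid(np.asarray(params["grid"]["cuts"]))
    model = _HEADS[doc["head"]](**params)
    model.grid_ = TimeGrid(np.asarray(doc["grid_cuts"]))
    model.n_features_in_ = doc["n_features_in"]
    net = MLP(
        n_in=model.n_features_in_,
        n_out=model.grid_.m,
        hidden_layers=model.hidden_layers,
        hidden_nodes=model.hidden_nodes,
        dropout=model.dropout,
        batch_norm=model.batch_norm,
        rng=np.random.default_rng(0),
    )
    net.set_state([np.asarray(a, dtype=float) for a in doc["network"]["state"]])
    model.net_ = net
    model.best_epoch_ = doc["best_epoch"]
    model.best_val_loss_ = doc["best_val_loss"]
    model.history_ = pd.DataFrame(doc["history"])
    return model
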