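"""A small NumPy multilayer perceptron with manual backpropagation.

The survival heads in this package need custom likelihood losses, so the
backbone is a self-contained MLP: per hidden block ``Linear -> ReLU ->
BatchNorm -> Dropout`` (batch norm and dropout optional), then a final
linear map to the ``m`` output logits.  Gradients are computed by hand and
parameters are updated with Adam.  Everything is driven by a
``numpy.random.Generator``, so runs are reproducible from a seed in
single-threaded mode.

Zero hidden layers gives a linear model ``phi = W x + b``; combined with an
empty covariate matrix (q = 0) this degenerates to a bias-only model, the
closed-form test vehicle for the maximum-likelihood recovery checks.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigurationError

__all__ = ["MLP", "Adam"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


def _he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


class MLP:
    """Multilayer perceptron with ReLU activations.

    Parameters
    ----------
    n_in, n_out : int
        Input (covariate) and output (logit) dimensions; ``n_in`` may be 0.
    hidden_layers : int
        Number of hidden layers (0 = linear/bias-only model).
    hidden_nodes : int
        Width of every hidden layer.
    dropout : float in [0, 1)
        Dropout probability after each hidden block (inverted dropout).
    batch_norm : bool
        Batch normalization after each ReLU, with running statistics for
        inference.
    rng : numpy.random.Generator
        Source of initialization and dropout randomness.
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        hidden_layers: int = 2,
        hidden_nodes: int = 32,
        dropout: float = 0.0,
        batch_norm: bool = True,
        rng: np.random.Generator | None = None,
    ):
        if hidden_layers < 0 or hidden_nodes < 1 or n_out < 1:
            raise ConfigurationError("invalid network dimensions")
        if not 0 <= dropout < 1:
            raise ConfigurationError("dropout must lie in [0, 1)")
        rng = rng if rng is not None else np.random.default_rng()
        self.n_in, self.n_out = n_in, n_out
        self.hidden_layers = hidden_layers
        self.hidden_nodes = hidden_nodes
        self.dropout = dropout
        self.batch_norm = batch_norm and hidden_layers > 0
        self.rng = rng

        dims = [n_in] + [hidden_nodes] * hidden_layers + [n_out]
        self.weights = [_he_init(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)]
        self.biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        if self.batch_norm:
            self.bn_gamma = [np.ones(hidden_nodes) for _ in range(hidden_layers)]
            self.bn_beta = [np.zeros(hidden_nodes) for _ in range(hidden_layers)]
            self.bn_rmean = [np.zeros(hidden_nodes) for _ in range(hidden_layers)]
            self.bn_rvar = [np.ones(hidden_nodes) for _ in range(hidden_layers)]
        else:
            self.bn_gamma = self.bn_beta = self.bn_rmean = self.bn_rvar = []

    # -- parameter plumbing ------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        """Trainable arrays, in a fixed order (views, not copies)."""
        return self.weights + self.biases + self.bn_gamma + self.bn_beta

    def get_state(self) -> list[np.ndarray]:
        """Copies of all arrays (incl. batch-norm running stats)."""
        return [p.copy() for p in self.parameters() + self.bn_rmean + self.bn_rvar]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters() + self.bn_rmean + self.bn_rvar, state):
            p[...] = s

    # -- forward / backward ------------------------------------------------

    def forward(self, X: np.ndarray, training: bool = False):
        """Compute logits; returns ``(phi, cache)`` where ``cache`` feeds
        :meth:`backward`."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cache = {"inputs": [], "relu": [], "bn": [], "drop": []}
        a = X
        for layer in range(self.hidden_layers):
            cache["inputs"].append(a)
            z = a @ self.weights[layer] + self.biases[layer]
            r = np.maximum(z, 0.0)
            cache["relu"].append(z > 0)
            if self.batch_norm:
                if training:
                    mu = r.mean(axis=0)
                    var = r.var(axis=0)
                    self.bn_rmean[layer][...] = (
                        _BN_MOMENTUM * self.bn_rmean[layer] + (1 - _BN_MOMENTUM) * mu
                    )
                    self.bn_rvar[layer][...] = (
                        _BN_MOMENTUM * self.bn_rvar[layer] + (1 - _BN_MOMENTUM) * var
                    )
                else:
                    mu, var = self.bn_rmean[layer], self.bn_rvar[layer]
                inv_std = 1.0 / np.sqrt(var + _BN_EPS)
                xhat = (r - mu) * inv_std
                cache["bn"].append((r, xhat, inv_std, training))
                a = self.bn_gamma[layer] * xhat + self.bn_beta[layer]
            else:
                cache["bn"].append(None)
                a = r
            if training and self.dropout > 0:
                mask = self.rng.random(a.shape) >= self.dropout
                a = a * mask / (1.0 - self.dropout)
                cache["drop"].append(mask)
            else:
                cache["drop"].append(None)
        cache["last_input"] = a
        phi = a @ self.weights[-1] + self.biases[-1]
        return phi, cache

    def backward(self, dphi: np.ndarray, cache) -> list[np.ndarray]:
        """Gradients of the scalar loss w.r.t. :meth:`parameters`, given
        ``d loss / d phi`` (already including the batch-mean factor)."""
        gW = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        gG = [None] * self.hidden_layers if self.batch_norm else []
        gB = [None] * self.hidden_layers if self.batch_norm else []

        a = cache["last_input"]
        gW[-1] = a.T @ dphi
        gb[-1] = dphi.sum(axis=0)
        da = dphi @ self.weights[-1].T

        for layer in range(self.hidden_layers - 1, -1, -1):
            mask = cache["drop"][layer]
            if mask is not None:
                da = da * mask / (1.0 - self.dropout)
            if self.batch_norm:
                r, xhat, inv_std, was_training = cache["bn"][layer]
                gG[layer] = (da * xhat).sum(axis=0)
                gB[layer] = da.sum(axis=0)
                dxhat = da * self.bn_gamma[layer]
                if was_training:
                    nb = r.shape[0]
                    dr = (
                        inv_std
                        / nb
                        * (
                            nb * dxhat
                            - dxhat.sum(axis=0)
                            - xhat * (dxhat * xhat).sum(axis=0)
                        )
                    )
                else:
                    dr = dxhat * inv_std
                da = dr
            dz = da * cache["relu"][layer]
            a_prev = cache["inputs"][layer]
            gW[layer] = a_prev.T @ dz
            gb[layer] = dz.sum(axis=0)
            da = dz @ self.weights[layer].T
        return gW + gb + gG + gB


class Adam:
    """Adam optimizer over a fixed list of parameter arrays (in-place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g**2
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
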