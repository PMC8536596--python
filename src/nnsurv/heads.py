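"""Output heads for discrete-time and piecewise-constant-hazard survival nets.

A network produces unbounded logits ``phi(x)`` with one column per grid
interval.  Three heads turn those logits into a survival model:

* **Logistic-Hazard** -- ``h_j = sigmoid(phi_j)`` is the discrete hazard; the
  loss is the right-censored negative log-likelihood, which reduces to a
  binary cross-entropy over the intervals up to each individual's label
  index, and ``S(tau_j) = prod_{k<=j} (1 - h_k)``.
* **PMF** -- a softmax over ``(phi_1, ..., phi_m, 0)`` (the fixed zero logit
  is the mass of surviving past ``tau_m``) gives the event-time probability
  mass function; the loss is the censored negative log-likelihood with a
  tail sum for censored individuals.
* **PC-Hazard** -- ``softplus(phi_j)`` is the integrated hazard
  ``eta_j * delta_j`` of a continuous-time model whose hazard is constant
  within each interval; the loss is the exact censored likelihood with the
  fractional exposure ``rho(t)`` in the last interval.  The constant
  ``d_i * log(delta_kappa)`` term is dropped (it does not depend on the
  parameters), so reported loss values are comparable only within one grid
  and the loss may be negative.

Every loss is evaluated directly from logits through log-sigmoid /
log-sum-exp identities -- probabilities are never materialised inside a
logarithm -- and each ``*_loss`` has a matching ``*_loss_grad`` returning
``d(mean loss)/d(phi)``, used by the NumPy training loop.  Individuals with
label index 0 (censored at or before ``tau_1`` under the rounding rule)
contribute zero loss and zero gradient but stay in the batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

from .discretization import DiscreteLabels, TimeGrid, assign_interval
from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "SurvivalCurves",
    "hazard_from_logits",
    "surv_from_hazard",
    "logistic_hazard_loss",
    "logistic_hazard_loss_grad",
    "pmf_from_logits",
    "surv_from_pmf",
    "pmf_loss",
    "pmf_loss_grad",
    "softplus_rates",
    "pc_hazard_loss",
    "pc_hazard_loss_grad",
    "surv_pc_hazard",
]


@dataclass
class SurvivalCurves:
    """Per-individual survival probabilities over a grid.

    ``surv`` has shape (n, m+1); column ``j`` is ``S(tau_j | x_i)`` with
    ``S(tau_0) = 1``.  Rows are nonincreasing and lie in [0, 1].
    """

    grid: TimeGrid
    surv: np.ndarray

    def __post_init__(self):
        self.surv = np.asarray(self.surv, dtype=float)
        if self.surv.ndim != 2 or self.surv.shape[1] != self.grid.m + 1:
            raise ValidationError(
                f"surv must have shape (n, m+1)=(n, {self.grid.m + 1}), "
                f"got {self.surv.shape}"
            )
        if not np.allclose(self.surv[:, 0], 1.0, atol=1e-12):
            raise ValidationError("survival at tau_0 must equal 1")
        if ((self.surv < -1e-12) | (self.surv > 1 + 1e-12)).any():
            raise ValidationError("survival values must lie in [0, 1]")
        if (np.diff(self.surv, axis=1) > 1e-9).any():
            raise ValidationError("survival rows must be nonincreasing")

    @property
    def n(self) -> int:
        return self.surv.shape[0]


def _check_labels(phi: np.ndarray, labels: DiscreteLabels) -> np.ndarray:
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    if not np.isfinite(phi).all():
        raise ValidationError("logits must be finite")
    if phi.shape[1] != labels.m:
        raise ConfigurationError(
            f"logits have {phi.shape[1]} columns but labels were built for m={labels.m}"
        )
    if phi.shape[0] != labels.n:
        raise ValidationError(
            f"logits have {phi.shape[0]} rows but labels have n={labels.n}"
        )
    return phi


def _log_sigmoid(z: np.ndarray) -> np.ndarray:
    # log(expit(z)) = -softplus(-z), overflow-safe
    return np.minimum(z, 0.0) - np.log1p(np.exp(-np.abs(z)))


# ---------------------------------------------------------------------------
# Logistic-Hazard


def hazard_from_logits(phi) -> np.ndarray:
    """Discrete hazards ``h_j = sigmoid(phi_j)`` elementwise."""
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    if not np.isfinite(phi).all():
        raise ValidationError("logits must be finite")
    return expit(phi)


def surv_from_hazard(hazard, grid: TimeGrid | None = None) -> np.ndarray | SurvivalCurves:
    """Survival ``S(tau_j) = prod_{k<=j} (1 - h_k)``, computed in log space,
    with ``S(tau_0) = 1`` prepended.

    Returns a plain array of shape (n, m+1), or a :class:`SurvivalCurves`
    when a grid is supplied.
    """
    hazard = np.atleast_2d(np.asarray(hazard, dtype=float))
    if ((hazard < 0) | (hazard > 1)).any():
        raise ValidationError("hazards must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        log_surv = np.cumsum(np.log1p(-hazard), axis=1)
    surv = np.hstack([np.ones((hazard.shape[0], 1)), np.exp(log_surv)])
    if grid is None:
        return surv
    return SurvivalCurves(grid, surv)


def logistic_hazard_loss(phi, labels: DiscreteLabels) -> float:
    """Mean negative log-likelihood of the discrete hazard parameterization.

    For individual ``i`` with label index ``kappa_i`` the contribution is the
    binary cross-entropy over intervals ``j = 1..kappa_i`` against targets
    ``y_ij = 1{j = kappa_i, d_i = 1}``.
    """
    phi = _check_labels(phi, labels)
    cols = np.arange(1, labels.m + 1)
    mask = cols[None, :] <= labels.idx[:, None]
    y = (cols[None, :] == labels.idx[:, None]) & (labels.events[:, None] == 1)
    ll = np.where(y, _log_sigmoid(phi), _log_sigmoid(-phi))
    return float(-np.sum(ll * mask) / labels.n)


def logistic_hazard_loss_grad(phi, labels: DiscreteLabels) -> np.ndarray:
    """Gradient of :func:`logistic_hazard_loss` w.r.t. ``phi``."""
    phi = _check_labels(phi, labels)
    cols = np.arange(1, labels.m + 1)
    mask = cols[None, :] <= labels.idx[:, None]
    y = (cols[None, :] == labels.idx[:, None]) & (labels.events[:, None] == 1)
    return mask * (expit(phi) - y) / labels.n


# ---------------------------------------------------------------------------
# PMF


def pmf_from_logits(phi) -> tuple[np.ndarray, np.ndarray]:
    """Event-time PMF and tail mass from logits.

    ``f(tau_j) = exp(phi_j) / (1 + sum_k exp(phi_k))`` and the tail
    ``S(tau_m) = 1 / (1 + sum_k exp(phi_k))``, i.e. a softmax over the
    logits with a fixed extra zero.  Rows of ``(pmf, tail)`` sum to 1.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    if not np.isfinite(phi).all():
        raise ValidationError("logits must be finite")
    z = np.hstack([phi, np.zeros((phi.shape[0], 1))])
    log_z = logsumexp(z, axis=1, keepdims=True)
    soft = np.exp(z - log_z)
    return soft[:, :-1], soft[:, -1]


def surv_from_pmf(pmf, tail, grid: TimeGrid | None = None) -> np.ndarray | SurvivalCurves:
    """Survival from a PMF: ``S(tau_j) = sum_{k>j} f(tau_k) + tail``."""
    pmf = np.atleast_2d(np.asarray(pmf, dtype=float))
    tail = np.asarray(tail, dtype=float).ravel()
    total = pmf.sum(axis=1) + tail
    if not np.allclose(total, 1.0, atol=1e-9):
        raise ValidationError("rows of (pmf, tail) must sum to 1")
    n, m = pmf.shape
    rev_cum = np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1]  # inclusive suffix sums
    beyond = np.hstack([rev_cum[:, 1:], np.zeros((n, 1))])
    surv = np.hstack([np.ones((n, 1)), np.clip(beyond + tail[:, None], 0.0, 1.0)])
    # float round-off can leave ~1e-16 upticks; project onto monotone curves
    surv = np.minimum.accumulate(surv, axis=1)
    if grid is None:
        return surv
    return SurvivalCurves(grid, surv)


def pmf_loss(phi, labels: DiscreteLabels) -> float:
    """Mean negative log-likelihood of the PMF parameterization.

    Events contribute ``-log sigma_kappa``; censored individuals contribute
    ``-log sum_{k>kappa}^{m+1} sigma_k`` where ``sigma`` is the softmax of
    ``(phi, 0)``.  Censored labels with ``kappa = 0`` contribute 0.
    """
    phi = _check_labels(phi, labels)
    if ((labels.events == 1) & (labels.idx == 0)).any():
        raise ValidationError("an event label with idx=0 is invalid for the PMF loss")
    n, m = phi.shape
    z = np.hstack([phi, np.zeros((n, 1))])
    log_z = logsumexp(z, axis=1)
    is_event = labels.events == 1
    ll = np.zeros(n)
    if is_event.any():
        ll[is_event] = z[is_event, labels.idx[is_event] - 1] - log_z[is_event]
    cens = ~is_event
    if cens.any():
        # tail over extended columns c >= kappa (0-based c maps to k = c+1)
        cols = np.arange(m + 1)
        tail_mask = cols[None, :] >= labels.idx[cens, None]
        z_c = np.where(tail_mask, z[cens], -np.inf)
        ll[cens] = logsumexp(z_c, axis=1) - log_z[cens]
    return float(-ll.mean())


def pmf_loss_grad(phi, labels: DiscreteLabels) -> np.ndarray:
    """Gradient of :func:`pmf_loss` w.r.t. ``phi`` (the fixed zero logit has
    no gradient)."""
    phi = _check_labels(phi, labels)
    n, m = phi.shape
    z = np.hstack([phi, np.zeros((n, 1))])
    log_z = logsumexp(z, axis=1, keepdims=True)
    sigma = np.exp(z - log_z)
    grad = sigma[:, :m].copy()
    is_event = labels.events == 1
    rows = np.arange(n)
    if is_event.any():
        grad[rows[is_event], labels.idx[is_event] - 1] -= 1.0
    cens = ~is_event
    if cens.any():
        cols = np.arange(m + 1)
        tail_mask = cols[None, :] >= labels.idx[cens, None]
        z_c = np.where(tail_mask, z[cens], -np.inf)
        log_tail = logsumexp(z_c, axis=1, keepdims=True)
        # d(-log P_tail)/dphi_c = sigma_c - 1{c in tail} * exp(z_c - log_tail)
        grad[cens] -= np.where(tail_mask[:, :m], np.exp(z[cens, :m] - log_tail), 0.0)
    return grad / n


# ---------------------------------------------------------------------------
# PC-Hazard


def softplus_rates(phi) -> np.ndarray:
    """Integrated interval hazards ``eta_tilde_j = log(1 + exp(phi_j))``,
    via the overflow-safe branch ``max(phi, 0) + log1p(exp(-|phi|))``."""
    phi = np.asarray(phi, dtype=float)
    if not np.isfinite(phi).all():
        raise ValidationError("logits must be finite")
    return np.maximum(phi, 0.0) + np.log1p(np.exp(-np.abs(phi)))


def _log_softplus(phi: np.ndarray) -> np.ndarray:
    # log(softplus(phi)); for very negative phi, softplus(phi) ~ exp(phi)
    out = np.where(phi < -30, phi, np.log(np.maximum(softplus_rates(phi), 1e-300)))
    return out


def pc_hazard_loss(phi, labels: DiscreteLabels) -> float:
    """Mean negative log-likelihood of the piecewise-constant-hazard model
    (up to the data-constant ``d_i log(delta_kappa)`` term).

    Contribution of individual ``i`` with interval index ``kappa_i`` and
    fraction ``rho_i``::

        -[ d_i log eta_kappa - eta_kappa * rho_i - sum_{j < kappa} eta_j ]

    ``kappa = 0`` (censored before any exposure) contributes 0.  May be
    negative because of the dropped constant.
    """
    phi = _check_labels(phi, labels)
    if ((labels.events == 1) & (labels.idx == 0)).any():
        raise ValidationError("an event label must have idx >= 1 for PC-Hazard")
    eta = softplus_rates(phi)
    n, m = phi.shape
    rows = np.arange(n)
    active = labels.idx >= 1
    k = np.clip(labels.idx - 1, 0, m - 1)  # 0-based column of interval kappa
    cum = np.cumsum(eta, axis=1)
    prev = np.where(labels.idx >= 2, cum[rows, np.clip(labels.idx - 2, 0, m - 1)], 0.0)
    log_eta_k = _log_softplus(phi[rows, k])
    contrib = (
        labels.events * log_eta_k - eta[rows, k] * labels.frac - prev
    )
    return float(-(contrib * active).sum() / n)


def pc_hazard_loss_grad(phi, labels: DiscreteLabels) -> np.ndarray:
    """Gradient of :func:`pc_hazard_loss` w.r.t. ``phi``."""
    phi = _check_labels(phi, labels)
    eta = softplus_rates(phi)
    n, m = phi.shape
    rows = np.arange(n)
    cols = np.arange(1, m + 1)
    # d loss / d eta
    d_eta = (cols[None, :] < labels.idx[:, None]).astype(float)  # j < kappa: +1
    k = np.clip(labels.idx - 1, 0, m - 1)
    active = labels.idx >= 1
    # at j = kappa: rho - d / eta_kappa   (ratio sigmoid/softplus -> 1 as phi -> -inf)
    phi_k = phi[rows, k]
    ratio = np.where(phi_k < -30, 1.0, expit(phi_k) / np.maximum(eta[rows, k], 1e-300))
    d_eta[rows, k] = np.where(active, labels.frac, 0.0)
    grad = d_eta * expit(phi)
    grad[rows, k] -= np.where(active, labels.events * ratio, 0.0)
    return grad / n


def surv_pc_hazard(eta_tilde, grid: TimeGrid, t) -> np.ndarray:
    """Survival of the piecewise-constant-hazard model at arbitrary times.

    ``S(t|x) = exp(-eta_kappa * rho(t)) * prod_{j<kappa} exp(-eta_j)`` --
    the exponential of minus the piecewise-linear cumulative hazard.  Times
    beyond ``tau_m`` return ``S(tau_m)`` (constant extension).

    Returns an array of shape ``(n, len(t))``.
    """
    eta = np.atleast_2d(np.asarray(eta_tilde, dtype=float))
    if (eta < 0).any():
        raise ValidationError("eta_tilde must be nonnegative")
    if eta.shape[1] != grid.m:
        raise ConfigurationError(
            f"eta_tilde has {eta.shape[1]} columns but the grid has m={grid.m}"
        )
    t = np.atleast_1d(np.asarray(t, dtype=float))
    kappa, rho = assign_interval(t, grid, clip=True)
    cum = np.hstack([np.zeros((eta.shape[0], 1)), np.cumsum(eta, axis=1)])
    # H(t) = cum[:, kappa-1] + eta[:, kappa-1] * rho
    H = cum[:, kappa - 1] + eta[:, kappa - 1] * rho[None, :]
    return np.exp(-H)
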