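"""Evaluation statistics for survival predictions.

* :func:`mse_true_survival` -- mean squared error against a known true
  survival function (simulation studies only).
* :func:`concordance_td` -- Antolini's time-dependent concordance: the
  probability that, of two comparable individuals, the one with the earlier
  event has the lower predicted survival at that event time.  Comparable
  pairs are ``(i, j)`` with ``T_i < T_j`` and ``D_i = 1``, plus tied-time
  pairs ``T_i = T_j`` with ``D_i = 1, D_j = 0`` (the event precedes the tied
  censoring).  Prediction ties are credited 0.5.
* :func:`brier_score` / :func:`integrated_brier_score` -- the Graf Brier
  score with inverse-probability-of-censoring weights (IPCW); the censoring
  survival ``G`` is evaluated with a left limit at event times, and the
  integrated score is the trapezoidal integral over an evaluation grid
  divided by the grid's time span.
"""

from __future__ import annotations

import logging

import numpy as np

from .data import StepEstimate, check_durations_events
from .exceptions import ValidationError

__all__ = [
    "mse_true_survival",
    "concordance_td",
    "brier_score",
    "integrated_brier_score",
]

logger = logging.getLogger(__name__)


def mse_true_survival(est, truth) -> float:
    """Mean over individuals of the mean over time points of squared error
    between estimated and true survival curves (same evaluation grid)."""
    est = np.atleast_2d(np.asarray(est, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if est.shape != truth.shape:
        raise ValidationError(
            f"estimate shape {est.shape} does not match truth shape {truth.shape}"
        )
    return float(np.mean((est - truth) ** 2))


def concordance_td(durations, events, surv_at_event_times) -> float:
    """Time-dependent concordance from a matrix of survival evaluations.

    Parameters
    ----------
    durations, events : array-like of shape (n,)
        Observed times and event indicators.
    surv_at_event_times : ndarray of shape (n, n)
        ``surv_at_event_times[i, j] = S_hat(T_i | x_j)`` -- every
        individual's predicted survival evaluated at every individual's
        observed time.  Build it with any interpolation scheme; only rows
        belonging to observed events are used.

    Returns
    -------
    float in [0, 1]
    """
    durations, events = check_durations_events(durations, events)
    S = np.asarray(surv_at_event_times, dtype=float)
    n = durations.shape[0]
    if S.shape != (n, n):
        raise ValidationError(f"surv_at_event_times must be (n, n)=({n}, {n}), got {S.shape}")
    concordant = 0.0
    comparable = 0
    for i in np.flatnonzero(events == 1):
        cmp_mask = (durations > durations[i]) | (
            (durations == durations[i]) & (events == 0)
        )
        if not cmp_mask.any():
            continue
        s_i = S[i, i]
        s_j = S[i, cmp_mask]
        concordant += np.sum(s_i < s_j) + 0.5 * np.sum(s_i == s_j)
        comparable += int(cmp_mask.sum())
    if comparable == 0:
        raise ValidationError("no comparable pairs: concordance is undefined")
    return float(concordant / comparable)


def brier_score(t: float, durations, events, surv_at_t, censor_G: StepEstimate) -> float:
    """IPCW Brier score at a single time ``t``.

    ``mean_i [ 1{T_i <= t, D_i=1} S_hat(t|x_i)^2 / G(T_i-)
             + 1{T_i > t} (1 - S_hat(t|x_i))^2 / G(t) ]``.

    Individuals censored at or before ``t`` contribute 0.  Terms whose IPCW
    denominator is 0 are dropped with a logged warning.
    """
    durations, events = check_durations_events(durations, events)
    s = np.asarray(surv_at_t, dtype=float).ravel()
    if s.shape[0] != durations.shape[0]:
        raise ValidationError("surv_at_t must have one value per individual")
    g_left = np.asarray(censor_G.left(durations), dtype=float)
    g_t = float(censor_G(t))
    past_event = (durations <= t) & (events == 1)
    still_alive = durations > t

    contrib = np.zeros_like(s)
    bad = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        past_terms = s**2 / g_left
        alive_terms = (1.0 - s) ** 2 / g_t if g_t > 0 else np.full_like(s, np.inf)
    if past_event.any():
        ok = g_left > 0
        contrib[past_event & ok] = past_terms[past_event & ok]
        bad += int((past_event & ~ok).sum())
    if still_alive.any():
        if g_t > 0:
            contrib[still_alive] = alive_terms[still_alive]
        else:
            bad += int(still_alive.sum())
    if bad:
        logger.warning(
            "Brier score at t=%g dropped %d term(s) with zero IPCW weight", t, bad
        )
    return float(contrib.mean())


def integrated_brier_score(
    eval_times, durations, events, surv_matrix, censor_G: StepEstimate
) -> float:
    """Trapezoidal integral of the Brier score over ``eval_times`` divided by
    the spanned time range.

    ``surv_matrix[i, k]`` is individual ``i``'s predicted survival at
    ``eval_times[k]`` (use :func:`nnsurv.interpolation.eval_survival`).
    """
    eval_times = np.asarray(eval_times, dtype=float).ravel()
    if eval_times.size == 0:
        raise ValidationError("evaluation grid must be nonempty")
    if (np.diff(eval_times) <= 0).any():
        raise ValidationError("evaluation times must be strictly increasing")
    surv_matrix = np.atleast_2d(np.asarray(surv_matrix, dtype=float))
    if surv_matrix.shape[1] != eval_times.size:
        raise ValidationError("surv_matrix must have one column per evaluation time")
    scores = np.array(
        [
            brier_score(t, durations, events, surv_matrix[:, k], censor_G)
            for k, t in enumerate(eval_times)
        ]
    )
    if eval_times.size == 1:
        return float(scores[0])
    span = eval_times[-1] - eval_times[0]
    return float(np.trapezoid(scores, eval_times) / span)
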