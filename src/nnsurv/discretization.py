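"""Time-axis discretization.

A :class:`TimeGrid` holds cut points ``0 = tau_0 < tau_1 < ... < tau_m``;
interval ``j`` is the half-open set ``(tau_{j-1}, tau_j]`` (the single
coordinate convention used throughout the package).  Grids are built either
equidistantly on ``[0, t_max]`` or from Kaplan-Meier quantiles, which places
cuts so each interval carries (as nearly as ties allow) the same drop in the
marginal survival estimate.

Continuous observations are turned into per-individual labels by
:func:`discretize_labels`:

* ``scheme="rounded"`` (discrete-time heads): an event in ``(tau_{j-1}, tau_j]``
  is moved to ``tau_j`` (index ``j``), a censoring to ``tau_{j-1}`` (index
  ``j-1``).  A censoring *exactly at* a cut stays at that cut.  Censorings
  rounded down to ``tau_0`` get index 0 and contribute nothing to the
  discrete likelihoods.
* ``scheme="interval"`` (piecewise-constant-hazard head): the label is the
  interval index ``kappa(t)`` of the unrounded time for events and
  censorings alike, because the continuous-time likelihood uses the exact
  within-interval exposure.

In both schemes ``frac`` stores ``rho(t) = (t - tau_{kappa-1}) / delta_kappa``,
the proportion of interval ``kappa(t)`` elapsed at the *original* time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import check_durations_events, kaplan_meier
from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "TimeGrid",
    "DiscreteLabels",
    "make_equidistant_grid",
    "make_km_quantile_grid",
    "assign_interval",
    "discretize_labels",
    "SurvivalDiscretizer",
]

logger = logging.getLogger(__name__)


@dataclass
class TimeGrid:
    """Cut points ``0 = tau_0 < tau_1 < ... < tau_m`` with ``m >= 1``."""

    cuts: np.ndarray

    def __post_init__(self):
        self.cuts = np.asarray(self.cuts, dtype=float).ravel()
        if self.cuts.size < 2:
            raise ConfigurationError("a TimeGrid needs at least cuts (0, tau_1)")
        if self.cuts[0] != 0.0:
            raise ConfigurationError(f"tau_0 must be 0, got {self.cuts[0]}")
        if not (np.diff(self.cuts) > 0).all():
            raise ConfigurationError("cuts must be strictly increasing")

    @property
    def m(self) -> int:
        """Number of intervals (= number of positive cuts)."""
        return self.cuts.size - 1

    @property
    def t_max(self) -> float:
        return float(self.cuts[-1])

    @property
    def delta(self) -> np.ndarray:
        """Interval widths ``delta_j = tau_j - tau_{j-1}``, length m."""
        return np.diff(self.cuts)

    def to_list(self) -> list[float]:
        return [float(c) for c in self.cuts]


@dataclass
class DiscreteLabels:
    """Per-individual interval index, event indicator and interval fraction.

    ``idx`` lies in {0, ..., m}; ``idx == 0`` only for censored observations
    mapped to ``tau_0`` (no likelihood contribution).  ``frac`` is ``rho(t)``
    of the original observation time and lives in (0, 1].
    """

    idx: np.ndarray
    events: np.ndarray
    frac: np.ndarray
    m: int

    def __post_init__(self):
        self.idx = np.asarray(self.idx, dtype=np.int64).ravel()
        self.events = np.asarray(self.events, dtype=np.int64).ravel()
        self.frac = np.asarray(self.frac, dtype=float).ravel()
        if not (self.idx.shape == self.events.shape == self.frac.shape):
            raise ValidationError("idx, events, frac must share one length")
        if ((self.idx < 0) | (self.idx > self.m)).any():
            raise ValidationError(f"idx must lie in 0..{self.m}")
        if ((self.events == 1) & (self.idx == 0)).any():
            raise ValidationError("an event label must have idx >= 1")

    @property
    def n(self) -> int:
        return self.idx.shape[0]

    def subset(self, index) -> "DiscreteLabels":
        index = np.asarray(index)
        return DiscreteLabels(self.idx[index], self.events[index], self.frac[index], self.m)


def make_equidistant_grid(t_max: float, m: int) -> TimeGrid:
    """Equidistant cuts ``(0, t_max/m, ..., t_max)``."""
    if m < 1:
        raise ConfigurationError(f"grid size m must be >= 1, got {m}")
    if not (np.isfinite(t_max) and t_max > 0):
        raise ConfigurationError(f"t_max must be positive and finite, got {t_max}")
    return TimeGrid(np.linspace(0.0, float(t_max), int(m) + 1))


def make_km_quantile_grid(durations, events, m: int) -> TimeGrid:
    """Cuts at Kaplan-Meier quantiles: equal survival drop per interval.

    With ``S_hat`` the Kaplan-Meier estimate and ``t_max`` the largest
    observed duration, the target levels are
    ``zeta_j = 1 - j * (1 - S_hat(t_max)) / m`` and ``tau_j`` is the smallest
    observed time with ``S_hat(t) <= zeta_j``.  Duplicate cuts (steep drops
    hitting several levels at one time) are collapsed, so the grid may end up
    with fewer than ``m`` intervals; the final cut is forced to ``t_max``.
    """
    if m < 1:
        raise ConfigurationError(f"grid size m must be >= 1, got {m}")
    durations, events = check_durations_events(durations, events)
    if events.sum() == 0:
        raise ConfigurationError(
            "Kaplan-Meier quantile grid needs at least one observed event"
        )
    km = kaplan_meier(durations, events)
    t_max = float(durations.max())
    s_tau = float(km(t_max))
    j = np.arange(1, int(m) + 1)
    zeta = 1.0 - j * (1.0 - s_tau) / m
    # km.values is nonincreasing over km.times; find the first time with S <= zeta_j
    # (up to float round-off in the product-limit values).  searchsorted needs
    # ascending order, so search on the reversed values.
    rev = km.values[::-1]
    pos = km.values.size - np.searchsorted(rev, zeta + 1e-9, side="right")
    taus = km.times[np.clip(pos, 0, km.times.size - 1)]
    taus[-1] = t_max
    cuts = np.unique(np.concatenate(([0.0], taus)))
    if cuts.size - 1 < m:
        logger.info(
            "KM-quantile grid collapsed to %d intervals (requested %d): "
            "tied event times hit several quantile levels at once",
            cuts.size - 1,
            m,
        )
    return TimeGrid(cuts)


def assign_interval(t, grid: TimeGrid, *, clip: bool = True):
    """Interval index ``kappa`` and fraction ``rho`` for times ``t``.

    Returns the unique ``kappa`` with ``tau_{kappa-1} < t <= tau_kappa`` and
    ``rho = (t - tau_{kappa-1}) / delta_kappa`` in (0, 1].  Times above
    ``tau_m`` are clipped to ``tau_m`` (``kappa = m``, ``rho = 1``) when
    ``clip`` is true, else raise.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if ((t <= 0) | ~np.isfinite(t)).any():
        raise ValidationError("times must be strictly positive and finite")
    above = t > grid.cuts[-1]
    if above.any():
        if not clip:
            raise ValidationError(
                f"time {t[above][0]} exceeds the grid's last cut {grid.cuts[-1]}"
            )
        if above.sum():
            logger.warning(
                "%d observation(s) beyond tau_m=%g clipped to the last cut",
                int(above.sum()),
                grid.cuts[-1],
            )
        t = np.minimum(t, grid.cuts[-1])
    kappa = np.searchsorted(grid.cuts, t, side="left")
    rho = (t - grid.cuts[kappa - 1]) / grid.delta[kappa - 1]
    if scalar:
        return int(kappa[0]), float(rho[0])
    return kappa.astype(np.int64), rho


def discretize_labels(durations, events, grid: TimeGrid, scheme: str = "rounded") -> DiscreteLabels:
    """Turn continuous right-censored observations into discrete labels.

    See the module docstring for the two schemes.  Durations above ``tau_m``
    are clipped to ``tau_m`` with a logged warning; the event indicator is
    preserved.
    """
    durations, events = check_durations_events(durations, events)
    kappa, rho = assign_interval(durations, grid, clip=True)
    t_clipped = np.minimum(durations, grid.cuts[-1])
    if scheme == "interval":
        idx = kappa
    elif scheme == "rounded":
        at_cut = t_clipped == grid.cuts[kappa]
        idx = np.where((events == 1) | at_cut, kappa, kappa - 1)
    else:
        raise ConfigurationError(f"unknown label scheme {scheme!r}")
    return DiscreteLabels(idx, events, rho, grid.m)


class SurvivalDiscretizer:
    """Transformer that learns a grid on training data and reuses it.

    Parameters
    ----------
    n_intervals : int
        Requested grid size ``m``.
    grid : {"km", "equidistant"}
        Cut placement: Kaplan-Meier quantiles or equidistant on
        ``[0, max duration]``.
    scheme : {"rounded", "interval"}
        Label convention, see :func:`discretize_labels`.

    Attributes
    ----------
    grid_ : TimeGrid
        The fitted grid (training data only; store with the model).
    """

    def __init__(self, n_intervals: int = 25, grid: str = "km", scheme: str = "rounded"):
        self.n_intervals = n_intervals
        self.grid = grid
        self.scheme = scheme

    def fit(self, durations, events) -> "SurvivalDiscretizer":
        durations, events = check_durations_events(durations, events)
        if self.grid == "km":
            self.grid_ = make_km_quantile_grid(durations, events, self.n_intervals)
        elif self.grid == "equidistant":
            self.grid_ = make_equidistant_grid(float(durations.max()), self.n_intervals)
        else:
            raise ConfigurationError(f"unknown grid scheme {self.grid!r}")
        return self

    def transform(self, durations, events) -> DiscreteLabels:
        if not hasattr(self, "grid_"):
            raise ConfigurationError("SurvivalDiscretizer is not fitted")
        return discretize_labels(durations, events, self.grid_, scheme=self.scheme)

    def fit_transform(self, durations, events) -> DiscreteLabels:
        return self.fit(durations, events).transform(durations, events)
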