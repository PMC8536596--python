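"""Right-censored survival data: container, CSV round-trip, Kaplan-Meier.

The central objects are :class:`SurvivalDataset` -- the classical
``(x_i, t_i, d_i)`` triples of covariates, observed time and event indicator
-- and :class:`StepEstimate`, a right-continuous, nonincreasing step function
on [0, inf) starting at 1, which is what the product-limit (Kaplan-Meier)
estimator returns.

Tie convention: when an event and a censoring occur at the same time, the
event is processed first, i.e. the censored individual still counts as at
risk for the tied event.  The censoring-distribution estimator
:func:`censoring_kaplan_meier` is the same product-limit computation with
flipped indicators, which realises the symmetric rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "SurvivalDataset",
    "StepEstimate",
    "read_survival_table",
    "kaplan_meier",
    "censoring_kaplan_meier",
    "check_durations_events",
]


def check_durations_events(durations, events, *, allow_empty: bool = False):
    """Validate and coerce a (durations, events) pair to float/int arrays."""
    durations = np.asarray(durations, dtype=float).ravel()
    events = np.asarray(events, dtype=float).ravel()
    if durations.shape[0] != events.shape[0]:
        raise ValidationError(
            f"durations (n={durations.shape[0]}) and events (n={events.shape[0]}) "
            "must have the same length"
        )
    if durations.shape[0] == 0 and not allow_empty:
        raise ValidationError("empty survival data: need at least one observation")
    bad = ~(np.isfinite(durations) & (durations > 0))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"durations must be strictly positive and finite; "
            f"offending value {durations[row]!r} at row {row}"
        )
    if not np.isin(events, (0.0, 1.0)).all():
        row = int(np.flatnonzero(~np.isin(events, (0.0, 1.0)))[0])
        raise ValidationError(
            f"event indicators must be exactly 0 or 1; "
            f"offending value {events[row]!r} at row {row}"
        )
    return durations, events.astype(np.int64)


@dataclass
class SurvivalDataset:
    """Covariates, observed times and event indicators for ``n`` individuals.

    Parameters
    ----------
    covariates : ndarray of shape (n, q)
        Feature matrix ``x_i``.
    durations : ndarray of shape (n,)
        Observed event or censoring time ``t_i``; strictly positive.
    events : ndarray of shape (n,)
        Event indicator ``d_i``; 1 = event observed, 0 = right-censored.
    feature_names : list of str, optional
        Column names, preserved through CSV round-trips.
    """

    covariates: np.ndarray
    durations: np.ndarray
    events: np.ndarray
    feature_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        self.durations, self.events = check_durations_events(
            self.durations, self.events
        )
        if self.covariates.shape[0] != self.durations.shape[0]:
            raise ValidationError(
                f"covariates have {self.covariates.shape[0]} rows but "
                f"{self.durations.shape[0]} durations were given"
            )
        if not np.isfinite(self.covariates).all():
            raise ValidationError("covariates must be finite")
        if self.feature_names is None:
            self.feature_names = [f"x{j}" for j in range(self.covariates.shape[1])]
        elif len(self.feature_names) != self.covariates.shape[1]:
            raise ValidationError("feature_names length must match covariate columns")

    @property
    def n(self) -> int:
        return self.durations.shape[0]

    @property
    def q(self) -> int:
        return self.covariates.shape[1]

    def to_frame(self, duration_col: str = "duration", event_col: str = "event") -> pd.DataFrame:
        df = pd.DataFrame(self.covariates, columns=self.feature_names)
        df[duration_col] = self.durations
        df[event_col] = self.events
        return df

    def to_csv(self, path, duration_col: str = "duration", event_col: str = "event") -> None:
        self.to_frame(duration_col, event_col).to_csv(path, index=False)

    def subset(self, index) -> "SurvivalDataset":
        index = np.asarray(index)
        return SurvivalDataset(
            self.covariates[index],
            self.durations[index],
            self.events[index],
            feature_names=list(self.feature_names),
        )


def read_survival_table(
    path,
    duration_col: str = "duration",
    event_col: str = "event",
) -> SurvivalDataset:
    """Read a delimited (comma-separated, with header) survival table.

    All columns other than ``duration_col`` and ``event_col`` are treated as
    numeric covariates; their order is preserved in ``feature_names``.
    """
    df = pd.read_csv(path)
    for col in (duration_col, event_col):
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path!r}; available: {list(df.columns)}"
            )
    feature_names = [c for c in df.columns if c not in (duration_col, event_col)]
    try:
        covariates = df[feature_names].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric covariate column in {path!r}: {exc}") from exc
    return SurvivalDataset(
        covariates,
        df[duration_col].to_numpy(),
        df[event_col].to_numpy(),
        feature_names=feature_names,
    )


@dataclass
class StepEstimate:
    """A right-continuous nonincreasing step function with value 1 before
    the first stored time (the shape of a survival-function estimate).

    ``times`` must be strictly increasing and positive; ``values`` are the
    function's values *at and after* the corresponding times.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.times.shape != self.values.shape:
            raise ValidationError("times and values must have the same length")
        if self.times.size:
            if not (np.diff(self.times) > 0).all() or self.times[0] <= 0:
                raise ValidationError("times must be strictly increasing and positive")
            if ((self.values < 0) | (self.values > 1)).any():
                raise ValidationError("values must lie in [0, 1]")
            if (np.diff(self.values) > 1e-12).any():
                raise ValidationError("values must be nonincreasing")

    def __call__(self, t):
        """Evaluate at ``t`` (scalar or array): value at the largest stored
        time <= t, and 1 if t is below all stored times."""
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            return np.ones_like(t, dtype=float) if t.ndim else 1.0
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.values[np.clip(idx, 0, None)])
        return out if t.ndim else float(out)

    def left(self, t):
        """Left limit: value at the largest stored time strictly below t.

        This is the Graf convention ``G(t-)`` used in IPCW weights.
        """
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            return np.ones_like(t, dtype=float) if t.ndim else 1.0
        idx = np.searchsorted(self.times, t, side="left") - 1
        out = np.where(idx < 0, 1.0, self.values[np.clip(idx, 0, None)])
        return out if t.ndim else float(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "value": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def kaplan_meier(durations, events) -> StepEstimate:
    """Product-limit (Kaplan-Meier) estimate of the marginal survival function.

    Steps occur only at observed event times.  At tied event/censoring times
    the censored individuals count as at risk for the tied event.
    """
    durations, events = check_durations_events(durations, events)
    order = np.argsort(durations, kind="stable")
    t = durations[order]
    d = events[order]
    uniq, start = np.unique(t, return_index=True)
    n_events = np.add.reduceat(d, start)
    at_risk = t.shape[0] - start  # sorted ascending: everyone from `start` on has T >= uniq
    with np.errstate(divide="ignore"):
        log_factors = np.log1p(-n_events / at_risk)  # -inf when the risk set empties
    surv = np.exp(np.cumsum(log_factors))
    has_event = n_events > 0
    return StepEstimate(uniq[has_event], np.clip(surv[has_event], 0.0, 1.0))


def censoring_kaplan_meier(durations, events) -> StepEstimate:
    """Kaplan-Meier estimate of the censoring survival ``G(t)``.

    Identical product-limit computation with flipped indicators ``1 - d``;
    individuals with tied events remain in the risk set at the tied time,
    which is the mirror image of the event-first tie rule.
    """
    durations, events = check_durations_events(durations, events)
    return kaplan_meier(durations, 1 - events)
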