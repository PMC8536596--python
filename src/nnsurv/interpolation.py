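"""Continuous-time evaluation of discrete survival curves.

A discrete model only defines ``S(tau_j | x)`` at its grid points.  Three
evaluation schemes extend it to arbitrary times:

* ``step`` -- right-continuous step function (the raw discrete estimate);
* ``cdi`` -- *constant density interpolation*: the density is constant inside
  each interval, so the survival curve is piecewise linear between cuts;
* ``chi`` -- *constant hazard interpolation*: the hazard is constant inside
  each interval, so the survival curve is piecewise exponential,
  ``S(t) = s0 * (s1/s0)^rho``.

All schemes agree with the stored values at every grid point and are
nonincreasing.  Beyond ``tau_m`` the curve is extended as the constant
``S(tau_m)``.  Degenerate intervals: when ``s1 = 0`` the CHI hazard is
infinite; we return 0 for any ``rho > 0`` (evaluated in log space).  When
``s0 = 0`` the whole interval is 0.
"""

from __future__ import annotations

import numpy as np

from .discretization import assign_interval
from .exceptions import ConfigurationError
from .heads import SurvivalCurves

__all__ = ["eval_survival", "SCHEMES"]

SCHEMES = ("step", "cdi", "chi")


def eval_survival(curves: SurvivalCurves, t, scheme: str = "step") -> np.ndarray:
    """Evaluate survival curves at times ``t`` under an interpolation scheme.

    Parameters
    ----------
    curves : SurvivalCurves
        Discrete survival estimates over a grid.
    t : array-like of positive floats
        Evaluation times (need not be sorted).
    scheme : {"step", "cdi", "chi"}

    Returns
    -------
    ndarray of shape (n, len(t))
    """
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown interpolation scheme {scheme!r}; use one of {SCHEMES}")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    grid = curves.grid
    surv = curves.surv
    kappa, rho = assign_interval(t, grid, clip=True)
    s0 = surv[:, kappa - 1]
    s1 = surv[:, kappa]
    t_clipped = np.minimum(t, grid.t_max)
    at_cut = t_clipped == grid.cuts[kappa]

    if scheme == "step":
        # right-continuous: value of the last cut <= t; inside an interval
        # that is s0, at the cut itself s1
        return np.where(at_cut[None, :], s1, s0)
    if scheme == "cdi":
        return np.where(at_cut[None, :], s1, s0 + rho[None, :] * (s1 - s0))
    # chi
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log(s1) - np.log(s0)  # -inf when s1=0; nan when s0=0 too
        out = s0 * np.exp(rho[None, :] * log_ratio)
    out = np.where(s0 == 0.0, 0.0, out)
    out = np.where((s1 == 0.0) & (rho[None, :] > 0), 0.0, out)
    # exact agreement at grid points regardless of round-off
    return np.where(at_cut[None, :], s1, out)
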