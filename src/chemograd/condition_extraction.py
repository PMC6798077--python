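"""Turn measured profiles into model initial and boundary conditions.

The first measured profile becomes the initial condition via piecewise
linear interpolation.  The intensity time series recorded next to the
source and buffer channels become time-varying Dirichlet boundary
conditions via least-squares polynomial fits; fitting is done in
normalized time (mapped to [-1, 1]) so that degree-7 fits over thousands
of seconds stay well conditioned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial

from .transport_model import ConcentrationProfile

__all__ = [
    "BoundarySeries",
    "BoundaryPolynomial",
    "PiecewiseLinearInitialCondition",
    "interpolate_initial",
    "fit_boundary",
    "select_degree",
]

logger = logging.getLogger(__name__)

SIDES = ("source", "buffer")


@dataclass
class BoundarySeries:
    """Intensity time series recorded adjacent to one fluid channel."""

    side: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("boundary series times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("boundary series values must be finite")


@dataclass
class BoundaryPolynomial:
    """Least-squares polynomial boundary condition ``C(t)``.

    The fit lives in normalized time ``s = (t - t_mid) / t_half``; raw-time
    coefficients (low order first) are recovered by re-expansion and both
    are reported.  Valid only on the fitted series' time span.
    """

    side: str
    degree: int
    coefficients: np.ndarray        # raw time, ascending powers of t
    norm_coefficients: np.ndarray   # normalized time, ascending powers of s
    t_first: float
    t_last: float
    residual_rms: float
    _poly: Polynomial = field(repr=False, default=None)

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < self.t_first - 1e-9) or np.any(t_arr > self.t_last + 1e-9):
            raise ValueError(
                f"boundary polynomial for {self.side!r} evaluated at t={t} "
                f"outside its validity interval [{self.t_first}, {self.t_last}]"
            )
        return self._poly(t_arr)


class PiecewiseLinearInitialCondition:
    """Piecewise-linear interpolant of the first measured profile.

    Exact at every anchor position; evaluation outside the anchored span
    raises, because extrapolating fluorescence data is not meaningful.
    """

    def __init__(self, positions: np.ndarray, values: np.ndarray, time: float) -> None:
        self.positions = np.asarray(positions, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.time = time

    def __call__(self, x):
        x_arr = np.asarray(x, dtype=float)
        lo, hi = self.positions[0], self.positions[-1]
        if np.any(x_arr < lo - 1e-12) or np.any(x_arr > hi + 1e-12):
            raise ValueError(
                f"initial condition evaluated outside data span [{lo}, {hi}]"
            )
        return np.interp(x_arr, self.positions, self.values)


def interpolate_initial(profile: ConcentrationProfile) -> PiecewiseLinearInitialCondition:
    """Piecewise-linear initial condition from the first measured profile."""
    order = np.argsort(profile.positions)
    pos = profile.positions[order]
    val = profile.values[order]
    if pos.size < 2:
        raise ValueError("initial profile needs at least 2 data points")
    if np.any(np.diff(pos) == 0):
        dup = pos[:-1][np.diff(pos) == 0][0]
        raise ValueError(f"duplicate position {dup} in initial profile")
    return PiecewiseLinearInitialCondition(pos, val, profile.time)


def fit_boundary(series: BoundarySeries, degree: int) -> BoundaryPolynomial:
    """Ordinary least-squares polynomial fit of the given degree.

    Raises if ``degree >= number of points`` (the normal equations would be
    rank deficient and the "fit" would no longer be a least-squares
    smoother).
    """
    n = series.times.size
    if degree < 0:
        raise ValueError("degree must be non-negative")
    if degree >= n:
        raise ValueError(
            f"degree {degree} requires more than {n} data points (need > degree)"
        )
    poly = Polynomial.fit(series.times, series.values, deg=degree)
    resid = series.values - poly(series.times)
    raw = poly.convert()  # re-expand in raw time
    return BoundaryPolynomial(
        side=series.side,
        degree=degree,
        coefficients=raw.coef,
        norm_coefficients=poly.coef,
        t_first=float(series.times[0]),
        t_last=float(series.times[-1]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        _poly=poly,
    )


def select_degree(
    series: BoundarySeries, max_degree: int, rel_tol: float = 0.02
) -> int:
    """Smallest polynomial degree giving an adequate boundary fit.

    A degree qualifies when its RMS residual, relative to the series' value
    range, drops below ``rel_tol``, or when raising the degree from the next
    lower one improves the relative RMS by less than ``rel_tol`` (a fit
    plateau).  Deterministic; returns ``max_degree`` with a warning when the
    criterion is never met.
    """
    if max_degree >= series.times.size:
        raise ValueError("max_degree must be below the number of data points")
    vrange = float(np.ptp(series.values))
    scale = vrange if vrange > 0 else 1.0
    prev_rel = None
    for deg in range(max_degree + 1):
        rel = fit_boundary(series, deg).residual_rms / scale
        if rel <= rel_tol:
            return deg
        if prev_rel is not None and (prev_rel - rel) < rel_tol:
            return deg
        prev_rel = rel
    logger.warning(
        "select_degree: no degree up to %d met rel_tol=%g for side %r; "
        "returning max_degree",
        max_degree, rel_tol, series.side,
    )
    return max_degree
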