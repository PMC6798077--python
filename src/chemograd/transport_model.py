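"""One-dimensional advection-diffusion transport across a hydrogel channel.

The solute concentration ``C(x, t)`` in a channel of width ``d`` obeys

.. math::

    \\frac{\\partial C}{\\partial t}
        = D \\frac{\\partial^2 C}{\\partial x^2}
        - u \\frac{\\partial C}{\\partial x},
    \\qquad 0 < x < d,

with an initial profile ``C(x, t0) = C0(x)`` and time-varying Dirichlet
boundaries ``C(0, t) = Cs(t)`` (source channel) and ``C(d, t) = Cb(t)``
(buffer/sink channel).  ``D`` is the effective diffusivity of the solute in
the gel (mm^2/s) and ``u`` the uniform advection velocity (mm/s).

Discretization: central differences for the diffusive term, second-order
upwinding for the advective term (falling back to first-order upwind at the
interior node adjacent to the inflow boundary, where the second upstream
node does not exist), and implicit Euler time stepping.  Each step solves a
pentadiagonal linear system with a banded LU factorization; for a fixed
parameter set the factorization is reused across all time steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import lapack as _lapack

__all__ = [
    "SpatialGrid",
    "TimeGrid",
    "TransportParameters",
    "ConcentrationProfile",
    "BoundaryFn",
    "constant_boundary",
    "step_implicit",
    "simulate",
    "steady_state_analytic",
    "peclet",
]


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform grid of ``n_nodes`` nodes on ``[0, width]`` (mm)."""

    width: float
    n_nodes: int

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"channel width must be positive, got {self.width}")
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes (two boundaries + interior)")

    @property
    def x(self) -> np.ndarray:
        """Node positions, first node at 0, last at ``width``."""
        return np.linspace(0.0, self.width, self.n_nodes)

    @property
    def h(self) -> float:
        """Uniform node spacing."""
        return self.width / (self.n_nodes - 1)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time stepping from ``t_start`` to ``t_end`` with step ``dt`` (s)."""

    t_start: float
    t_end: float
    dt: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        ratio = (self.t_end - self.t_start) / self.dt
        if abs(ratio - round(ratio)) > 1e-8 * max(1.0, ratio):
            raise ValueError(
                f"(t_end - t_start)/dt = {ratio} is not an integer number of steps"
            )

    @property
    def n_steps(self) -> int:
        return int(round((self.t_end - self.t_start) / self.dt))

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n_steps + 1)


@dataclass(frozen=True)
class TransportParameters:
    """Effective diffusivity ``D`` (mm^2/s) and advection velocity ``u`` (mm/s)."""

    diffusivity: float
    advection: float

    def __post_init__(self) -> None:
        if not self.diffusivity > 0:
            raise ValueError(f"diffusivity must be positive, got {self.diffusivity}")
        if not math.isfinite(self.advection):
            raise ValueError("advection must be finite")


@dataclass
class ConcentrationProfile:
    """Concentration (fluorescence intensity, a.u.) at positions at one time."""

    time: float
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite concentration values at t={self.time}")


class BoundaryFn:
    """Time-varying boundary intensity with an explicit validity interval."""

    def __init__(
        self,
        fn: Callable[[float], float],
        t_first: float = -math.inf,
        t_last: float = math.inf,
    ) -> None:
        self._fn = fn
        self.t_first = t_first
        self.t_last = t_last

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < self.t_first) or np.any(t_arr > self.t_last):
            raise ValueError(
                f"boundary function evaluated at t={t} outside its validity "
                f"interval [{self.t_first}, {self.t_last}]"
            )
        return self._fn(t)


def constant_boundary(value: float) -> BoundaryFn:
    """Boundary held at a constant intensity for all time."""
    return BoundaryFn(lambda t: np.full_like(np.asarray(t, dtype=float), value)
                      if np.ndim(t) else float(value))


class ImplicitStepper:
    """Banded-LU implicit-Euler operator for fixed ``(D, u, grid, dt)``.

    The system matrix ``A = I - dt*L`` (with Dirichlet identity rows at both
    boundaries) is assembled in LAPACK band storage and LU-factored once
    with partial pivoting (``dgbtrf``); every step is then a single
    ``dgbtrs`` solve.
    """

    _KL = 2  # two lower diagonals (second-order upwind for u >= 0)
    _KU = 2  # two upper diagonals (mirrored stencil for u < 0)

    def __init__(self, params: TransportParameters, grid: SpatialGrid, dt: float) -> None:
        if not dt > 0:
            raise ValueError("dt must be positive")
        self.grid = grid
        self.dt = dt
        n = grid.n_nodes
        h = grid.h
        kl, ku = self._KL, self._KU
        D = params.diffusivity
        u = params.advection
        s = D * dt / h**2

        ab = np.zeros((2 * kl + ku + 1, n))

        def put(i, j, v):
            # A[i, j] -> ab[kl + ku + i - j, j]
            ab[kl + ku + np.asarray(i) - np.asarray(j), j] = v

        # Dirichlet rows.
        put(0, 0, 1.0)
        put(n - 1, n - 1, 1.0)

        if u >= 0:
            r = u * dt / h
            # first interior node: first-order upwind fallback
            put(1, 0, -(s + r))
            put(1, 1, 1.0 + 2.0 * s + r)
            put(1, 2, -s)
            i = np.arange(2, n - 1)
            put(i, i - 2, 0.5 * r)
            put(i, i - 1, -(s + 2.0 * r))
            put(i, i, 1.0 + 2.0 * s + 1.5 * r)
            put(i, i + 1, -s)
        else:
            # mirror image: upstream is on the right
            r = -u * dt / h
            put(n - 2, n - 1, -(s + r))
            put(n - 2, n - 2, 1.0 + 2.0 * s + r)
            put(n - 2, n - 3, -s)
            i = np.arange(1, n - 2)
            put(i, i + 2, 0.5 * r)
            put(i, i + 1, -(s + 2.0 * r))
            put(i, i, 1.0 + 2.0 * s + 1.5 * r)
            put(i, i - 1, -s)

        lu, ipiv, info = _lapack.dgbtrf(ab, kl, ku)
        if info != 0:
            raise np.linalg.LinAlgError(
                f"banded LU factorization of the implicit-Euler system failed "
                f"(dgbtrf info={info}; D={D}, u={u}, dt={dt}, n={n})"
            )
        self._lu = lu
        self._ipiv = ipiv

    def step(self, values: np.ndarray, bc_left: float, bc_right: float) -> np.ndarray:
        """Advance nodal values by one implicit-Euler step.

        ``bc_left``/``bc_right`` are the boundary intensities at the *new*
        time level; the returned array satisfies them exactly.
        """
        rhs = np.array(values, dtype=float)
        rhs[0] = bc_left
        rhs[-1] = bc_right
        x, info = _lapack.dgbtrs(self._lu, self._KL, self._KU, rhs, self._ipiv)
        if info != 0:
            raise np.linalg.LinAlgError(f"banded solve failed (dgbtrs info={info})")
        if not np.all(np.isfinite(x)):
            raise np.linalg.LinAlgError(
                "implicit step produced non-finite values (ill-conditioned system)"
            )
        return x


def step_implicit(
    profile: ConcentrationProfile,
    params: TransportParameters,
    grid: SpatialGrid,
    dt: float,
    bc_left: float,
    bc_right: float,
) -> ConcentrationProfile:
    """One implicit-Euler step of the advection-diffusion equation.

    ``profile`` must be defined on the nodes of ``grid``.  The returned
    profile is at ``profile.time + dt`` and matches the prescribed boundary
    intensities exactly at ``x = 0`` and ``x = width``.
    """
    if profile.positions.shape[0] != grid.n_nodes or not np.allclose(
        profile.positions, grid.x
    ):
        raise ValueError("profile is not defined on the nodes of the given grid")
    stepper = ImplicitStepper(params, grid, dt)
    new = stepper.step(profile.values, bc_left, bc_right)
    return ConcentrationProfile(time=profile.time + dt, positions=grid.x, values=new)


def simulate(
    ic: Callable[[np.ndarray], np.ndarray],
    bc_left: Callable[[float], float],
    bc_right: Callable[[float], float],
    params: TransportParameters,
    grid: SpatialGrid,
    times: TimeGrid,
    output_times: Sequence[float],
) -> list[ConcentrationProfile]:
    """Integrate the transport equation and return profiles at chosen times.

    Parameters
    ----------
    ic
        Initial concentration as a function of position, sampled on the grid
        at ``times.t_start``.
    bc_left, bc_right
        Source and buffer boundary intensities as functions of time.  If a
        function exposes ``t_first``/``t_last`` attributes (as
        :class:`BoundaryFn` does), all evaluation times must fall inside
        that validity interval.
    output_times
        Times at which profiles are returned.  Each must lie in
        ``[t_start, t_end]``; it is snapped to the nearest internal step
        (within ``dt/2`` by construction).
    """
    t0, t1, dt = times.t_start, times.t_end, times.dt
    out_idx: dict[int, float] = {}
    for t in output_times:
        if t < t0 - 1e-9 or t > t1 + 1e-9:
            raise ValueError(
                f"requested output time {t} outside simulation window [{t0}, {t1}]"
            )
        out_idx[int(round((t - t0) / dt))] = t

    # Validate boundary coverage before stepping.
    for bc in (bc_left, bc_right):
        tf = getattr(bc, "t_first", -math.inf)
        tl = getattr(bc, "t_last", math.inf)
        if t0 < tf - 1e-9 or t1 > tl + 1e-9:
            bad = t0 if t0 < tf else t1
            raise ValueError(
                f"boundary condition not valid at t={bad}: validity interval "
                f"is [{tf}, {tl}]"
            )

    x = grid.x
    values = np.asarray(ic(x), dtype=float)
    if values.shape != x.shape:
        raise ValueError("initial condition did not evaluate to one value per node")

    stepper = ImplicitStepper(params, grid, dt)
    out: list[ConcentrationProfile] = []
    if 0 in out_idx:
        out.append(ConcentrationProfile(time=t0, positions=x, values=values.copy()))
    for k in range(1, times.n_steps + 1):
        t = t0 + k * dt
        values = stepper.step(values, float(bc_left(t)), float(bc_right(t)))
        if k in out_idx:
            out.append(ConcentrationProfile(time=t, positions=x, values=values.copy()))
    return out


def steady_state_analytic(
    params: TransportParameters,
    width: float,
    c_left: float,
    c_right: float,
) -> Callable[[np.ndarray], np.ndarray]:
    """Closed-form steady state of ``D C'' - u C' = 0`` with Dirichlet ends.

    For ``u = 0`` this is the linear interpolant between the boundary
    values; otherwise

    .. math:: C(x) = C_0 + (C_d - C_0)
              \\frac{e^{u x / D} - 1}{e^{u d / D} - 1}.

    Serves as an exact verification oracle for the finite-difference solver.
    """
    if not width > 0:
        raise ValueError("width must be positive")
    D, u = params.diffusivity, params.advection

    if u == 0:
        def linear(x):
            return c_left + (c_right - c_left) * np.asarray(x) / width
        return linear

    def exponential(x):
        p = u / D
        return c_left + (c_right - c_left) * np.expm1(p * np.asarray(x)) / np.expm1(
            p * width
        )

    return exponential


def peclet(params: TransportParameters, width: float) -> float:
    """Péclet number ``u * d / D``: advective over diffusive transport."""
    return params.advection * width / params.diffusivity
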