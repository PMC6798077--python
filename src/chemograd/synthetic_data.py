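"""Synthetic microfluidic datasets with known ground truth.

Emulates the experimental conditions the pipeline is meant for: fluorescence
profiles across a hydrogel channel (width 0.91 mm or 0.496 mm) sampled
every 120 s or 30 s, driven by a source channel whose intensity rises
from zero toward a plateau and a near-constant buffer, and corrupted by
additive i.i.d. Gaussian noise of about 1% of the plateau signal.

The clean profiles come from the same transport equation the inference
fits, but solved on a grid four times finer in space and time than the
inference default, so parameter-recovery tests are not circular at the
discretization level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cli_io import Dataset
from .condition_extraction import BoundarySeries
from .transport_model import (
    BoundaryFn,
    ConcentrationProfile,
    SpatialGrid,
    TimeGrid,
    TransportParameters,
    simulate,
)

__all__ = [
    "SourceWaveform",
    "BufferWaveform",
    "ScenarioSpec",
    "SyntheticDataset",
    "generate",
    "reference_scenarios",
]


@dataclass(frozen=True)
class SourceWaveform:
    """Saturating rise ``A * (1 - exp(-t / tau))`` of the source intensity."""

    amplitude: float = 100.0
    tau: float = 300.0

    def __call__(self, t):
        return self.amplitude * -np.expm1(-np.asarray(t, dtype=float) / self.tau)


@dataclass(frozen=True)
class BufferWaveform:
    """Low, slowly drifting buffer (sink) intensity."""

    level: float = 2.0
    drift: float = 5e-4  # intensity units per second

    def __call__(self, t):
        return self.level + self.drift * np.asarray(t, dtype=float)


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground-truth description of one synthetic experiment.

    ``sigma_frac`` is the noise standard deviation as a fraction of the
    source plateau amplitude.  ``boundary_oversample`` controls how much
    denser the boundary series is than the profile sampling interval.
    """

    name: str
    params: TransportParameters
    width: float = 0.91
    t0: float = 120.0
    t_end: float = 2640.0
    interval: float = 120.0
    sigma_frac: float = 0.01
    n_positions: int = 100
    source: SourceWaveform = field(default_factory=SourceWaveform)
    buffer: BufferWaveform = field(default_factory=BufferWaveform)
    boundary_noise: bool = True
    boundary_oversample: int = 8
    grid_refinement: int = 4
    substep_refinement: int = 4
    seed: int = 0

    @property
    def profile_times(self) -> np.ndarray:
        obs = np.arange(self.t0 + self.interval, self.t_end + 1e-9, self.interval)
        return np.concatenate([[self.t0], obs])

    @property
    def sigma(self) -> float:
        """Absolute noise standard deviation (intensity units)."""
        return self.sigma_frac * self.source.amplitude


@dataclass
class SyntheticDataset:
    """Noisy dataset, its clean ground truth, and the recorded noise draws."""

    dataset: Dataset
    clean_profiles: list[ConcentrationProfile]
    noise: np.ndarray  # shape (n_times, n_positions); noisy - clean
    scenario: ScenarioSpec


def _checked_waveform(fn, times, side):
    vals = np.asarray(fn(times), dtype=float)
    if np.any(vals < 0):
        warnings.warn(
            f"{side} waveform produced negative intensities; clipping at 0",
            stacklevel=3,
        )
        vals = np.clip(vals, 0.0, None)
    return vals


def generate(scenario: ScenarioSpec, seed: int | None = None) -> SyntheticDataset:
    """Simulate one synthetic experiment.

    The transport equation is integrated from a fluorescence-free state at
    ``t = 0`` on a refined grid; clean profiles are sampled at the scenario
    positions and times, then i.i.d. ``N(0, sigma^2)`` noise is added.
    Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    # refined solver settings relative to the inference defaults (101 nodes,
    # 60 substeps per interval)
    n_nodes = scenario.grid_refinement * 100 + 1
    dt = scenario.interval / (60 * scenario.substep_refinement)
    grid = SpatialGrid(scenario.width, n_nodes)
    n_steps = int(round(scenario.t_end / dt))
    tgrid = TimeGrid(0.0, n_steps * dt, dt)

    src = BoundaryFn(lambda t: _checked_waveform(scenario.source, t, "source"))
    buf = BoundaryFn(lambda t: _checked_waveform(scenario.buffer, t, "buffer"))
    times = scenario.profile_times
    solutions = simulate(
        lambda x: np.zeros_like(x), src, buf,
        scenario.params, grid, tgrid, list(times),
    )

    positions = np.linspace(0.0, scenario.width, scenario.n_positions)
    clean = [
        ConcentrationProfile(
            time=sol.time,
            positions=positions,
            values=np.interp(positions, grid.x, sol.values),
        )
        for sol in solutions
    ]
    noise = rng.normal(0.0, scenario.sigma, size=(len(clean), positions.size))
    noisy = [
        ConcentrationProfile(time=c.time, positions=positions, values=c.values + e)
        for c, e in zip(clean, noise)
    ]

    bt = np.arange(
        0.0, scenario.t_end + 1e-9, scenario.interval / scenario.boundary_oversample
    )
    boundaries = {}
    for side, fn in (("source", scenario.source), ("buffer", scenario.buffer)):
        vals = _checked_waveform(fn, bt, side)
        if scenario.boundary_noise:
            vals = vals + rng.normal(0.0, scenario.sigma, size=vals.size)
        boundaries[side] = BoundarySeries(side=side, times=bt.copy(), values=vals)

    dataset = Dataset(
        name=scenario.name,
        width_mm=scenario.width,
        t0_s=scenario.t0,
        profiles=noisy,
        boundaries=boundaries,
    )
    return SyntheticDataset(
        dataset=dataset, clean_profiles=clean, noise=noise, scenario=scenario
    )


def reference_scenarios() -> dict[str, ScenarioSpec]:
    """Three named fixtures mirroring typical gradient-chamber experiments.

    * ``dextranI-like`` — 0.91 mm channel, profiles every 120 s from a
      t0 of 120 s out to 2640 s, Dextran-scale diffusivity 5e-5 mm^2/s.
    * ``dextranII-like`` — same channel and cadence, shorter run (1440 s).
    * ``ccl19-like`` — 0.496 mm channel, every 30 s from t0 = 0 to 120 s,
      chemokine-in-gel diffusivity 1.3e-5 mm^2/s.

    Advection is a few 1e-4 mm/s (the lower interstitial-flow range) and
    noise is 1% of the source plateau throughout.
    """
    return {
        "dextranI-like": ScenarioSpec(
            name="dextranI-like",
            params=TransportParameters(diffusivity=5e-5, advection=2e-4),
            width=0.91, t0=120.0, t_end=2640.0, interval=120.0,
        ),
        "dextranII-like": ScenarioSpec(
            name="dextranII-like",
            params=TransportParameters(diffusivity=5e-5, advection=1e-4),
            width=0.91, t0=120.0, t_end=1440.0, interval=120.0,
        ),
        "ccl19-like": ScenarioSpec(
            name="ccl19-like",
            params=TransportParameters(diffusivity=1.3e-5, advection=1e-4),
            width=0.496, t0=0.0, t_end=120.0, interval=30.0,
        ),
    }


def scaled_scenario(base: ScenarioSpec, **overrides) -> ScenarioSpec:
    """A copy of a scenario with selected fields replaced."""
    return replace(base, **overrides)
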