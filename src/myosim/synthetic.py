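"""Synthetic imaging-table generators.

These emulate the two table kinds a live/fixed imaging pipeline would
produce — tracked-myoblast trajectories and day-0/day-5 nuclei position
tables — with controllable speed, turning, proliferation and spacing
statistics, so the metrics, inference and optimization modules are fully
testable without any imaging data.  Every generator is a pure function
of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .metrics import QualityIndicators, quality_from_sim
from .params import SimParams

__all__ = ["SynthSpec", "ObservedQuality", "generate_tracks",
           "generate_nuclei_tables", "generate_observed_quality"]


@dataclass(frozen=True)
class SynthSpec:
    """Specification of the synthetic imaging tables.

    Track parameters mirror the persistent-random-walk behaviour metrics
    (speed in μm·min⁻¹, turning SD in degrees·min⁻¹); nuclei-table
    parameters control day-0/day-5 composition and the day-5
    internuclear spacing distribution (gamma, parameterised by target
    mean in μm and coefficient of variation).
    """

    n_tracks: int = 100
    n_frames: int = 50
    frame_interval_min: float = 5.0
    speed_mean: float = 0.5
    speed_sd: float = 0.2
    turning_sd: float = 10.0
    n_divisions: int = 0
    n_day0_myoblasts: int = 400
    n_day0_myonuclei: int = 0
    n_day5_myoblasts: int = 150
    n_day5_myonuclei: int = 300
    nuclei_per_tube: int = 8
    spacing_mean_um: float = 30.0
    spacing_cv: float = 0.4
    area_mm2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tracks", "n_frames", "n_divisions",
                     "n_day0_myoblasts", "n_day0_myonuclei",
                     "n_day5_myoblasts", "n_day5_myonuclei"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        if self.nuclei_per_tube < 2:
            raise ValueError("nuclei_per_tube: must be >= 2")
        if self.spacing_cv < 0:
            raise ValueError("spacing_cv: must be >= 0")
        if self.frame_interval_min <= 0 or self.area_mm2 <= 0:
            raise ValueError("frame_interval_min and area_mm2 must be > 0")
        if self.speed_mean < 0 or self.speed_sd < 0 or self.turning_sd < 0:
            raise ValueError("speed/turning parameters must be >= 0")


@dataclass(frozen=True)
class ObservedQuality:
    """Pseudo-observed quality indicators with the generating truth attached.

    ``truth`` holds the inferred-parameter values the run was generated
    with, for parameter-recovery harnesses; it must never be shown to
    the inference machinery itself.
    """

    q: QualityIndicators
    truth: dict[str, float]
    sim_output: engine.SimOutput = field(repr=False, compare=False)


def generate_tracks(spec: SynthSpec) -> pd.DataFrame:
    """Persistent-random-walk trajectory table in the track CSV dialect.

    Per-track speed ~ Normal(mean, sd) truncated at 0; per-step heading
    change ~ Normal(0, turning_sd · Δt) degrees.  With turning_sd = 0
    every track is a straight line.
    """
    rng = np.random.default_rng(spec.seed)
    side = math.sqrt(spec.area_mm2) * 1000.0
    dt = spec.frame_interval_min
    rows = []
    speeds = engine._draw_speeds(rng, spec.n_tracks, spec.speed_mean,
                                 spec.speed_sd)
    for tid in range(spec.n_tracks):
        x, y = rng.uniform(0.0, side, size=2)
        heading = rng.uniform(0.0, 360.0)
        step = speeds[tid] * dt
        for frame in range(spec.n_frames):
            rows.append((frame, frame * dt, tid, x, y))
            if spec.turning_sd > 0:
                heading += rng.normal(0.0, spec.turning_sd * dt)
            rad = math.radians(heading)
            x += step * math.cos(rad)
            y += step * math.sin(rad)
    return pd.DataFrame(rows,
                        columns=["frame", "time_min", "track_id",
                                 "x_um", "y_um"])


def _gamma_spacings(rng: np.random.Generator, n: int, mean: float,
                    cv: float) -> np.ndarray:
    """n spacings with the requested mean and coefficient of variation.

    Gamma with shape 1/cv² and scale mean·cv² has exactly these first
    two moments; cv = 0 degenerates to constant spacing.
    """
    if cv == 0.0:
        return np.full(n, mean)
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean * cv**2, size=n)


def _lay_tubes(rng: np.random.Generator, n_myonuclei: int,
               nuclei_per_tube: int, spacing_mean: float, cv: float,
               side: float, first_tube_id: int,
               ) -> tuple[np.ndarray, np.ndarray]:
    """Place myonuclei in collinear tubes on random axes; returns (xy, tube)."""
    xy = np.empty((n_myonuclei, 2))
    tube = np.empty(n_myonuclei, dtype=np.int64)
    placed = 0
    tid = first_tube_id
    while placed < n_myonuclei:
        size = min(nuclei_per_tube, n_myonuclei - placed)
        anchor = rng.uniform(0.0, side, size=2)
        theta = rng.uniform(0.0, 2 * math.pi)
        u = np.array([math.cos(theta), math.sin(theta)])
        if size >= 2:
            gaps = _gamma_spacings(rng, size - 1, spacing_mean, cv)
            offsets = np.concatenate([[0.0], np.cumsum(gaps)])
        else:
            offsets = np.array([0.0])
        xy[placed:placed + size] = anchor + offsets[:, None] * u
        tube[placed:placed + size] = tid
        placed += size
        tid += 1
    return xy, tube


def generate_nuclei_tables(spec: SynthSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Day-0 and day-5 nuclei tables in the nuclei CSV dialect.

    Day 0 holds myoblasts placed uniformly (plus optional seeded tubes);
    day 5 holds myotubes laid on random axes with gamma-distributed
    consecutive spacings hitting the target mean and CV, plus the
    remaining unfused myoblasts.
    """
    n_spacings_day5 = sum(
        max(0, min(spec.nuclei_per_tube,
                   spec.n_day5_myonuclei - k) - 1)
        for k in range(0, spec.n_day5_myonuclei, spec.nuclei_per_tube))
    if spec.spacing_cv > 0 and n_spacings_day5 <= 1:
        raise ValueError("spacing_cv > 0 requires at least two day-5 "
                         "spacings; increase n_day5_myonuclei")
    rng = np.random.default_rng(spec.seed)
    side = math.sqrt(spec.area_mm2) * 1000.0

    def _table(day: int, n_mb: int, n_mn: int, first_tube: int) -> pd.DataFrame:
        xy_mb = rng.uniform(0.0, side, size=(n_mb, 2))
        xy_mn, tube = _lay_tubes(rng, n_mn, spec.nuclei_per_tube,
                                 spec.spacing_mean_um, spec.spacing_cv,
                                 side, first_tube)
        xy = np.vstack([xy_mb, xy_mn])
        return pd.DataFrame({
            "day": day,
            "nucleus_id": np.arange(n_mb + n_mn),
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "state": ["myoblast"] * n_mb + ["myonucleus"] * n_mn,
            "tube_id": [pd.NA] * n_mb + list(tube),
        })

    day0 = _table(0, spec.n_day0_myoblasts, spec.n_day0_myonuclei, 0)
    day5 = _table(5, spec.n_day5_myoblasts, spec.n_day5_myonuclei, 1000)
    return day0, day5


def generate_observed_quality(params: SimParams) -> ObservedQuality:
    """Run the engine forward and measure Q, keeping the truth on the side.

    This is the ground-truth generator for the ABC parameter-recovery
    experiment: the returned indicators are what "imaging" would have
    measured, and ``truth`` records the residence-time, age-gate and
    force parameters that actually produced them.
    """
    out = engine.simulate(params)
    q = quality_from_sim(out)
    truth = {
        "t_rmax": params.fusion.t_rmax,
        "t_mtfuse": params.fusion.t_mtfuse,
        "k_lat": params.mechanics.k_lat,
        "k_nuc": params.mechanics.k_nuc,
    }
    return ObservedQuality(q=q, truth=truth, sim_output=out)
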