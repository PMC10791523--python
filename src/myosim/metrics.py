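"""Behaviour metrics and myotube quality indicators.

Early-stage behaviour metrics are computed from tracked-myoblast
trajectory tables (live imaging): speed S_mb, variation in angular
velocity ω_mb and proliferation rate P.  Quality indicators are computed
from nuclei-position tables (fixed imaging at days 0 and 5) or from
simulation output: the change in myonuclei density dM, the mean
consecutive internuclear distance D within myotubes, its coefficient of
variation D_var = σ_D/D̄ (uniformity of nuclear spreading), and the
fusion index (myonuclei / total nuclei).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import SimOutput, compute_major_axis, unwrap_positions
from .params import BehaviourMetrics

__all__ = [
    "QualityIndicators",
    "behaviour_metrics_from_tracks",
    "proliferation_rate",
    "fusion_index",
    "internuclear_distances",
    "pooled_tube_distances",
    "quality_indicators",
    "quality_from_sim",
]

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["frame", "time_min", "track_id", "x_um", "y_um"]
NUCLEI_COLUMNS = ["day", "nucleus_id", "x_um", "y_um", "state", "tube_id"]


@dataclass(frozen=True)
class QualityIndicators:
    """Myotube quality indicators (the model's Q).

    Undefined components (e.g. D when no tube has two nuclei) are NaN.
    """

    dm: float                       # myonuclei·mm⁻², day 5 − day 0
    d: float                        # μm, pooled mean consecutive distance
    d_var: float                    # dimensionless, σ_D / D̄
    fusion_index: float             # myonuclei / total nuclei (day 5)
    fusion_index_day0: float = float("nan")
    per_tube: pd.DataFrame | None = field(default=None, compare=False,
                                          repr=False)

    def as_dict(self) -> dict[str, float]:
        return {"dm": self.dm, "d": self.d, "d_var": self.d_var,
                "fusion_index": self.fusion_index}


# ---------------------------------------------------------------------------
# behaviour metrics from trajectories

def _wrap_angle(deg: np.ndarray) -> np.ndarray:
    """Wrap angles to (−180, 180]."""
    return -((-np.asarray(deg) + 180.0) % 360.0 - 180.0)


def behaviour_metrics_from_tracks(tracks: pd.DataFrame) -> BehaviourMetrics:
    """Measure S_mb, ω_mb and motion diagnostics from a trajectory table.

    S_mb is the mean over all steps of (step displacement / frame
    interval); ω_mb the sample standard deviation over all steps of the
    signed heading change per minute, with heading changes wrapped to
    (−180, 180].  Tracks with fewer than two frames are excluded (a
    count is logged); zero-length displacements contribute no angular
    sample.  Persistence is the per-track net displacement over path
    length, averaged over tracks; the proliferation rate is not
    measurable from trajectories alone and is reported as 0.
    """
    required = set(TRACK_COLUMNS)
    missing = required - set(tracks.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")

    speeds: list[np.ndarray] = []
    turns: list[np.ndarray] = []
    angles: list[np.ndarray] = []
    persistences: list[float] = []
    n_excluded = 0

    for _, g in tracks.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        if len(g) < 2:
            n_excluded += 1
            continue
        xy = g[["x_um", "y_um"]].to_numpy(dtype=float)
        t = g["time_min"].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(
                f"track {g['track_id'].iloc[0]!r}: time not increasing")
        disp = np.diff(xy, axis=0)
        step_len = np.hypot(disp[:, 0], disp[:, 1])
        speeds.append(step_len / dt)
        path = step_len.sum()
        net = float(np.hypot(*(xy[-1] - xy[0])))
        if path > 0:
            persistences.append(net / path)
        moving = step_len > 0
        ang = np.rad2deg(np.arctan2(disp[moving, 1], disp[moving, 0]))
        angles.append(ang)
        if moving.sum() >= 2:
            dheading = _wrap_angle(np.diff(ang))
            # pair each heading change with the interval of the later step
            turns.append(dheading / dt[moving][1:])

    if n_excluded:
        logger.info("excluded %d track(s) with <2 frames", n_excluded)
    if not speeds:
        raise ValueError("no track with >=2 frames")

    all_speeds = np.concatenate(speeds)
    all_turns = np.concatenate(turns) if turns else np.array([])
    all_angles = np.concatenate(angles) if angles else np.array([])

    s_mb = float(all_speeds.mean())
    omega = float(all_turns.std(ddof=1)) if all_turns.size >= 2 else 0.0
    if all_angles.size:
        rad = np.deg2rad(all_angles)
        direction = float(np.rad2deg(np.arctan2(np.sin(rad).mean(),
                                                np.cos(rad).mean())))
    else:
        direction = float("nan")
    persistence = float(np.mean(persistences)) if persistences else None
    return BehaviourMetrics(
        s_mb_mean=s_mb,
        s_mb_sd=float(all_speeds.std(ddof=1)) if all_speeds.size >= 2 else 0.0,
        omega_mb_sd=omega,
        p_rate=0.0,
        direction_mean=direction,
        persistence=persistence,
    )


def proliferation_rate(division_count: int,
                       cell_observation_minutes: float) -> float:
    """Divisions per cell per minute: count / total observed cell·minutes."""
    if division_count < 0:
        raise ValueError("division_count must be >= 0")
    if cell_observation_minutes <= 0:
        raise ValueError("cell_observation_minutes must be > 0")
    return division_count / cell_observation_minutes


def fusion_index(n_myonuclei: int, n_total: int) -> float:
    """Ratio of myonuclei to total nuclei; NaN when no nuclei at all."""
    if n_myonuclei < 0 or n_total < n_myonuclei:
        raise ValueError("need 0 <= n_myonuclei <= n_total")
    if n_total == 0:
        return float("nan")
    return n_myonuclei / n_total


# ---------------------------------------------------------------------------
# quality indicators from nuclei tables

def internuclear_distances(positions: np.ndarray,
                           axis: tuple[np.ndarray, np.ndarray] | None = None,
                           ) -> np.ndarray:
    """Consecutive-neighbour distances along a myotube.

    Nuclei are projected onto the tube axis (computed from the positions
    when not supplied), ordered by axial coordinate, and the Euclidean
    distances between consecutive neighbours returned (n−1 values).
    Fewer than two nuclei give an empty array.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    if positions.shape[0] < 2:
        return np.array([])
    if axis is None:
        centroid, u = compute_major_axis(positions)
    else:
        centroid, u = axis
    if u is None:
        return np.array([])  # degenerate (coincident) tube
    order = np.argsort((positions - centroid) @ u, kind="stable")
    ordered = positions[order]
    gaps = np.diff(ordered, axis=0)
    return np.hypot(gaps[:, 0], gaps[:, 1])


def pooled_tube_distances(nuclei: pd.DataFrame,
                          periodic_domain: tuple[float, float] | None = None,
                          ) -> tuple[np.ndarray, pd.DataFrame]:
    """Pool consecutive internuclear distances across all myotubes.

    Returns the pooled distance array and a per-tube summary frame
    (tube_id, n_nuclei, d_mean).  ``periodic_domain`` unwraps tube
    member positions on a toroidal domain (simulation snapshots).
    """
    mn = nuclei[nuclei["state"] == "myonucleus"]
    pooled: list[np.ndarray] = []
    rows = []
    for tid, g in mn.groupby("tube_id", sort=True):
        pos = g[["x_um", "y_um"]].to_numpy(dtype=float)
        if periodic_domain is not None and len(pos):
            pos = unwrap_positions(pos, *periodic_domain)
        dist = internuclear_distances(pos)
        if dist.size:
            pooled.append(dist)
            rows.append((tid, len(pos), float(dist.mean())))
    pooled_arr = np.concatenate(pooled) if pooled else np.array([])
    per_tube = pd.DataFrame(rows, columns=["tube_id", "n_nuclei", "d_mean"])
    return pooled_arr, per_tube


def _density(nuclei: pd.DataFrame, state: str, area_mm2: float) -> float:
    return float((nuclei["state"] == state).sum()) / area_mm2


def quality_indicators(day0: pd.DataFrame, day5: pd.DataFrame,
                       area_mm2: float,
                       periodic_domain: tuple[float, float] | None = None,
                       ) -> QualityIndicators:
    """Compute dM, D, D_var and fusion index from day-0/day-5 nuclei tables.

    dM is the myonuclei areal density difference (day 5 − day 0).
    Distances are pooled across all day-5 tubes before taking the mean D
    and the coefficient of variation D_var (sample SD, n−1).  When no
    day-5 tube holds two or more nuclei, D and D_var are NaN but dM is
    still returned.
    """
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be > 0")
    dm = (_density(day5, "myonucleus", area_mm2)
          - _density(day0, "myonucleus", area_mm2))
    pooled, per_tube = pooled_tube_distances(day5, periodic_domain)
    if pooled.size:
        d = float(pooled.mean())
        d_var = (float(pooled.std(ddof=1) / d)
                 if pooled.size >= 2 and d > 0 else 0.0)
    else:
        d = float("nan")
        d_var = float("nan")
    fi5 = fusion_index(int((day5["state"] == "myonucleus").sum()), len(day5))
    fi0 = fusion_index(int((day0["state"] == "myonucleus").sum()), len(day0))
    return QualityIndicators(dm=dm, d=d, d_var=d_var, fusion_index=fi5,
                             fusion_index_day0=fi0, per_tube=per_tube)


def quality_from_sim(out: SimOutput) -> QualityIndicators:
    """Quality indicators of a simulation run.

    dM comes from the recorded myonuclei density series (final − initial);
    D and D_var from the final snapshot with periodic unwrapping; the
    fusion index from the final counts.
    """
    dens = out.densities["myonuclei_per_mm2"]
    dm = float(dens.iloc[-1] - dens.iloc[0])
    domain = (out.params.domain_width, out.params.domain_height)
    pooled, per_tube = pooled_tube_distances(out.final_nuclei, domain)
    if pooled.size:
        d = float(pooled.mean())
        d_var = (float(pooled.std(ddof=1) / d)
                 if pooled.size >= 2 and d > 0 else 0.0)
    else:
        d = float("nan")
        d_var = float("nan")
    n_mb, n_mn = out.final_counts
    return QualityIndicators(dm=dm, d=d, d_var=d_var,
                             fusion_index=fusion_index(n_mn, n_mb + n_mn),
                             per_tube=per_tube)
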