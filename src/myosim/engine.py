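"""Off-lattice agent-based model of myoblast fusion and myonuclei positioning.

Agents are cell nuclei on a continuous, periodic 2-D domain.  Unfused
myoblasts perform a persistent random walk and divide; sustained contact
(a residence-time counter within a circular area of influence, AoI)
triggers fusion into multinucleated myotubes; myonuclei then obey an
overdamped force balance that pulls them toward the tube's major axis
(lateral spring) and spreads them along it (inverse-square lengthwise
repulsion).

The fixed per-step update order is: motion → proliferation → residence
clocks → fusion → mechanics.  All randomness flows from one seeded
``numpy`` generator, so identical ``(params, seed)`` give bit-identical
outputs including the fusion-event log.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .params import SimParams

logger = logging.getLogger(__name__)

__all__ = [
    "MYOBLAST",
    "MYONUCLEUS",
    "Myotube",
    "SimState",
    "SimOutput",
    "init_state",
    "step_motion",
    "step_proliferation",
    "update_residence_clocks",
    "apply_fusions",
    "step_mechanics",
    "step",
    "simulate",
    "simulate_tracks",
    "compute_major_axis",
    "lateral_force",
    "repulsion_force",
    "unwrap_positions",
    "state_to_nuclei_table",
]

MYOBLAST = 0
MYONUCLEUS = 1

# event kinds in the fusion log
MB_MT = "mb-mt"
MB_MB = "mb-mb"
MT_MT = "mt-mt"

_SEEDED_TUBE_SIZE = 5  # nuclei per seeded day-0 myotube


class ConsistencyError(RuntimeError):
    """A fusion request named an agent or tube that does not exist."""


@dataclass
class Myotube:
    """A myotube: an ordered set of member myonuclei and a formation time.

    The axis is the first principal direction of the member positions,
    recomputed once per step; ``axis_dir`` is ``None`` while degenerate
    (single member or coincident nuclei).
    """

    id: int
    members: list[int]
    formed_at: float
    axis_centroid: np.ndarray | None = None
    axis_dir: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class SimState:
    """Mutable simulation state (struct-of-arrays over nuclei).

    Nuclei are never removed, so a nucleus id is simply its array index.
    """

    params: SimParams
    rng: np.random.Generator
    time: float
    pos: np.ndarray          # (n, 2) μm, wrapped into [0, W) × [0, H)
    state: np.ndarray        # (n,) MYOBLAST | MYONUCLEUS
    heading: np.ndarray      # (n,) degrees, myoblasts only meaningful
    speed: np.ndarray        # (n,) μm·min⁻¹, drawn once at birth
    tube_id: np.ndarray      # (n,) int, -1 when unfused
    fused_at: np.ndarray     # (n,) minutes, nan when unfused
    tubes: dict[int, Myotube] = field(default_factory=dict)
    next_tube_id: int = 0
    # residence-time counters, minutes; rebuilt from current contacts each step
    clocks_mb_mb: dict[tuple[int, int], float] = field(default_factory=dict)
    clocks_mb_mt: dict[tuple[int, int], float] = field(default_factory=dict)
    clocks_mt_mt: dict[tuple[int, int], float] = field(default_factory=dict)
    fusion_queue: list[tuple[str, int, int]] = field(default_factory=list)
    events: list[tuple[float, str, int, int]] = field(default_factory=list)
    n_divisions: int = 0
    n_clamped: int = 0
    # memoised tube-membership arrays for the mechanics kernel; reset
    # whenever tube composition changes
    _mech_cache: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    def counts(self) -> tuple[int, int]:
        n_mn = int(np.count_nonzero(self.state == MYONUCLEUS))
        return self.n - n_mn, n_mn


@dataclass
class SimOutput:
    """Recorded output of one run.

    densities
        DataFrame (time_min, myoblast_per_mm2, myonuclei_per_mm2,
        cum_divisions) at the recording cadence.
    events
        DataFrame (time_min, kind, id_a, id_b); for mb–mt fusions id_b is
        the tube id, for mt–mt both ids are tube ids.
    final_nuclei
        Final snapshot in the nuclei-table dialect (day, nucleus_id,
        x_um, y_um, state, tube_id).
    """

    densities: pd.DataFrame
    events: pd.DataFrame
    final_nuclei: pd.DataFrame
    params: SimParams
    n_divisions: int
    n_clamped: int

    @property
    def final_counts(self) -> tuple[int, int]:
        n_mn = int((self.final_nuclei["state"] == "myonucleus").sum())
        return len(self.final_nuclei) - n_mn, n_mn


# ---------------------------------------------------------------------------
# geometry helpers

def _wrap(pos: np.ndarray, width: float, height: float) -> np.ndarray:
    pos[:, 0] %= width
    pos[:, 1] %= height
    return pos


def unwrap_positions(pos: np.ndarray, width: float, height: float,
                     ref: np.ndarray | None = None) -> np.ndarray:
    """Map positions to the periodic images nearest ``ref``.

    Valid while the object (a myotube) spans less than half the domain in
    each direction, which holds for the tube extents this model produces.
    """
    if ref is None:
        ref = pos[0]
    d = pos - ref
    d[:, 0] -= width * np.round(d[:, 0] / width)
    d[:, 1] -= height * np.round(d[:, 1] / height)
    return ref + d


def compute_major_axis(
    positions: np.ndarray,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Centroid and first principal direction of a 2-D point scatter.

    Returns ``(centroid, u)`` with ``u`` the unit leading eigenvector of
    the position covariance, sign-fixed to a non-negative x component
    (non-negative y on ties).  Degenerate scatters (fewer than two
    distinct points) return ``(centroid, None)``.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("positions must be an (n, 2) array")
    centroid = positions.mean(axis=0)
    centered = positions - centroid
    if positions.shape[0] < 2 or not np.any(np.abs(centered) > 1e-12):
        return centroid, None
    cov = centered.T @ centered / (positions.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, int(np.argmax(evals))]
    if u[0] < 0 or (u[0] == 0 and u[1] < 0):
        u = -u
    return centroid, u


def lateral_force(position: np.ndarray, centroid: np.ndarray,
                  axis_dir: np.ndarray | None, k_lat: float) -> np.ndarray:
    """Linear spring pulling a myonucleus perpendicularly onto the tube axis.

    ``f = -k_lat · d_perp`` where ``d_perp`` is the perpendicular offset
    from the axis line; a degenerate axis yields zero force.
    """
    if axis_dir is None:
        return np.zeros(2)
    r = np.asarray(position, dtype=float) - centroid
    perp = r - (r @ axis_dir) * axis_dir
    return -k_lat * perp


def repulsion_force(position: np.ndarray, others: np.ndarray,
                    axis_dir: np.ndarray | None, k_nuc: float,
                    min_separation: float) -> np.ndarray:
    """Lengthwise inverse-square repulsion from the other tube members.

    Each partner j contributes magnitude ``k_nuc / max(d_ij, d_min)²``
    directed away from j, projected onto the tube axis; the returned
    force is the sum.  With no partners or a degenerate axis the force
    is zero.
    """
    others = np.asarray(others, dtype=float).reshape(-1, 2)
    if others.shape[0] == 0 or axis_dir is None:
        return np.zeros(2)
    diff = np.asarray(position, dtype=float) - others
    dist = np.hypot(diff[:, 0], diff[:, 1])
    safe = np.maximum(dist, 1e-300)
    unit = diff / safe[:, None]
    unit[dist == 0.0] = 0.0  # coincident partner: no defined direction
    mag = k_nuc / np.maximum(dist, min_separation) ** 2
    axial = (unit @ axis_dir) * mag
    return float(axial.sum()) * axis_dir


# ---------------------------------------------------------------------------
# initialisation

def _append_agents(st: SimState, pos, state, heading, speed, tube, fused):
    st.pos = np.vstack([st.pos, pos])
    st.state = np.concatenate([st.state, state])
    st.heading = np.concatenate([st.heading, heading])
    st.speed = np.concatenate([st.speed, speed])
    st.tube_id = np.concatenate([st.tube_id, tube])
    st.fused_at = np.concatenate([st.fused_at, fused])


def _draw_speeds(rng: np.random.Generator, n: int, mean: float,
                 sd: float) -> np.ndarray:
    """Per-cell speeds ~ Normal(mean, sd) truncated at 0 (by redraw)."""
    if sd == 0.0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = out < 0.0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < 0.0
    return out


def init_state(params: SimParams) -> SimState:
    """Seed the domain with myoblasts and (optionally) pre-formed myotubes.

    ``n_myoblasts_t0`` nuclei total; a fraction ``myotube_proportion_t0``
    are seeded as myonuclei grouped into small tubes (chains of up to
    five nuclei at AoI spacing along a random orientation, anchored
    uniformly at random); the rest are myoblasts placed uniformly with
    uniform headings and per-cell truncated-normal speeds.
    """
    rng = np.random.default_rng(params.seed)
    W, H = params.domain_width, params.domain_height
    n_total = params.n_myoblasts_t0
    n_mn = int(round(params.myotube_proportion_t0 * n_total))
    n_mb = n_total - n_mn

    st = SimState(
        params=params, rng=rng, time=0.0,
        pos=np.empty((0, 2)), state=np.empty(0, dtype=np.int8),
        heading=np.empty(0), speed=np.empty(0),
        tube_id=np.empty(0, dtype=np.int64), fused_at=np.empty(0),
    )

    if n_mb > 0:
        pos = rng.uniform([0, 0], [W, H], size=(n_mb, 2))
        _append_agents(
            st, pos,
            np.full(n_mb, MYOBLAST, dtype=np.int8),
            rng.uniform(0.0, 360.0, size=n_mb),
            _draw_speeds(rng, n_mb, params.behaviour.s_mb_mean,
                         params.behaviour.s_mb_sd),
            np.full(n_mb, -1, dtype=np.int64),
            np.full(n_mb, np.nan),
        )

    # seeded tubes: chains of nuclei along random axes
    remaining = n_mn
    spacing = params.fusion.aoi_radius
    while remaining > 0:
        size = min(_SEEDED_TUBE_SIZE, remaining)
        remaining -= size
        anchor = rng.uniform([0, 0], [W, H])
        theta = rng.uniform(0.0, 2 * math.pi)
        u = np.array([math.cos(theta), math.sin(theta)])
        offsets = np.arange(size)[:, None] * spacing * u
        pos = _wrap(anchor + offsets, W, H)
        tid = st.next_tube_id
        st.next_tube_id += 1
        first = st.n
        _append_agents(
            st, pos,
            np.full(size, MYONUCLEUS, dtype=np.int8),
            np.zeros(size),
            _draw_speeds(rng, size, params.behaviour.s_mb_mean,
                         params.behaviour.s_mb_sd),
            np.full(size, tid, dtype=np.int64),
            np.zeros(size),
        )
        st.tubes[tid] = Myotube(id=tid,
                                members=list(range(first, first + size)),
                                formed_at=0.0)
    return st


# ---------------------------------------------------------------------------
# per-step updates

def step_motion(st: SimState) -> SimState:
    """Persistent random walk: turn by Normal(0, ω_mb·dt), advance speed·dt."""
    p = st.params
    mb = st.state == MYOBLAST
    n_mb = int(mb.sum())
    if n_mb == 0:
        return st
    if p.behaviour.omega_mb_sd > 0.0:
        st.heading[mb] += st.rng.normal(
            0.0, p.behaviour.omega_mb_sd * p.dt, size=n_mb)
    rad = np.deg2rad(st.heading[mb])
    disp = (st.speed[mb] * p.dt)[:, None] * np.column_stack(
        [np.cos(rad), np.sin(rad)])
    st.pos[mb] += disp
    _wrap(st.pos, p.domain_width, p.domain_height)
    return st


def step_proliferation(st: SimState) -> SimState:
    """Each myoblast divides independently with probability p_rate·dt.

    The daughter is a fresh myoblast (new heading and speed draw) placed
    one AoI radius away in a uniform random direction; no agent ever
    dies.
    """
    p = st.params
    prob = p.behaviour.p_rate * p.dt
    if prob == 0.0:
        return st
    mb_idx = np.flatnonzero(st.state == MYOBLAST)
    if mb_idx.size == 0:
        return st
    dividing = mb_idx[st.rng.random(mb_idx.size) < prob]
    k = dividing.size
    if k == 0:
        return st
    theta = st.rng.uniform(0.0, 2 * math.pi, size=k)
    offset = p.fusion.aoi_radius * np.column_stack(
        [np.cos(theta), np.sin(theta)])
    pos = _wrap(st.pos[dividing] + offset, p.domain_width, p.domain_height)
    _append_agents(
        st, pos,
        np.full(k, MYOBLAST, dtype=np.int8),
        st.rng.uniform(0.0, 360.0, size=k),
        _draw_speeds(st.rng, k, p.behaviour.s_mb_mean, p.behaviour.s_mb_sd),
        np.full(k, -1, dtype=np.int64),
        np.full(k, np.nan),
    )
    st.n_divisions += k
    return st


@numba.njit(cache=True)
def _pairs_kernel(pos, W, H, r):
    """Exhaustive periodic (minimum-image) neighbour search, (m, 2)."""
    n = pos.shape[0]
    cap = 16 + 8 * n
    out = np.empty((cap, 2), dtype=np.int64)
    m = 0
    r2 = r * r
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        for j in range(i + 1, n):
            dx = abs(xi - pos[j, 0])
            dy = abs(yi - pos[j, 1])
            if W - dx < dx:
                dx = W - dx
            if H - dy < dy:
                dy = H - dy
            if dx * dx + dy * dy <= r2:
                if m == cap:
                    cap *= 2
                    bigger = np.empty((cap, 2), dtype=np.int64)
                    bigger[:m] = out
                    out = bigger
                out[m, 0] = i
                out[m, 1] = j
                m += 1
    return out[:m].copy()


def _contact_pairs(st: SimState) -> np.ndarray:
    """All nucleus pairs within one AoI radius (periodic metric), (m, 2).

    Small populations use an exhaustive minimum-image search (cheaper
    than building a KD-tree every step); larger ones a periodic cKDTree.
    Pair enumeration order is irrelevant downstream: the clock update
    sorts keys before advancing them.
    """
    p = st.params
    r = p.fusion.aoi_radius
    n = st.n
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)
    if n <= 600:
        return _pairs_kernel(st.pos, p.domain_width, p.domain_height, r)
    tree = cKDTree(st.pos, boxsize=[p.domain_width, p.domain_height])
    return tree.query_pairs(r, output_type="ndarray")


def update_residence_clocks(st: SimState) -> SimState:
    """Advance residence counters for pairs in contact; reset the rest.

    Eligible pairs: myoblast–myotube (the myoblast within one AoI radius
    of any member myonucleus), myoblast–myoblast when enabled, and
    myotube–myotube (any cross-pair of members in contact).  A pair
    whose counter crosses t_rmax queues exactly one fusion request.
    """
    p = st.params
    dt = p.dt
    t_rmax = p.fusion.t_rmax
    if not math.isfinite(t_rmax):
        # fusion disabled: no counter can ever reach the threshold
        st.clocks_mb_mb.clear()
        st.clocks_mb_mt.clear()
        st.clocks_mt_mt.clear()
        return st
    pairs = _contact_pairs(st)

    keys_mb_mb: list[tuple[int, int]] = []
    keys_mb_mt: set[tuple[int, int]] = set()
    keys_mt_mt: set[tuple[int, int]] = set()
    if pairs.size:
        si = st.state[pairs[:, 0]]
        sj = st.state[pairs[:, 1]]
        if p.fusion.allow_mb_mb_fusion:
            both_mb = (si == MYOBLAST) & (sj == MYOBLAST)
            keys_mb_mb = list(map(tuple, pairs[both_mb].tolist()))
        mixed_i = (si == MYOBLAST) & (sj == MYONUCLEUS)
        mixed_j = (si == MYONUCLEUS) & (sj == MYOBLAST)
        mb_side = np.concatenate([pairs[mixed_i, 0], pairs[mixed_j, 1]])
        mt_side = st.tube_id[
            np.concatenate([pairs[mixed_i, 1], pairs[mixed_j, 0]])]
        keys_mb_mt.update(zip(mb_side.tolist(), mt_side.tolist()))
        both_mn = (si == MYONUCLEUS) & (sj == MYONUCLEUS)
        ta = st.tube_id[pairs[both_mn, 0]]
        tb = st.tube_id[pairs[both_mn, 1]]
        cross = ta != tb
        lo = np.minimum(ta[cross], tb[cross])
        hi = np.maximum(ta[cross], tb[cross])
        keys_mt_mt.update(zip(lo.tolist(), hi.tolist()))

    queue = st.fusion_queue

    def _advance(old: dict, keys, kind: str) -> dict:
        new: dict[tuple[int, int], float] = {}
        for key in sorted(keys):
            t_old = old.get(key, 0.0)
            t_new = t_old + dt
            new[key] = t_new
            if t_old < t_rmax <= t_new:
                queue.append((kind, key[0], key[1]))
        return new

    st.clocks_mb_mb = _advance(st.clocks_mb_mb, keys_mb_mb, MB_MB)
    st.clocks_mb_mt = _advance(st.clocks_mb_mt, keys_mb_mt, MB_MT)
    st.clocks_mt_mt = _advance(st.clocks_mt_mt, keys_mt_mt, MT_MT)
    return st


def _remap_tube_clocks(st: SimState, old: int, new: int) -> None:
    """After a merge, carry residence counters over to the surviving tube."""
    mb_mt: dict[tuple[int, int], float] = {}
    for (mb, tid), v in st.clocks_mb_mt.items():
        tid2 = new if tid == old else tid
        mb_mt[(mb, tid2)] = max(v, mb_mt.get((mb, tid2), 0.0))
    st.clocks_mb_mt = mb_mt
    mt_mt: dict[tuple[int, int], float] = {}
    for (ta, tb), v in st.clocks_mt_mt.items():
        ta2 = new if ta == old else ta
        tb2 = new if tb == old else tb
        if ta2 == tb2:
            continue
        key = (min(ta2, tb2), max(ta2, tb2))
        mt_mt[key] = max(v, mt_mt.get(key, 0.0))
    st.clocks_mt_mt = mt_mt


def apply_fusions(st: SimState) -> SimState:
    """Consume the fusion queue, conserving the total nucleus count.

    mb–mt: the myoblast joins the tube as a myonucleus.  mb–mb: both
    found a new two-nucleus tube.  mt–mt: the tubes merge if the
    initiating (younger) tube's age is at most t_MTfuse; the merged
    tube keeps the earlier formation time.  Requests made stale by an
    earlier fusion in the same step are dropped; requests naming ids
    that never existed raise :class:`ConsistencyError`.
    """
    p = st.params
    now = st.time
    if st.fusion_queue:
        st._mech_cache = None
    merged_into: dict[int, int] = {}

    def _resolve(tid: int) -> int | None:
        seen = set()
        while tid in merged_into:
            if tid in seen:  # pragma: no cover - defensive
                return None
            seen.add(tid)
            tid = merged_into[tid]
        return tid if tid in st.tubes else None

    for kind, a, b in st.fusion_queue:
        if kind == MB_MB:
            if a >= st.n or b >= st.n:
                raise ConsistencyError(f"fusion names missing nucleus "
                                       f"{max(a, b)}")
            if st.state[a] != MYOBLAST or st.state[b] != MYOBLAST:
                continue  # one partner fused earlier this step
            tid = st.next_tube_id
            st.next_tube_id += 1
            st.tubes[tid] = Myotube(id=tid, members=[a, b], formed_at=now)
            for i in (a, b):
                st.state[i] = MYONUCLEUS
                st.tube_id[i] = tid
                st.fused_at[i] = now
            st.events.append((now, MB_MB, a, b))
        elif kind == MB_MT:
            if a >= st.n:
                raise ConsistencyError(f"fusion names missing nucleus {a}")
            tid = _resolve(b)
            if tid is None:
                if b >= st.next_tube_id:
                    raise ConsistencyError(f"fusion names missing tube {b}")
                continue
            if st.state[a] != MYOBLAST:
                continue
            tube = st.tubes[tid]
            tube.members.append(a)
            st.state[a] = MYONUCLEUS
            st.tube_id[a] = tid
            st.fused_at[a] = now
            st.events.append((now, MB_MT, a, tid))
        elif kind == MT_MT:
            ta, tb = _resolve(a), _resolve(b)
            if ta is None or tb is None or ta == tb:
                if (a >= st.next_tube_id) or (b >= st.next_tube_id):
                    raise ConsistencyError(
                        f"fusion names missing tube {max(a, b)}")
                continue
            tube_a, tube_b = st.tubes[ta], st.tubes[tb]
            # the initiating tube is the younger of the pair
            young, old_t = ((tube_a, tube_b)
                            if tube_a.formed_at >= tube_b.formed_at
                            else (tube_b, tube_a))
            if now - young.formed_at > p.fusion.t_mtfuse_minutes:
                continue  # merge refused: initiating tube too old
            old_t.members.extend(young.members)
            st.tube_id[young.members] = old_t.id
            del st.tubes[young.id]
            merged_into[young.id] = old_t.id
            _remap_tube_clocks(st, young.id, old_t.id)
            st.events.append((now, MT_MT, young.id, old_t.id))
        else:  # pragma: no cover - defensive
            raise ConsistencyError(f"unknown fusion kind {kind!r}")
    st.fusion_queue = []
    return st


@numba.njit(cache=True)
def _mechanics_kernel(pos, members, offsets, W, H, k_lat, k_nuc,
                      min_sep, mob_dt, max_disp, centroids, axes, axis_ok):
    """Per-tube axis recomputation and force-balance update (fast path).

    ``members``/``offsets`` hold the concatenated member indices of the
    tubes in id order; positions are updated in place and the per-tube
    axes written to ``centroids``/``axes``/``axis_ok``.  Returns the
    number of clamped (instability-limited) displacements.  Numerics
    match the reference ``compute_major_axis`` / ``lateral_force`` /
    ``repulsion_force`` functions.
    """
    n_clamped = 0
    n_tubes = offsets.shape[0] - 1
    for t in range(n_tubes):
        s, e = offsets[t], offsets[t + 1]
        m = e - s
        refx = pos[members[s], 0]
        refy = pos[members[s], 1]
        px = np.empty(m)
        py = np.empty(m)
        for i in range(m):
            dx = pos[members[s + i], 0] - refx
            dy = pos[members[s + i], 1] - refy
            dx -= W * np.round(dx / W)
            dy -= H * np.round(dy / H)
            px[i] = refx + dx
            py[i] = refy + dy
        cx = px.mean()
        cy = py.mean()
        centroids[t, 0] = cx
        centroids[t, 1] = cy
        axis_ok[t] = False
        if m < 2:
            continue
        # 2x2 covariance and its leading eigenvector, closed form
        a = 0.0
        b = 0.0
        c = 0.0
        for i in range(m):
            ddx = px[i] - cx
            ddy = py[i] - cy
            a += ddx * ddx
            b += ddx * ddy
            c += ddy * ddy
        a /= m - 1
        b /= m - 1
        c /= m - 1
        lam = 0.5 * (a + c) + np.sqrt(0.25 * (a - c) ** 2 + b * b)
        if lam <= 1e-20:
            continue  # coincident nuclei: degenerate axis
        if abs(b) > 1e-300:
            ux = lam - c
            uy = b
        elif a >= c:
            ux = 1.0
            uy = 0.0
        else:
            ux = 0.0
            uy = 1.0
        norm = np.sqrt(ux * ux + uy * uy)
        if norm == 0.0:  # b ~ 0 and lam == c: axis along y
            ux, uy, norm = 0.0, 1.0, 1.0
        ux /= norm
        uy /= norm
        if ux < 0.0 or (ux == 0.0 and uy < 0.0):
            ux = -ux
            uy = -uy
        axes[t, 0] = ux
        axes[t, 1] = uy
        axis_ok[t] = True
        if k_lat == 0.0 and k_nuc == 0.0:
            continue
        dispx = np.empty(m)
        dispy = np.empty(m)
        for i in range(m):
            rx = px[i] - cx
            ry = py[i] - cy
            axial = rx * ux + ry * uy
            fx = -k_lat * (rx - axial * ux)
            fy = -k_lat * (ry - axial * uy)
            fn = 0.0
            for j in range(m):
                if j == i:
                    continue
                dx = px[i] - px[j]
                dy = py[i] - py[j]
                dist = np.sqrt(dx * dx + dy * dy)
                if dist > 0.0:
                    ua = (dx * ux + dy * uy) / dist
                    md = dist if dist > min_sep else min_sep
                    fn += ua * k_nuc / (md * md)
            fx += fn * ux
            fy += fn * uy
            dispx[i] = mob_dt * fx
            dispy[i] = mob_dt * fy
            dnorm = np.sqrt(dispx[i] ** 2 + dispy[i] ** 2)
            if dnorm > max_disp:
                n_clamped += 1
                dispx[i] *= max_disp / dnorm
                dispy[i] *= max_disp / dnorm
        for i in range(m):
            pos[members[s + i], 0] = (px[i] + dispx[i]) % W
            pos[members[s + i], 1] = (py[i] + dispy[i]) % H
    return n_clamped


def step_mechanics(st: SimState) -> SimState:
    """Overdamped explicit-Euler update of myonuclei positions.

    Per tube: recompute the major axis from current member positions
    (minimum-image unwrapped), then displace each member by
    ``mobility · (f_lat + f_nuc) · dt``.  Displacements exceeding one
    AoI radius are clamped and counted as instability warnings.
    """
    p = st.params
    mech = p.mechanics
    if not st.tubes:
        return st
    if st._mech_cache is None:
        tids = sorted(st.tubes)
        members = np.concatenate(
            [np.asarray(st.tubes[t].members, dtype=np.int64) for t in tids])
        sizes = np.array([st.tubes[t].n for t in tids], dtype=np.int64)
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        st._mech_cache = (tids, members, offsets)
    else:
        tids, members, offsets = st._mech_cache
    centroids = np.empty((len(tids), 2))
    axes = np.empty((len(tids), 2))
    axis_ok = np.zeros(len(tids), dtype=np.bool_)
    n_bad = _mechanics_kernel(
        st.pos, members, offsets, p.domain_width, p.domain_height,
        mech.k_lat, mech.k_nuc, mech.min_separation,
        mech.mobility * p.dt, p.fusion.aoi_radius,
        centroids, axes, axis_ok)
    for k, tid in enumerate(tids):
        tube = st.tubes[tid]
        tube.axis_centroid = centroids[k]
        tube.axis_dir = axes[k] if axis_ok[k] else None
    if n_bad:
        if st.n_clamped == 0:
            logger.warning(
                "mechanics step displacement exceeded one AoI radius at "
                "t=%.0f min; clamped (consider reducing dt or force "
                "coefficients)", st.time)
        st.n_clamped += n_bad
    return st


def step(st: SimState) -> SimState:
    """One full time step in the fixed update order."""
    st.time += st.params.dt
    step_motion(st)
    step_proliferation(st)
    update_residence_clocks(st)
    apply_fusions(st)
    step_mechanics(st)
    return st


def simulate_tracks(params: SimParams, n_frames: int) -> pd.DataFrame:
    """Motion-only run that records unwrapped trajectories per myoblast.

    Runs the same initialisation and per-step motion sampling as
    :func:`simulate` (no proliferation, fusion or mechanics) and returns
    a trajectory table in the track CSV dialect.  Coordinates are
    cumulative (unwrapped), so step displacements measured from the
    table equal the walk's true steps — what a tracking pipeline on an
    unbounded field of view would report.
    """
    st = init_state(params)
    mb = st.state == MYOBLAST
    idx = np.flatnonzero(mb)
    traj = np.empty((n_frames, idx.size, 2))
    traj[0] = st.pos[idx]
    unwrapped = st.pos[idx].copy()
    for frame in range(1, n_frames):
        before = st.pos[idx].copy()
        step_motion(st)
        d = st.pos[idx] - before
        # undo the periodic wrap on the recorded displacement
        d[:, 0] -= params.domain_width * np.round(d[:, 0] / params.domain_width)
        d[:, 1] -= params.domain_height * np.round(
            d[:, 1] / params.domain_height)
        unwrapped += d
        traj[frame] = unwrapped
    frames = np.arange(n_frames)
    rows = {
        "frame": np.tile(frames, idx.size),
        "time_min": np.tile(frames * params.dt, idx.size),
        "track_id": np.repeat(np.arange(idx.size), n_frames),
        "x_um": traj[:, :, 0].T.ravel(),
        "y_um": traj[:, :, 1].T.ravel(),
    }
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# output

def state_to_nuclei_table(st: SimState, day: int | None = None) -> pd.DataFrame:
    """Snapshot in the nuclei-table CSV dialect."""
    if day is None:
        day = int(round(st.time / 1440.0))
    is_mn = st.state == MYONUCLEUS
    return pd.DataFrame({
        "day": day,
        "nucleus_id": np.arange(st.n),
        "x_um": st.pos[:, 0],
        "y_um": st.pos[:, 1],
        "state": np.where(is_mn, "myonucleus", "myoblast"),
        "tube_id": np.where(is_mn, st.tube_id, pd.NA),
    })


def simulate(params: SimParams) -> SimOutput:
    """Run the full model and record density series, events and a snapshot.

    Densities (per mm²) are recorded at t = 0, every ``record_every``
    minutes, and at the final time.
    """
    st = init_state(params)
    n_steps = int(round(params.duration / params.dt))
    area = params.area_mm2
    records = []

    def _record():
        n_mb, n_mn = st.counts()
        records.append((st.time, n_mb / area, n_mn / area, st.n_divisions))

    _record()
    next_record = params.record_every
    for _ in range(n_steps):
        step(st)
        if st.time + 1e-9 >= next_record:
            _record()
            while next_record <= st.time + 1e-9:
                next_record += params.record_every
    if records[-1][0] < st.time:
        _record()

    densities = pd.DataFrame(
        records, columns=["time_min", "myoblast_per_mm2",
                          "myonuclei_per_mm2", "cum_divisions"])
    events = pd.DataFrame(
        st.events, columns=["time_min", "kind", "id_a", "id_b"])
    return SimOutput(
        densities=densities,
        events=events,
        final_nuclei=state_to_nuclei_table(st),
        params=params,
        n_divisions=st.n_divisions,
        n_clamped=st.n_clamped,
    )
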