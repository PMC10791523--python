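import dataclasses

import numpy as np
import pytest

from myosim import FusionParams, MechanicsParams, SimParams
from myosim.engine import (MYOBLAST, MYONUCLEUS, Myotube, _append_agents,
                           _mechanics_kernel, apply_fusions,
                           compute_major_axis, init_state, lateral_force,
                           repulsion_force, simulate, step_mechanics,
                           step_motion, step_proliferation,
                           update_residence_clocks)
from myosim.params import BehaviourMetrics


def make_state(params, myoblasts=(), tubes=()):
    """Forge a state with explicit myoblasts (x, y, heading, speed) and
    myotubes (list of member positions)."""
    st = init_state(dataclasses.replace(params, n_myoblasts_t0=0,
                                        myotube_proportion_t0=0.0))
    for x, y, heading, speed in myoblasts:
        _append_agents(st, np.array([[x, y]], dtype=float),
                       np.array([MYOBLAST], dtype=np.int8),
                       np.array([heading], dtype=float),
                       np.array([speed], dtype=float),
                       np.array([-1], dtype=np.int64),
                       np.array([np.nan]))
    for members in tubes:
        tid = st.next_tube_id
        st.next_tube_id += 1
        first = st.n
        pos = np.asarray(members, dtype=float)
        k = len(pos)
        _append_agents(st, pos,
                       np.full(k, MYONUCLEUS, dtype=np.int8),
                       np.zeros(k), np.zeros(k),
                       np.full(k, tid, dtype=np.int64),
                       np.zeros(k))
        st.tubes[tid] = Myotube(id=tid,
                                members=list(range(first, first + k)),
                                formed_at=0.0)
    return st


# ---------------------------------------------------------------------------
# initialisation

def test_no_seeded_tubes_means_no_myonuclei(small_params):
    p = dataclasses.replace(small_params, myotube_proportion_t0=0.0)
    st = init_state(p)
    assert st.counts() == (p.n_myoblasts_t0, 0)
    assert not st.tubes


def test_init_is_deterministic(small_params):
    a, b = init_state(small_params), init_state(small_params)
    np.testing.assert_array_equal(a.pos, b.pos)
    np.testing.assert_array_equal(a.state, b.state)
    np.testing.assert_array_equal(a.heading, b.heading)
    assert sorted(a.tubes) == sorted(b.tubes)


def test_initial_density_is_count_over_area():
    p = SimParams(domain_width=1000.0, domain_height=1000.0,
                  n_myoblasts_t0=200, myotube_proportion_t0=0.0,
                  duration=60.0)
    out = simulate(p)
    assert out.densities.loc[0, "myoblast_per_mm2"] == pytest.approx(200.0)
    assert out.densities.loc[0, "myonuclei_per_mm2"] == 0.0


def test_seeded_myonuclei_belong_to_tubes(small_params):
    st = init_state(small_params)
    n_mn = int((st.state == MYONUCLEUS).sum())
    assert n_mn == round(small_params.myotube_proportion_t0
                         * small_params.n_myoblasts_t0)
    assert sum(t.n for t in st.tubes.values()) == n_mn
    for tid, tube in st.tubes.items():
        assert all(st.tube_id[m] == tid for m in tube.members)


# ---------------------------------------------------------------------------
# motion

def test_zero_turning_noise_gives_straight_path(small_params):
    p = dataclasses.replace(
        small_params,
        behaviour=BehaviourMetrics(s_mb_mean=0.4, s_mb_sd=0.0,
                                   omega_mb_sd=0.0, p_rate=0.0))
    st = make_state(p, myoblasts=[(200.0, 200.0, 30.0, 0.4)])
    start = st.pos[0].copy()
    for _ in range(10):
        step_motion(st)
    rad = np.deg2rad(30.0)
    expected = start + 10 * 0.4 * p.dt * np.array([np.cos(rad), np.sin(rad)])
    np.testing.assert_allclose(st.pos[0], expected, atol=1e-9)


def test_zero_speed_leaves_positions_unchanged(small_params):
    st = make_state(small_params, myoblasts=[(50.0, 60.0, 10.0, 0.0)])
    before = st.pos.copy()
    step_motion(st)
    np.testing.assert_array_equal(st.pos, before)


def test_mean_step_length_matches_speed_distribution(small_params):
    """Monte-Carlo: empirical mean step / dt within 2 SE of the truncated
    per-cell speed draw's sample mean."""
    p = dataclasses.replace(small_params, n_myoblasts_t0=500,
                            myotube_proportion_t0=0.0, seed=3)
    st = init_state(p)
    drawn_mean = st.speed.mean()
    lengths = []
    for _ in range(288):
        before = st.pos.copy()
        step_motion(st)
        d = st.pos - before
        d[:, 0] -= p.domain_width * np.round(d[:, 0] / p.domain_width)
        d[:, 1] -= p.domain_height * np.round(d[:, 1] / p.domain_height)
        lengths.append(np.hypot(d[:, 0], d[:, 1]) / p.dt)
    lengths = np.concatenate(lengths)
    # step length equals the per-cell speed exactly; compare to the draw
    assert lengths.mean() == pytest.approx(drawn_mean, abs=1e-12)
    se = p.behaviour.s_mb_sd / np.sqrt(500)
    assert abs(drawn_mean - p.behaviour.s_mb_mean) < 2 * se + 0.01


# ---------------------------------------------------------------------------
# proliferation

def test_zero_proliferation_keeps_count_constant(small_params):
    p = dataclasses.replace(
        small_params,
        behaviour=dataclasses.replace(small_params.behaviour, p_rate=0.0))
    st = init_state(p)
    n0 = st.n
    for _ in range(50):
        step_proliferation(st)
    assert st.n == n0


def test_daughters_are_always_myoblasts(small_params):
    p = dataclasses.replace(
        small_params,
        behaviour=dataclasses.replace(small_params.behaviour, p_rate=5e-3))
    st = init_state(p)
    n0 = st.n
    for _ in range(20):
        step_proliferation(st)
    assert st.n > n0
    assert np.all(st.state[n0:] == MYOBLAST)
    assert st.n == n0 + st.n_divisions


def test_mean_growth_matches_branching_expectation():
    """Mean final count over replicates within 3 SE of N0 * exp(p*T)."""
    p_rate, T, n0 = 2e-4, 1440.0, 100
    p = SimParams(behaviour=BehaviourMetrics(p_rate=p_rate),
                  fusion=FusionParams(t_rmax=float("inf")),
                  mechanics=MechanicsParams(k_lat=0.0, k_nuc=0.0),
                  domain_width=500.0, domain_height=500.0,
                  duration=T, n_myoblasts_t0=n0, seed=0)
    finals = []
    for s in range(80):
        out = simulate(dataclasses.replace(p, seed=s))
        finals.append(sum(out.final_counts))
    finals = np.array(finals, dtype=float)
    expected = n0 * np.exp(p_rate * T)
    se = finals.std(ddof=1) / np.sqrt(len(finals))
    assert abs(finals.mean() - expected) < 3 * se


# ---------------------------------------------------------------------------
# residence clocks and fusion

def test_clock_accumulates_while_in_contact(small_params):
    st = make_state(small_params,
                    myoblasts=[(100.0, 100.0, 0.0, 0.0)],
                    tubes=[[(105.0, 100.0), (120.0, 100.0)]])
    for k in range(3):
        update_residence_clocks(st)
        assert st.clocks_mb_mt[(0, 0)] == pytest.approx((k + 1)
                                                        * small_params.dt)


def test_clock_resets_on_separation(small_params):
    st = make_state(small_params,
                    myoblasts=[(100.0, 100.0, 0.0, 0.0)],
                    tubes=[[(105.0, 100.0), (120.0, 100.0)]])
    update_residence_clocks(st)
    assert st.clocks_mb_mt[(0, 0)] > 0
    st.pos[0] = [300.0, 300.0]  # move far out of contact
    update_residence_clocks(st)
    assert (0, 0) not in st.clocks_mb_mt
    st.fusion_queue.clear()


def test_never_in_contact_never_fuses(small_params):
    st = make_state(small_params,
                    myoblasts=[(50.0, 50.0, 0.0, 0.0)],
                    tubes=[[(300.0, 300.0), (315.0, 300.0)]])
    for _ in range(30):
        update_residence_clocks(st)
        apply_fusions(st)
    assert st.counts() == (1, 2)
    assert not st.events


def test_threshold_crossing_queues_exactly_one_fusion(small_params):
    # t_rmax = 30 min, dt = 5 -> 6 steps to cross; one event only
    st = make_state(small_params,
                    myoblasts=[(100.0, 100.0, 0.0, 0.0)],
                    tubes=[[(105.0, 100.0), (120.0, 100.0)]])
    for _ in range(6):
        update_residence_clocks(st)
    assert st.fusion_queue == [("mb-mt", 0, 0)]
    for _ in range(5):  # staying in contact must not re-queue
        update_residence_clocks(st)
    assert st.fusion_queue == [("mb-mt", 0, 0)]


def test_mb_mt_fusion_conserves_total_count(small_params):
    st = make_state(small_params,
                    myoblasts=[(100.0, 100.0, 0.0, 0.0)],
                    tubes=[[(105.0, 100.0), (120.0, 100.0)]])
    st.fusion_queue = [("mb-mt", 0, 0)]
    n_mb0, n_mn0 = st.counts()
    apply_fusions(st)
    assert st.counts() == (n_mb0 - 1, n_mn0 + 1)
    assert st.tube_id[0] == 0 and 0 in st.tubes[0].members


def test_old_initiating_tube_refuses_merge(small_params):
    st = make_state(small_params,
                    tubes=[[(100.0, 100.0), (110.0, 100.0)],
                           [(118.0, 100.0), (128.0, 100.0)]])
    st.time = small_params.fusion.t_mtfuse_minutes + small_params.dt
    # both tubes formed at t=0: initiating (younger) tube is too old
    st.fusion_queue = [("mt-mt", 0, 1)]
    apply_fusions(st)
    assert len(st.tubes) == 2 and not st.events


def test_merge_unions_members_without_duplicates(small_params):
    st = make_state(small_params,
                    tubes=[[(100.0, 100.0), (110.0, 100.0)],
                           [(118.0, 100.0), (128.0, 100.0)]])
    st.tubes[1].formed_at = 60.0  # tube 1 is younger, initiates
    st.time = 120.0
    st.fusion_queue = [("mt-mt", 0, 1)]
    apply_fusions(st)
    assert list(st.tubes) == [0]
    members = st.tubes[0].members
    assert sorted(members) == [0, 1, 2, 3]
    assert len(set(members)) == 4
    assert st.tubes[0].formed_at == 0.0
    assert np.all(st.tube_id[[0, 1, 2, 3]] == 0)


# ---------------------------------------------------------------------------
# axis and forces

def test_collinear_points_on_x_axis():
    centroid, u = compute_major_axis(
        np.array([[0.0, 2.0], [1.0, 2.0], [4.0, 2.0]]))
    np.testing.assert_allclose(centroid, [5.0 / 3.0, 2.0])
    np.testing.assert_allclose(u, [1.0, 0.0], atol=1e-12)


def test_diagonal_symmetry_gives_diagonal_axis():
    pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0],
                    [1.5, 1.3], [1.3, 1.5]])
    _, u = compute_major_axis(pts)
    np.testing.assert_allclose(u, [1.0, 1.0] / np.sqrt(2.0), atol=1e-12)


def test_coincident_points_are_degenerate():
    centroid, u = compute_major_axis(np.array([[3.0, 4.0]] * 4))
    assert u is None
    np.testing.assert_allclose(centroid, [3.0, 4.0])


def test_major_axis_matches_dense_eigensolver(rng):
    for _ in range(100):
        pts = rng.normal(size=(6, 2)) * rng.uniform(0.5, 20.0)
        centroid, u = compute_major_axis(pts)
        cov = np.cov(pts.T, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        ref = evecs[:, np.argmax(evals)]
        if ref[0] < 0 or (ref[0] == 0 and ref[1] < 0):
            ref = -ref
        np.testing.assert_allclose(centroid, pts.mean(axis=0), atol=1e-9)
        np.testing.assert_allclose(u, ref, atol=1e-9)


def test_lateral_force_examples():
    mech = MechanicsParams(k_lat=0.5, k_nuc=0.0)
    centroid = np.array([0.0, 0.0])
    u = np.array([1.0, 0.0])
    # on-axis nucleus: zero force
    np.testing.assert_allclose(
        lateral_force(np.array([3.0, 0.0]), centroid, u, mech.k_lat), 0.0)
    # k_lat = 0.5, d_perp = 4 -> magnitude 2 toward the axis
    f = lateral_force(np.array([1.0, 4.0]), centroid, u, mech.k_lat)
    np.testing.assert_allclose(f, [0.0, -2.0], atol=1e-12)
    # mirror-image nuclei get opposite forces
    g = lateral_force(np.array([1.0, -4.0]), centroid, u, mech.k_lat)
    np.testing.assert_allclose(f, -g, atol=1e-12)
    # degenerate axis: zero force
    assert np.all(lateral_force(np.array([1.0, 4.0]), centroid, None, 0.5)
                  == 0.0)


def test_repulsion_force_examples():
    u = np.array([1.0, 0.0])
    # no partners -> zero
    assert np.all(repulsion_force(np.array([0.0, 0.0]), np.empty((0, 2)),
                                  u, 0.5, 1.0) == 0.0)
    # middle of three equally spaced collinear nuclei -> net zero
    f = repulsion_force(np.array([10.0, 0.0]),
                        np.array([[0.0, 0.0], [20.0, 0.0]]), u, 0.7, 1.0)
    np.testing.assert_allclose(f, 0.0, atol=1e-15)


def test_repulsion_matches_bruteforce_double_loop(rng):
    for _ in range(100):
        n = int(rng.integers(2, 7))
        t = np.sort(rng.uniform(0.0, 60.0, size=n))
        theta = rng.uniform(0.0, 2 * np.pi)
        u = np.array([np.cos(theta), np.sin(theta)])
        if u[0] < 0:
            u = -u
        pts = t[:, None] * u
        k_nuc = float(rng.uniform(0.1, 1.0))
        i = int(rng.integers(n))
        others = np.delete(pts, i, axis=0)
        f = repulsion_force(pts[i], others, u, k_nuc, 1.0)
        ref = np.zeros(2)
        for q in others:
            d = pts[i] - q
            dist = float(np.sqrt(d @ d))
            e = d / dist
            ref += (e @ u) * k_nuc / max(dist, 1.0) ** 2 * u
        np.testing.assert_allclose(f, ref, atol=1e-12)


# ---------------------------------------------------------------------------
# mechanics step

def test_zero_coefficients_freeze_myonuclei(small_params):
    p = dataclasses.replace(small_params,
                            mechanics=MechanicsParams(k_lat=0.0, k_nuc=0.0))
    st = make_state(p, tubes=[[(100.0, 100.0), (112.0, 103.0),
                               (125.0, 99.0)]])
    before = st.pos.copy()
    step_mechanics(st)
    np.testing.assert_array_equal(st.pos, before)
    assert st.tubes[0].axis_dir is not None  # axis still refreshed


def test_symmetric_pair_midpoint_fixed(small_params):
    p = dataclasses.replace(small_params,
                            mechanics=MechanicsParams(k_lat=0.1, k_nuc=0.4))
    st = make_state(p, tubes=[[(195.0, 200.0), (205.0, 200.0)]])
    before = st.pos.copy()
    step_mechanics(st)
    d0 = st.pos[0] - before[0]
    d1 = st.pos[1] - before[1]
    np.testing.assert_allclose(d0, -d1, atol=1e-12)
    np.testing.assert_allclose((st.pos[0] + st.pos[1]) / 2,
                               (before[0] + before[1]) / 2, atol=1e-12)


def test_repulsion_strictly_increases_separation(small_params):
    p = dataclasses.replace(small_params,
                            mechanics=MechanicsParams(k_lat=0.0, k_nuc=0.5))
    st = make_state(p, tubes=[[(200.0, 200.0), (205.0, 200.0)]])
    gap0 = 5.0
    step_mechanics(st)
    gap1 = abs(st.pos[1, 0] - st.pos[0, 0])
    assert gap1 > gap0


def test_mechanics_kernel_matches_reference_forces(rng, small_params):
    """The JIT fast path reproduces the reference axis + force functions."""
    for trial in range(25):
        n = int(rng.integers(2, 9))
        pts = (np.array([200.0, 200.0])
               + rng.normal(scale=20.0, size=(n, 2)))
        mech = MechanicsParams(k_lat=float(rng.uniform(0.0, 0.3)),
                               k_nuc=float(rng.uniform(0.0, 1.0)))
        p = dataclasses.replace(small_params, mechanics=mech)
        st = make_state(p, tubes=[pts.tolist()])
        step_mechanics(st)
        centroid, u = compute_major_axis(pts)
        np.testing.assert_allclose(st.tubes[0].axis_centroid, centroid,
                                   atol=1e-9)
        np.testing.assert_allclose(st.tubes[0].axis_dir, u, atol=1e-9)
        for i in range(n):
            f = (lateral_force(pts[i], centroid, u, mech.k_lat)
                 + repulsion_force(pts[i], np.delete(pts, i, axis=0), u,
                                   mech.k_nuc, mech.min_separation))
            disp = mech.mobility * f * p.dt
            norm = np.linalg.norm(disp)
            if norm > p.fusion.aoi_radius:
                disp *= p.fusion.aoi_radius / norm
            np.testing.assert_allclose(st.pos[st.tubes[0].members[i]],
                                       pts[i] + disp, atol=1e-9)


# ---------------------------------------------------------------------------
# full simulation

def test_disabled_fusion_keeps_myonuclei_at_seeded_count(small_params):
    p = dataclasses.replace(
        small_params,
        fusion=FusionParams(t_rmax=float("inf")))
    out = simulate(p)
    mn = out.densities["myonuclei_per_mm2"].to_numpy()
    assert np.all(mn == mn[0])


def test_counts_monotone_and_conserved(small_params):
    out = simulate(small_params)
    d = out.densities
    area = small_params.area_mm2
    total = (d["myoblast_per_mm2"] + d["myonuclei_per_mm2"]) * area
    np.testing.assert_allclose(
        total, small_params.n_myoblasts_t0 + d["cum_divisions"], atol=1e-9)
    mn = d["myonuclei_per_mm2"].to_numpy()
    assert np.all(np.diff(mn) >= 0)
    assert np.all(np.diff(total) >= 0)


def test_identical_seed_gives_identical_event_log(small_params):
    a, b = simulate(small_params), simulate(small_params)
    assert a.events.equals(b.events)
    assert a.densities.equals(b.densities)
    assert a.final_nuclei.equals(b.final_nuclei)
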