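"""Occupancy, principal axes, tilt decomposition, rank-sum statistics."""

import itertools

import numpy as np
import pytest

from allonet.cg_system import SelectionConfig, Trajectory
from allonet.datasets import glic_tilt_tables
from allonet.structure_geometry import (
    TiltAnalysis,
    TiltSummary,
    bonferroni_threshold,
    compare_conditions,
    ligand_occupancy,
    pore_axis,
    principal_axis,
    rank_sum_test,
    tilt_decompose,
    tilt_series,
    tilt_summary,
)
from allonet.synthetic_data import (
    SyntheticSpec,
    default_selection,
    make_ligand_trajectory,
    make_toy_pentamer,
)


def _rotation(axis, deg):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K


# ---------------------------------------------------------------------------
# occupancy


def test_scripted_occupancy_recovered_exactly():
    plan = [(2, 0.3), (6, 0.8), (9, 1.0)]
    spec = SyntheticSpec(noise_sigma=0.005, n_frames=20, contact_plan=plan, seed=2)
    topo, traj = make_toy_pentamer(spec)
    topo2, traj2 = make_ligand_trajectory(traj, topo, plan, cutoff=0.7, seed=3)
    sel = default_selection(spec)
    for mode in ("mean", "any"):
        prof = ligand_occupancy(traj2, topo2, sel, cutoff=0.7, combine_mode=mode)
        for pos, f in plan:
            assert prof.fractions[pos] == pytest.approx(f, abs=1e-12), mode


def test_zero_plan_gives_zero_occupancy():
    spec = SyntheticSpec(noise_sigma=0.01, n_frames=8, seed=2)
    topo, traj = make_toy_pentamer(spec)
    topo2, traj2 = make_ligand_trajectory(traj, topo, [(4, 0.0)], cutoff=0.7, seed=3)
    prof = ligand_occupancy(traj2, topo2, default_selection(spec), cutoff=0.7)
    assert np.all(prof.fractions == 0.0)


def test_occupancy_monotone_in_cutoff():
    plan = [(3, 0.5)]
    spec = SyntheticSpec(noise_sigma=0.02, n_frames=12, seed=7)
    topo, traj = make_toy_pentamer(spec)
    topo2, traj2 = make_ligand_trajectory(traj, topo, plan, cutoff=0.7, seed=8)
    sel = default_selection(spec)
    profiles = [
        ligand_occupancy(traj2, topo2, sel, cutoff=c).fractions
        for c in (0.4, 0.7, 1.0, 1.5)
    ]
    for lo, hi in zip(profiles, profiles[1:]):
        assert np.all(hi >= lo - 1e-12)


def test_occupancy_requires_ligand_beads(quiet_pentamer):
    _, topo, traj, sel = quiet_pentamer
    with pytest.raises(ValueError, match="ligand"):
        ligand_occupancy(traj, topo, sel, cutoff=0.7)


# ---------------------------------------------------------------------------
# principal axis / pore axis


def test_principal_axis_of_a_line():
    pts = np.outer(np.linspace(-1, 1, 9), [0.0, 0.0, 1.0])
    np.testing.assert_allclose(principal_axis(pts), [0, 0, 1], atol=1e-12)


def test_principal_axis_of_long_pitch_helix():
    """Helical arc with pitch >> radius: axis within 1 degree of the screw axis."""
    t = np.linspace(0, 4 * np.pi, 60)
    pts = np.column_stack([t * 2.0, 0.05 * np.cos(t), 0.05 * np.sin(t)])
    axis = principal_axis(pts, reference=[1.0, 0, 0])
    angle = np.degrees(np.arccos(np.clip(abs(axis @ np.array([1.0, 0, 0])), -1, 1)))
    assert angle < 1.0


def test_principal_axis_equivariance(rng):
    pts = rng.normal(size=(10, 3)) * np.array([3.0, 1.0, 0.3])
    rot = _rotation([1, 2, 3], 37.0)
    a1 = principal_axis(pts, reference=[1, 0, 0])
    a2 = principal_axis(pts @ rot.T, reference=rot @ np.array([1.0, 0, 0]))
    np.testing.assert_allclose(a2, rot @ a1, atol=1e-9)


def test_principal_axis_needs_three_points():
    with pytest.raises(ValueError):
        principal_axis(np.zeros((2, 3)))


def _symmetric_pentamer():
    """Identical schedule on all chains: exact C5 symmetry about z."""
    sched = {(c, e): (10.0, -3.0) for c in "ABCDE" for e in ("helix", "leaflet")}
    spec = SyntheticSpec(noise_sigma=0.0, n_frames=1, tilt_schedule=sched)
    topo, traj = make_toy_pentamer(spec)
    return topo, traj


def test_pore_axis_modes_on_aligned_pentamer():
    topo, traj = _symmetric_pentamer()
    coords = traj.coordinates[0]
    for mode in ("fixed_z", "per_frame_principal"):
        axis, center = pore_axis(coords, topo, mode)
        np.testing.assert_allclose(np.abs(axis), [0, 0, 1], atol=1e-6)


def test_pore_axis_follows_rigid_rotation():
    topo, traj = _symmetric_pentamer()
    coords = traj.coordinates[0]
    center = coords.mean(axis=0)
    rot = _rotation([1, 0, 0], 30.0)
    rotated = (coords - center) @ rot.T + center
    axis, _ = pore_axis(rotated, topo, "per_frame_principal")
    np.testing.assert_allclose(axis, rot @ np.array([0, 0, 1.0]), atol=1e-6)
    fixed, _ = pore_axis(rotated, topo, "fixed_z")
    np.testing.assert_allclose(fixed, [0, 0, 1.0])


# ---------------------------------------------------------------------------
# tilt decomposition


def test_tilt_of_axis_parallel_to_pore_is_zero():
    r, l = tilt_decompose([0, 0, 1], [2, 0, 0], [0, 0, 1], [0, 0, 0])
    assert (r, l) == (0.0, 0.0)


def test_pure_radial_tilt():
    rot = _rotation([0, 1, 0], 10.0)  # tilts +z toward +x
    u = rot @ np.array([0, 0, 1.0])
    r, l = tilt_decompose(u, [2, 0, 0], [0, 0, 1], [0, 0, 0])
    assert r == pytest.approx(10.0, abs=1e-9)
    assert l == pytest.approx(0.0, abs=1e-9)


def test_pure_lateral_tilt():
    rot = _rotation([1, 0, 0], -7.0)  # tilts +z toward +y (= e_t for centroid on +x)
    u = rot @ np.array([0, 0, 1.0])
    r, l = tilt_decompose(u, [2, 0, 0], [0, 0, 1], [0, 0, 0])
    assert r == pytest.approx(0.0, abs=1e-9)
    assert l == pytest.approx(7.0, abs=1e-9)


def test_tilt_centroid_on_axis_is_degenerate():
    with pytest.raises(ValueError, match="axis"):
        tilt_decompose([0, 0, 1], [0, 0, 5], [0, 0, 1], [0, 0, 0])


def test_tilt_invariant_under_rigid_rotation(rng):
    """Rotating element axis, centroid, pore axis and centre together leaves
    the decomposition unchanged to 1e-6 degrees."""
    for _ in range(20):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        if u[2] < 0:
            u = -u
        centroid = rng.normal(size=3) + np.array([3.0, 0, 0])
        r0, l0 = tilt_decompose(u, centroid, [0, 0, 1], [0, 0, 0])
        rot = _rotation(rng.normal(size=3), float(rng.uniform(5, 170)))
        r1, l1 = tilt_decompose(rot @ u, rot @ centroid, rot @ np.array([0, 0, 1.0]), [0, 0, 0])
        assert r1 == pytest.approx(r0, abs=1e-6)
        assert l1 == pytest.approx(l0, abs=1e-6)


# ---------------------------------------------------------------------------
# tilt series and summaries


def test_zero_noise_schedule_recovered(quiet_pentamer):
    spec, topo, traj, sel = quiet_pentamer
    series = tilt_series(traj, topo, sel)
    for s in series:
        sched = spec.schedule_angles(s.chain_id, s.element)
        assert np.abs(s.radial - sched[:, 0]).max() < 0.2
        assert np.abs(s.lateral - sched[:, 1]).max() < 0.2


def test_static_trajectory_gives_constant_series(quiet_pentamer):
    spec, topo, traj, sel = quiet_pentamer
    frozen = Trajectory(np.repeat(traj.coordinates[:1], 5, axis=0), traj.box[0])
    series = tilt_series(frozen, topo, sel)
    for s in series:
        assert np.ptp(s.radial) == 0.0
        assert np.ptp(s.lateral) == 0.0


def test_noisy_schedule_mean_within_three_standard_errors():
    spec = SyntheticSpec(noise_sigma=0.03, n_frames=150, seed=21)
    topo, traj = make_toy_pentamer(spec)
    series = tilt_series(traj, topo, default_selection(spec))
    for s in series:
        sched = spec.schedule_angles(s.chain_id, s.element)[0]
        for angle, target in zip(("radial", "lateral"), sched):
            vals = getattr(s, angle)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - target) < max(3 * se, 0.05)


def test_summary_delta_against_published_tables():
    """Published per-subunit tilt tables: Δ recomputed from the means matches
    the printed Δ (exactly for self-consistent rows, within the 0.1 rounding
    bound everywhere)."""
    tabs = glic_tilt_tables()
    # self-consistent worked examples
    tm2_free = tabs[("free", "tm2")].set_index("subunit")
    tm2_prop = tabs[("propofol_tm", "tm2")].set_index("subunit")
    tm2_ket = tabs[("propofol_ec", "tm2")].set_index("subunit")
    assert tm2_prop.loc["B", "radial_mean"] - tm2_free.loc["B", "radial_mean"] == pytest.approx(0.7)
    assert tm2_ket.loc["C", "radial_mean"] - tm2_free.loc["C", "radial_mean"] == pytest.approx(5.5)
    # every row within the one-decimal rounding bound
    for (cond, el), df in tabs.items():
        if cond == "free":
            continue
        free = tabs[("free", el)]
        for col in ("radial", "lateral"):
            delta = df[f"{col}_mean"].to_numpy() - free[f"{col}_mean"].to_numpy()
            assert np.abs(delta - df[f"{col}_delta"].to_numpy()).max() <= 0.1 + 1e-9


def test_tilt_summary_reference_deltas(quiet_pentamer):
    spec, topo, traj, sel = quiet_pentamer
    res = TiltAnalysis(traj, topo, sel).fit()
    summ = res.summary()
    with_ref = res.summary(reference=res)
    assert np.allclose(with_ref.table.radial_delta, 0.0, atol=1e-12)
    assert np.allclose(with_ref.table.lateral_delta, 0.0, atol=1e-12)
    row = summ.row("A", "helix")
    assert row.radial_mean == pytest.approx(13.8, abs=0.05)


def test_scheduled_condition_difference_recovered_exactly():
    """Zero noise: summary Δs equal the scheduled between-condition differences."""
    base = SyntheticSpec(noise_sigma=0.0, n_frames=3, seed=1)
    shifted_sched = {("A", "helix"): (16.8, -3.3)}  # +3 radial on subunit A
    shifted = SyntheticSpec(noise_sigma=0.0, n_frames=3, seed=1, tilt_schedule=shifted_sched)
    t0, tr0 = make_toy_pentamer(base)
    t1, tr1 = make_toy_pentamer(shifted)
    r0 = TiltAnalysis(tr0, t0, default_selection(base)).fit()
    r1 = TiltAnalysis(tr1, t1, default_selection(shifted)).fit()
    summ = r1.summary(reference=r0)
    assert summ.row("A", "helix").radial_delta == pytest.approx(3.0, abs=1e-6)
    assert summ.row("B", "helix").radial_delta == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# rank-sum test and Bonferroni


def test_identical_samples_not_significant():
    x = np.arange(10.0)
    assert rank_sum_test(x, x) > 0.9


def _enumerated_two_sided_p(a, b):
    """Full permutation oracle for the rank-sum test (no ties)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    n1n2 = n1 * len(b)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = sum(sorted(ranks[pooled[i]] for i in combo)) - n1 * (n1 + 1) / 2
        total += 1
        if u <= min(u_obs, n1n2 - u_obs) or u >= max(u_obs, n1n2 - u_obs):
            count += 1
    return count / total


def test_exact_mode_matches_full_enumeration():
    cases = [
        (np.array([1.0, 2, 3]), np.array([4.0, 5, 6])),
        (np.array([1.0, 4, 6]), np.array([2.0, 3, 5, 7])),
        (np.array([10.0, 1, 7, 3]), np.array([2.0, 8, 9])),
    ]
    for a, b in cases:
        assert rank_sum_test(a, b) == pytest.approx(_enumerated_two_sided_p(a, b), abs=1e-12)


def test_all_identical_degenerate_gives_p_one():
    assert rank_sum_test([2.0, 2.0, 2.0], [2.0, 2.0]) == 1.0


def test_type_one_error_calibration():
    """Null rejection rate at alpha = 0.05 stays within binomial error."""
    rng = np.random.default_rng(99)
    n_reps, n = 1000, 25
    rejections = 0
    for _ in range(n_reps):
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        if rank_sum_test(a, b) < 0.05:
            rejections += 1
    rate = rejections / n_reps
    tol = 3 * np.sqrt(0.05 * 0.95 / n_reps)
    assert abs(rate - 0.05) < tol


def test_decorrelate_stride_subsamples():
    x = np.arange(40.0)
    y = np.arange(40.0) + 0.5
    # stride 10 leaves 4 observations each; still a valid test
    p = rank_sum_test(x, y, decorrelate_stride=10)
    assert 0.0 < p <= 1.0
    with pytest.raises(ValueError, match="at least 2"):
        rank_sum_test(x, y, decorrelate_stride=40)


def test_bonferroni_threshold_values():
    assert round(bonferroni_threshold(0.05, 120), 5) == 0.00042
    assert bonferroni_threshold(0.05, 1) == 0.05
    rng = np.random.default_rng(0)
    for _ in range(5):
        alpha, n = rng.uniform(0.001, 0.2), int(rng.integers(1, 500))
        assert bonferroni_threshold(alpha, n) * n == pytest.approx(alpha)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


def test_compare_conditions_flags_shifted_element():
    base = SyntheticSpec(noise_sigma=0.05, n_frames=60, seed=31)
    shifted = SyntheticSpec(
        noise_sigma=0.05, n_frames=60, seed=32,
        tilt_schedule={("A", "helix"): (20.0, -3.3)},
    )
    t0, tr0 = make_toy_pentamer(base)
    t1, tr1 = make_toy_pentamer(shifted)
    s0 = tilt_series(tr0, t0, default_selection(base))
    s1 = tilt_series(tr1, t1, default_selection(shifted))
    df = compare_conditions(s1, s0, alpha=0.05, n_comparisons=120)
    assert np.allclose(df.threshold, 0.05 / 120)
    hit = df[(df.chain == "A") & (df.element == "helix") & (df.angle == "radial")]
    assert bool(hit.significant.iloc[0])
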