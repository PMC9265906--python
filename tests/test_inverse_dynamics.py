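"""Newton–Euler chain: wrench assignment, closed-form statics, whole-foot
equivalence, aponeurosis torque bookkeeping, power and work."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pafoot import (GaitEvents, PlateSeries, SubjectConfig,
                    assign_plate_wrenches, build_segment_inertias,
                    compute_joint_centers, generate_static_load_case,
                    joint_power, joint_work, moment_to_proximal_frame,
                    pa_contribution, place_pa_points, run_sensitivity,
                    run_trial, template_marker_series)
from pafoot.inverse_dynamics import find_pushoff_index
from pafoot.kinematics import com_acceleration


# ---------------------------------------------------------------------------
# plate wrench assignment
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def static_geometry():
    markers = template_marker_series("right", n_frames=3)
    centers = compute_joint_centers(markers)
    he = markers.get("HE")
    return markers, centers, he


def _plate_at(cop_point, fz, n=3, rate=100.0):
    t = np.arange(n) / rate
    force = np.zeros((n, 3))
    force[:, 2] = fz
    cop = np.broadcast_to(np.append(cop_point[:2], 0.0), (n, 3)).copy()
    return PlateSeries(time=t, force=force, cop=cop,
                       free_moment_z=np.zeros(n), rate=rate)


def test_cop_distal_to_mtp_loads_the_phalanx(static_geometry):
    markers, centers, he = static_geometry
    axis = centers.mtp[0] - he[0]
    axis /= np.linalg.norm(axis)
    plate1 = _plate_at(centers.mtp[0] + 0.05 * axis, 300.0)
    plate2 = PlateSeries.zeros(plate1.time, plate1.rate)
    w1, w2 = assign_plate_wrenches(plate1, plate2, centers, he)
    assert set(w1.segment) == {"phalanx"}
    assert set(w2.segment) == {"none"}
    np.testing.assert_array_equal(w2.force, 0.0)


def test_cop_between_joints_loads_the_forefoot(static_geometry):
    markers, centers, he = static_geometry
    midway = 0.5 * (centers.midtarsal[0] + centers.mtp[0])
    plate2 = _plate_at(midway, 300.0)
    plate1 = PlateSeries.zeros(plate2.time, plate2.rate)
    _, w2 = assign_plate_wrenches(plate1, plate2, centers, he)
    assert set(w2.segment) == {"forefoot"}


def test_force_below_threshold_is_unloaded(static_geometry):
    markers, centers, he = static_geometry
    plate1 = _plate_at(centers.mtp[0], 5.0)
    plate2 = PlateSeries.zeros(plate1.time, plate1.rate)
    w1, _ = assign_plate_wrenches(plate1, plate2, centers, he, threshold_n=10.0)
    assert set(w1.segment) == {"none"}
    np.testing.assert_array_equal(w1.force, 0.0)
    np.testing.assert_array_equal(w1.moment, 0.0)


# ---------------------------------------------------------------------------
# closed-form statics
# ---------------------------------------------------------------------------

def test_gravity_only_statics_match_lever_arm_oracle(standing):
    """With no plate load, each joint reaction supports the distal segment
    weights and each joint moment equals their gravitational torque."""
    bundle, oracle = generate_static_load_case(force_n=0.0)
    cfg = SubjectConfig(body_mass_kg=62.8)
    res = run_trial(bundle, standing.markers, cfg, with_pa=False)

    inertias = build_segment_inertias(62.8)
    g = np.array([0.0, 0.0, -9.8])
    coms = res.coms
    centers = res.centers
    # independent oracle: sum over distal segments of m·g and (com-joint)×m·g
    chains = {"mtp": ["phalanx"], "midtarsal": ["phalanx", "forefoot"],
              "ankle": ["phalanx", "forefoot", "hindfoot"]}
    joints = {"mtp": centers.mtp, "midtarsal": centers.midtarsal,
              "ankle": centers.ankle}
    for joint, segs in chains.items():
        f_expect = -sum(inertias[s].mass for s in segs) * g
        n_expect = -sum(np.cross(coms[s] - joints[joint], inertias[s].mass * g)
                        for s in segs)
        np.testing.assert_allclose(res.loads[joint].force, f_expect[None, :] *
                                   np.ones((res.time.size, 1)), atol=1e-9)
        np.testing.assert_allclose(res.loads[joint].moment, n_expect, atol=1e-9)
        # the generator's emitted statics agree too
        np.testing.assert_allclose(res.loads[joint].force[0], oracle[joint][0],
                                   atol=1e-9)
        np.testing.assert_allclose(res.loads[joint].moment[0], oracle[joint][1],
                                   atol=1e-9)


def test_loaded_statics_match_emitted_closed_form(standing):
    """100 N vertical 5 cm distal to the MTP center: pipeline vs the
    generator's explicit cross-product statics."""
    bundle, oracle = generate_static_load_case(force_n=100.0, cop_offset_m=0.05)
    cfg = SubjectConfig(body_mass_kg=62.8)
    res = run_trial(bundle, standing.markers, cfg, with_pa=False)
    for joint, (f, n) in oracle.items():
        np.testing.assert_allclose(res.loads[joint].force,
                                   np.broadcast_to(f, (res.time.size, 3)),
                                   atol=1e-9)
        np.testing.assert_allclose(res.loads[joint].moment,
                                   np.broadcast_to(n, (res.time.size, 3)),
                                   atol=1e-9)
    # the applied force appears in the MTP moment through its lever arm
    _, gravity_only = generate_static_load_case(force_n=0.0)
    extra = oracle["mtp"][1] - gravity_only["mtp"][1]
    lever = np.linalg.norm(extra) / 100.0
    assert 0.0 < lever < 0.06   # horizontal component of the 5 cm offset


def test_single_point_load_moment_magnitude():
    """A 0.131 kg point mass 5 cm from its joint: |n| = m·g·d about y."""
    m, d = 0.131, 0.05
    n = np.cross(np.array([d, 0.0, 0.0]), m * np.array([0.0, 0.0, -9.8]))
    assert abs(n[1]) == pytest.approx(0.0642, abs=2e-4)
    assert n[0] == n[2] == 0.0


# ---------------------------------------------------------------------------
# whole-foot equivalence and aponeurosis bookkeeping
# ---------------------------------------------------------------------------

def test_recursive_chain_equals_whole_foot_free_body(result_with, config):
    """The ankle load from the three-segment recursion equals a single
    free-body balance of the entire foot (internal forces cancel)."""
    res = result_with
    g = np.array([0.0, 0.0, -config.gravity])
    dt = float(res.time[1] - res.time[0])
    inertias = build_segment_inertias(config.body_mass_kg,
                                      config.foot_mass_fraction)
    T = res.time.size
    f_expect = np.zeros((T, 3))
    n_expect = np.zeros((T, 3))
    ankle = res.centers.ankle
    for seg in ("phalanx", "forefoot", "hindfoot"):
        m = inertias[seg].mass
        acc = com_acceleration(res.coms[seg], dt)
        f_inert = m * (acc - g)
        f_expect += f_inert
        # angular-momentum term about the COM + inertial-force lever arm
        basis = res.frames[seg].basis
        w_s = np.einsum("tji,tj->ti", basis, res.motions[seg].omega)
        a_s = np.einsum("tji,tj->ti", basis, res.motions[seg].alpha)
        I = inertias[seg].inertia
        euler = np.einsum("tij,tj->ti",
                          basis, np.cross(w_s, w_s @ I.T) + a_s @ I.T)
        n_expect += euler + np.cross(res.coms[seg] - ankle, m * acc)
        n_expect -= np.cross(res.coms[seg] - ankle, m * g)
    for w in res.wrenches:
        f_expect -= w.force
        n_expect -= np.cross(w.cop - ankle, w.force) + w.moment

    scale = max(1.0, np.abs(res.loads["ankle"].force).max())
    assert np.abs(res.loads["ankle"].force - f_expect).max() / scale < 1e-9
    scale_n = max(1.0, np.abs(res.loads["ankle"].moment).max())
    assert np.abs(res.loads["ankle"].moment - n_expect).max() / scale_n < 1e-9


def test_ankle_load_invariant_to_aponeurosis(result_with, result_without):
    np.testing.assert_allclose(result_with.loads["ankle"].force,
                               result_without.loads["ankle"].force, atol=1e-9)
    np.testing.assert_allclose(result_with.loads["ankle"].moment,
                               result_without.loads["ankle"].moment, atol=1e-9)


def test_moment_difference_equals_distal_pa_torque(result_with, result_without):
    """with-PA minus no-PA joint moment equals minus the torque of the
    distal-side attachment forces about that joint (cross-product oracle)."""
    res, res0 = result_with, result_without
    r_ori, r_via, r_ins = place_pa_points(res.attachments, res.frames)
    pa = res.pa_state
    c = res.centers

    dn_mtp = res.loads["mtp"].moment - res0.loads["mtp"].moment
    oracle = -np.cross(r_ins - c.mtp[:, None, :], pa.f_ins).sum(axis=1)
    np.testing.assert_allclose(dn_mtp, oracle, atol=1e-9)

    dn_mt = res.loads["midtarsal"].moment - res0.loads["midtarsal"].moment
    oracle = -(np.cross(r_ins - c.midtarsal[:, None, :], pa.f_ins).sum(axis=1)
               + np.cross(r_via - c.midtarsal[:, None, :], pa.f_via).sum(axis=1))
    np.testing.assert_allclose(dn_mt, oracle, atol=1e-9)


# ---------------------------------------------------------------------------
# frame transform, power, work
# ---------------------------------------------------------------------------

def test_moment_transform_identity_rotation_and_isometry(rng):
    n = rng.normal(size=(10, 3))
    eye = np.broadcast_to(np.eye(3), (10, 3, 3))
    np.testing.assert_allclose(moment_to_proximal_frame(n, eye), n, atol=1e-12)

    Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    basis = np.broadcast_to(Rz, (1, 3, 3))
    out = moment_to_proximal_frame(np.array([[0.0, 1.0, 0.0]]), basis)
    np.testing.assert_allclose(out[0], [1.0, 0.0, 0.0], atol=1e-12)

    random_basis = Rotation.from_rotvec(rng.normal(size=(10, 3))).as_matrix()
    out = moment_to_proximal_frame(n, random_basis)
    np.testing.assert_allclose(np.linalg.norm(out, axis=1),
                               np.linalg.norm(n, axis=1), atol=1e-12)


def test_joint_power_cases_and_frame_invariance(rng):
    zero_total, _ = joint_power(np.array([[1.0, 2.0, 3.0]]), np.zeros((1, 3)))
    assert zero_total[0] == 0.0
    total, axes = joint_power(np.array([[0.0, 1.0, 0.0]]),
                              np.array([[0.0, 2.0, 0.0]]))
    assert total[0] == pytest.approx(2.0)
    np.testing.assert_allclose(axes[0], [0.0, 2.0, 0.0])

    n_lab = rng.normal(size=(20, 3))
    w_lab = rng.normal(size=(20, 3))
    basis = Rotation.from_rotvec(rng.normal(size=(20, 3))).as_matrix()
    p_lab, _ = joint_power(n_lab, w_lab)
    p_seg, _ = joint_power(moment_to_proximal_frame(n_lab, basis),
                           moment_to_proximal_frame(w_lab, basis))
    np.testing.assert_allclose(p_lab, p_seg, atol=1e-12)


def test_work_sine_lobes_constant_and_additivity():
    t = np.linspace(0.0, 2.0 * np.pi, 4001)
    w_pos, w_neg = joint_work(np.sin(t), t)
    assert w_pos == pytest.approx(2.0, abs=1e-5)
    assert w_neg == pytest.approx(-2.0, abs=1e-5)

    t1 = np.linspace(0.0, 1.0, 101)
    assert joint_work(np.ones_like(t1), t1) == (1.0, 0.0)

    rng = np.random.default_rng(3)
    p = rng.normal(size=501)
    tr = np.linspace(0.0, 5.0, 501)
    w_pos, w_neg = joint_work(p, tr)
    assert w_pos + w_neg == pytest.approx(np.trapezoid(p, tr), abs=1e-12)
    assert w_pos >= 0.0 >= w_neg


def test_trial_work_identity(result_with):
    for joint, p in result_with.power.items():
        w = result_with.work[joint]
        ev = result_with.events
        mask = (result_with.time >= ev.heel_strike) & \
               (result_with.time <= ev.toe_off)
        net = np.trapezoid(p["total"][mask], result_with.time[mask])
        assert w["positive"] + w["negative"] == pytest.approx(net, abs=1e-9)
        assert w["positive"] >= 0.0 >= w["negative"]


# ---------------------------------------------------------------------------
# aponeurosis contribution
# ---------------------------------------------------------------------------

def test_pa_contribution_limit_cases():
    n = np.array([0.0, -10.0, -20.0])
    assert pa_contribution(n, n, 2) == 0.0
    assert pa_contribution(np.zeros(3), n, 2) == pytest.approx(100.0)
    assert np.isnan(pa_contribution(n, np.zeros(3), 1))


def test_pa_contribution_recovers_injected_ratio():
    """A constructed pair of moment series whose difference is a known
    fraction at the push-off instant."""
    t = np.linspace(0.0, 1.0, 101)
    n_without = -np.sin(np.pi * t) * 30.0
    injected = 0.37
    n_with = n_without * (1.0 - injected)
    events = GaitEvents(0.0, 0.61, 1.0)
    idx = find_pushoff_index(n_without, t, events)
    assert t[idx] == pytest.approx(0.5, abs=0.05)   # peak of the lobe in window
    assert pa_contribution(n_with, n_without, idx) == \
        pytest.approx(100.0 * injected, abs=0.1)


def test_trial_contributions_fall_in_plausible_corridors(analysis):
    """%PA contributions at push-off on the default synthetic trial lie in
    physiologically plausible ranges (positive, below 100 %)."""
    c = analysis.contributions
    for joint in ("mtp", "midtarsal"):
        assert 0.0 < c[joint]["pushoff_pct"] < 100.0


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def sensitivity_table(gait, standing, config):
    return run_sensitivity(gait, standing.markers, config)


def test_default_cell_reproduces_baseline(sensitivity_table, result_with):
    row = sensitivity_table[
        (sensitivity_table.mass_scale == 1.0)
        & (sensitivity_table.natural_length_fraction == 0.98)
        & (sensitivity_table.strain == 0.07)].iloc[0]
    assert row["pa_force_peak_n"] == \
        result_with.pa_state.tension.sum(axis=1).max()
    for joint in ("mtp", "midtarsal", "ankle"):
        assert row[f"{joint}_moment_y_min_nm"] == \
            result_with.loads[joint].moment_reported[:, 1].min()


def test_inertial_scaling_has_minor_effect_on_quasi_static_trial(sensitivity_table):
    """0.5× vs 1.5× mass/inertia changes the peak flexion moments of the
    planted-stance synthetic trial by well under 1 %."""
    d = sensitivity_table[(sensitivity_table.natural_length_fraction == 0.98)
                          & (sensitivity_table.strain == 0.07)]
    d = d.set_index("mass_scale")
    for joint in ("mtp", "midtarsal", "ankle"):
        col = f"{joint}_moment_y_min_nm"
        change = abs(d.loc[1.5, col] - d.loc[0.5, col]) / abs(d.loc[1.0, col])
        assert change < 0.01


def test_pa_force_monotone_decreasing_in_strain(sensitivity_table):
    """Larger calibration strain → smaller stiffness → smaller force at
    fixed elongation, across every (mass, fraction) slice of the grid."""
    for (m, fr), sub in sensitivity_table.groupby(
            ["mass_scale", "natural_length_fraction"]):
        forces = sub.sort_values("strain")["pa_force_peak_n"].to_numpy()
        assert np.all(np.diff(forces) < 0.0)


def test_longer_natural_length_reduces_pa_force(sensitivity_table):
    for (m, s), sub in sensitivity_table.groupby(["mass_scale", "strain"]):
        forces = sub.sort_values("natural_length_fraction")[
            "pa_force_peak_n"].to_numpy()
        assert np.all(np.diff(forces) < 0.0)
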