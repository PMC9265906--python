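"""Frame construction, attachment scaling and rigid-motion equivariance."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pafoot import (DegenerateGeometryError, build_segment_frames,
                    compute_joint_centers, load_attachment_table,
                    place_pa_points, scale_pa_attachments,
                    template_marker_series)
from pafoot.foot_geometry import ANATOMICAL_TO_SEGMENT
from pafoot.io_formats import MarkerSeries
from pafoot.kinematics import JOINT_SEQUENCES, euler_angles, relative_rotation


@pytest.fixture(scope="module")
def template():
    return template_marker_series("right", n_frames=1)


@pytest.fixture(scope="module")
def template_frames(template):
    return build_segment_frames(template, "right")


def test_joint_centers_are_exact_midpoints(gait):
    centers = compute_joint_centers(gait.markers)
    m = gait.markers
    np.testing.assert_array_equal(centers.ankle, 0.5 * (m.get("ANKL") + m.get("ANKM")))
    np.testing.assert_array_equal(centers.midtarsal, 0.5 * (m.get("TN") + m.get("VMB")))
    np.testing.assert_array_equal(centers.mtp, 0.5 * (m.get("FMH") + m.get("VMH")))


def test_coincident_markers_give_their_midpoint():
    labels = ["ANKL", "ANKM", "TN", "VMB", "FMH", "VMH"]
    pos = np.ones((1, 6, 3))
    series = MarkerSeries(time=[0.0], labels=labels, positions=pos, rate=100.0)
    centers = compute_joint_centers(series)
    np.testing.assert_array_equal(centers.midtarsal, [[1.0, 1.0, 1.0]])


def test_bases_orthonormal_right_handed_every_step(gait):
    frames, _ = build_segment_frames(gait.markers, "right")
    for frame in frames.values():
        b = frame.basis
        np.testing.assert_allclose(np.einsum("tij,tik->tjk", b, b),
                                   np.broadcast_to(np.eye(3), b.shape),
                                   atol=1e-10)
        np.testing.assert_allclose(np.linalg.det(b), 1.0, atol=1e-10)


def test_hindfoot_frame_matches_gram_schmidt_oracle(template, template_frames):
    """Brute-force orthogonalization, written independently of the module."""
    frames, centers = template_frames
    ca = template.get("CA")[0]
    he = template.get("HE")[0]
    mid = centers.midtarsal[0]
    normal = np.cross(he - ca, mid - ca)
    y = normal / np.linalg.norm(normal)
    lat = template.get("VMB")[0] - template.get("TN")[0]
    if np.dot(y, lat) < 0:
        y = -y
    z = (ca - he) - np.dot(ca - he, y) * y
    z /= np.linalg.norm(z)
    if np.dot(z, ca - he) < 0:
        z = -z
    x = np.cross(y, z)
    oracle = np.stack([x, y, z], axis=-1)
    np.testing.assert_allclose(frames["hindfoot"].basis[0], oracle, atol=1e-10)
    np.testing.assert_array_equal(frames["hindfoot"].origin[0], he)


def test_planar_hindfoot_markers_give_lab_y_normal():
    """CA, HE and the midtarsal center confined to the x-z plane make the
    hindfoot y axis exactly ±lab-y."""
    labels = ["CA", "HE", "TN", "VMB", "ANKL", "ANKM", "FMH", "VMH"]
    pos = np.array([[[0.02, 0.0, 0.06], [0.0, 0.0, 0.02], [0.10, 0.03, 0.04],
                     [0.115, -0.03, 0.02], [0.065, -0.04, 0.065],
                     [0.07, 0.045, 0.07], [0.185, 0.035, 0.03],
                     [0.175, -0.04, 0.02]]])
    series = MarkerSeries(time=[0.0], labels=labels, positions=pos, rate=100.0)
    from pafoot import build_hindfoot_frame
    centers = compute_joint_centers(series)
    frame = build_hindfoot_frame(series, centers, "right")
    np.testing.assert_allclose(np.abs(frame.basis[0, :, 1]), [0.0, 1.0, 0.0],
                               atol=1e-12)


def test_collinear_plane_points_rejected():
    labels = ["CA", "HE", "TN", "VMB", "ANKL", "ANKM", "FMH", "VMH"]
    pos = np.zeros((1, 8, 3))
    pos[0, 0] = [0.0, 0.0, 0.2]    # CA
    pos[0, 1] = [0.0, 0.0, 0.0]    # HE
    pos[0, 2] = [0.0, 0.0, 0.4]    # TN: midtarsal collinear with CA-HE
    pos[0, 3] = [0.0, 0.0, 0.6]    # VMB
    pos[0, 4:] = [[0.1, 0, 0], [0.1, 0.1, 0], [0.2, 0, 0], [0.2, 0.1, 0]]
    series = MarkerSeries(time=[0.0], labels=labels, positions=pos, rate=100.0)
    from pafoot import build_hindfoot_frame
    centers = compute_joint_centers(series)
    with pytest.raises(DegenerateGeometryError):
        build_hindfoot_frame(series, centers, "right")


def test_shank_axis_vertical_for_vertical_shank(template, template_frames):
    frames, _ = template_frames
    z = frames["shank"].basis[0, :, 2]
    knee = 0.5 * (template.get("KNEL")[0] + template.get("KNEM")[0])
    ankle = 0.5 * (template.get("ANKL")[0] + template.get("ANKM")[0])
    direction = (knee - ankle) / np.linalg.norm(knee - ankle)
    np.testing.assert_allclose(z, direction, atol=1e-12)
    assert z[2] > 0.99   # near-vertical template shank


# ---------------------------------------------------------------------------
# attachment scaling and placement
# ---------------------------------------------------------------------------

def test_attachment_scale_is_anklvmh_length(template):
    att = scale_pa_attachments(template, "right")
    assert att.scale == pytest.approx(0.25, abs=1e-12)
    table = load_attachment_table()
    np.testing.assert_allclose(att.insertion_anatomical,
                               table["insertions"] * att.scale, atol=1e-15)


def test_printed_origin_entry_scales_to_quarter_meter_values(template):
    """Origin entry (0.284, 0.051, -0.107) at scale 0.25 m."""
    att = scale_pa_attachments(template, "right")
    np.testing.assert_allclose(att.origin_anatomical,
                               [0.0710, 0.01275, -0.02675], atol=1e-12)


def test_unit_scale_reproduces_table_entries(template):
    quadruple = MarkerSeries(time=template.time, labels=template.labels,
                             positions=template.positions * 4.0,
                             rate=template.rate)
    att = scale_pa_attachments(quadruple, "right")
    assert att.scale == pytest.approx(1.0, abs=1e-12)
    table = load_attachment_table()
    np.testing.assert_allclose(att.via_anatomical, table["via_points"], atol=1e-12)


def test_left_foot_mirrors_mediolateral_coordinate(template):
    att_r = scale_pa_attachments(template, "right")
    att_l = scale_pa_attachments(template_marker_series("left"), "left")
    np.testing.assert_allclose(att_l.insertion_anatomical[:, 1],
                               -att_r.insertion_anatomical[:, 1], atol=1e-12)
    np.testing.assert_allclose(att_l.insertion_anatomical[:, [0, 2]],
                               att_r.insertion_anatomical[:, [0, 2]], atol=1e-12)


def test_placement_is_affine_map_of_local_coordinates(template, template_frames):
    frames, _ = template_frames
    att = scale_pa_attachments(template, "right")
    r_ori, r_via, r_ins = place_pa_points(att, frames)
    B = frames["phalanx"].basis[0]
    o = frames["phalanx"].origin[0]
    for i in range(5):
        np.testing.assert_allclose(r_ins[0, i], o + B @ att.insertion_local[i],
                                   atol=1e-12)
    # mapping back through the frame recovers the local coordinates
    back = B.T @ (r_ins[0, 0] - o)
    np.testing.assert_allclose(back, att.insertion_local[0], atol=1e-10)


def test_anatomical_to_segment_map_is_proper_rotation():
    assert np.linalg.det(ANATOMICAL_TO_SEGMENT) == pytest.approx(1.0)
    np.testing.assert_array_equal(ANATOMICAL_TO_SEGMENT @ ANATOMICAL_TO_SEGMENT.T,
                                  np.eye(3))


def test_rigid_motion_equivariance(gait, rng):
    """One rigid transform of all markers moves every derived point and
    frame by exactly that transform."""
    R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
    t = rng.normal(size=3)
    moved = gait.markers.transformed(R, t)

    frames_a, centers_a = build_segment_frames(gait.markers, "right")
    frames_b, centers_b = build_segment_frames(moved, "right")
    np.testing.assert_allclose(centers_b.ankle, centers_a.ankle @ R.T + t,
                               atol=1e-9)
    for name in frames_a:
        np.testing.assert_allclose(frames_b[name].origin,
                                   frames_a[name].origin @ R.T + t, atol=1e-9)
        np.testing.assert_allclose(frames_b[name].basis,
                                   np.einsum("ij,tjk->tik", R, frames_a[name].basis),
                                   atol=1e-9)

    att = scale_pa_attachments(template_marker_series("right"), "right")
    _, via_a, ins_a = place_pa_points(att, frames_a)
    _, via_b, ins_b = place_pa_points(att, frames_b)
    np.testing.assert_allclose(ins_b, ins_a @ R.T + t, atol=1e-9)
    np.testing.assert_allclose(via_b, via_a @ R.T + t, atol=1e-9)


def test_attachment_distances_constant_under_rigid_motion(gait):
    """Within-segment attachment point spacing is invariant over the trial."""
    frames, _ = build_segment_frames(gait.markers, "right")
    att = scale_pa_attachments(template_marker_series("right"), "right")
    _, r_via, r_ins = place_pa_points(att, frames)
    for pts in (r_via, r_ins):
        d = np.linalg.norm(pts[:, :, None, :] - pts[:, None, :, :], axis=-1)
        assert np.abs(d - d[0]).max() < 1e-9


def test_imposed_dorsiflexion_reads_positive(template):
    """Directional calibration: rotating the toe physically upward about the
    metatarsal-head axis must increase the reported MTP flexion angle."""
    m = template
    fmh, vmh, pm = m.get("FMH")[0], m.get("VMH")[0], m.get("PM")[0]
    axis = (vmh - fmh) / np.linalg.norm(vmh - fmh)   # lateral for a right foot
    pivot = 0.5 * (fmh + vmh)
    R10 = Rotation.from_rotvec(np.deg2rad(10.0) * axis).as_matrix()
    pm_rot = pivot + R10 @ (pm - pivot)
    assert pm_rot[2] > pm[2]   # toes moved up: this is dorsiflexion

    pos = m.positions.copy()
    pos[0, m.index("PM")] = pm_rot
    moved = MarkerSeries(time=m.time, labels=m.labels, positions=pos, rate=m.rate)

    def mtp_angle(series):
        frames, _ = build_segment_frames(series, "right")
        rel = relative_rotation(frames["forefoot"], frames["phalanx"])
        angles, _ = euler_angles(rel, JOINT_SEQUENCES["mtp"])
        return angles[0, 1]

    assert mtp_angle(moved) - mtp_angle(template) == pytest.approx(10.0, abs=1e-9)
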