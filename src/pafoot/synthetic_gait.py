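"""Self-contained synthetic gait trials for the foot model.

The generator provides everything the analysis pipeline consumes — marker
trajectories, two-plate force records, quiet standing — from a stylized
template foot, so the package can be exercised end-to-end without motion
capture.

Joint motion is prescribed in angle space and realized as exact hinge
rotations about the template joint axes:

* MTP — the PM marker rotates about the FMH–VMH line (the phalanx frame's
  y axis);
* midtarsal — the forefoot marker set (plus PM) rotates about the TN–VMB
  line (the forefoot frame's y axis);
* ankle — the shank marker set rotates (with reversed sign) about the shank
  frame's y axis through the ankle center.

Because each rotation axis is the relevant frame's own flexion axis, and
the flexion angle is the last rotation of the z-x-y sequences (and the
first of y-x-z, where it is prepended on the proximal side), the prescribed
flexion profile adds *exactly* to the template's constant offset angles:
the ground truth emitted with every trial is recoverable by the kinematics
module up to filtering error.  A common rigid trajectory (stance: planted;
swing: forward translation with lift and pitch) is applied on top and
leaves the joint angles untouched.

Ground-reaction forces are prescribed, not derived from whole-body
dynamics: a double-hump vertical profile with biphasic shear is split
between the rear plate (under the hindfoot, early stance) and the front
plate (under the forefoot, late stance) by a smooth weight, with the COP
progressing heel→toe so that both branches of the plate-to-segment
assignment rule are exercised.  The template's geometric proportions are a
versioned fixture — uniformly rescaled so the attachment scaling length
|ANKL−VMH| is 0.25 m — not an anatomical claim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import PafootError
from .foot_geometry import build_segment_frames, place_pa_points, scale_pa_attachments
from .inertial_model import build_segment_inertias, segment_com
from .io_formats import (MarkerSeries, PlateSeries, SubjectConfig, TrialBundle,
                         write_config, write_plates, write_trc)
from .kinematics import GaitEvents, angle_sign_convention, euler_angles, JOINT_SEQUENCES

#: attachment scaling length |ANKL-VMH| of the template, m
TEMPLATE_SCALE_LENGTH = 0.25

#: base template marker coordinates (right foot, lab frame: x anterior,
#: y medial side of a right foot, z up); uniformly rescaled on build
_TEMPLATE_BASE = {
    "PM":   (0.225, 0.030, 0.020),
    "FMH":  (0.185, 0.035, 0.030),
    "SMH":  (0.195, 0.010, 0.030),
    "VMH":  (0.175, -0.040, 0.020),
    "FMB":  (0.120, 0.030, 0.035),
    "SMB":  (0.125, 0.005, 0.040),
    "VMB":  (0.115, -0.045, 0.020),
    "TN":   (0.100, 0.035, 0.040),
    "ST":   (0.050, 0.030, 0.030),
    "PT":   (0.050, -0.035, 0.025),
    "CA":   (0.020, 0.000, 0.060),
    "HE":   (0.000, 0.000, 0.020),
    "ANKL": (0.065, -0.040, 0.065),
    "ANKM": (0.070, 0.045, 0.070),
    "KNEL": (0.065, -0.050, 0.430),
    "KNEM": (0.070, 0.050, 0.430),
}

#: marker groups moved by each hinge (distal side)
SHANK_SET = ("ANKL", "ANKM", "KNEL", "KNEM")
HINDFOOT_SET = ("CA", "HE", "ST", "PT", "TN")
FOREFOOT_SET = ("VMB", "FMB", "SMB", "FMH", "SMH", "VMH")
PHALANX_SET = ("PM",)


def build_template_foot(side: str = "right") -> dict:
    """Static reference pose: label -> (3,) lab position in meters.

    Uniformly scaled so |ANKL−VMH| equals :data:`TEMPLATE_SCALE_LENGTH`;
    left feet mirror the medio-lateral (y) coordinate.
    """
    pts = {k: np.asarray(v, dtype=float) for k, v in _TEMPLATE_BASE.items()}
    d = np.linalg.norm(pts["ANKL"] - pts["VMH"])
    factor = TEMPLATE_SCALE_LENGTH / d
    mirror = np.array([1.0, -1.0, 1.0]) if side == "left" else np.ones(3)
    return {k: v * factor * mirror for k, v in pts.items()}


def template_marker_series(side: str = "right", n_frames: int = 1,
                           rate: float = 100.0) -> MarkerSeries:
    template = build_template_foot(side)
    labels = list(template)
    positions = np.broadcast_to(
        np.stack([template[l] for l in labels]), (n_frames, len(labels), 3)
    ).copy()
    return MarkerSeries(time=np.arange(n_frames) / rate, labels=labels,
                        positions=positions, rate=rate)


# ---------------------------------------------------------------------------
# trial specification
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTrialSpec:
    """Conditions of a generated trial.

    Defaults reproduce the study conditions of the reference gait data set
    (mean body mass 62.8 kg, cycle duration 1.03 s, stance 61 % of the
    cycle, walking speed 1.33 m/s) with qualitative late-stance profiles:
    MTP dorsiflexion and midtarsal/ankle plantarflexion at push-off.
    """

    body_mass_kg: float = 62.8
    side: str = "right"
    cycle_duration_s: float = 1.03
    stance_fraction: float = 0.61
    speed_m_s: float = 1.33
    marker_rate_hz: float = 100.0
    plate_rate_hz: float = 1000.0
    lead_s: float = 0.15              # quiet margin before/after the cycle
    # joint-angle profile amplitudes, deg
    mtp_early_plantarflexion_deg: float = 10.0
    mtp_pushoff_dorsiflexion_deg: float = 30.0
    midtarsal_dorsiflexion_deg: float = 8.0
    midtarsal_pushoff_plantarflexion_deg: float = 15.0
    ankle_early_plantarflexion_deg: float = 8.0
    ankle_mid_dorsiflexion_deg: float = 10.0
    ankle_pushoff_plantarflexion_deg: float = 20.0
    swing_pitch_deg: float = 10.0
    swing_lift_m: float = 0.04
    # ground-reaction profile, body weights
    grf_peak_bw: float = 1.10
    grf_valley_bw: float = 0.75
    grf_shear_bw: float = 0.15
    free_moment_peak_nm: float = 0.4
    marker_noise_sigma_m: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.cycle_duration_s <= 0 or self.lead_s < 0:
            raise PafootError("durations must be positive")
        if not 0.0 < self.stance_fraction < 1.0:
            raise PafootError("stance_fraction must lie in (0, 1)")
        if self.marker_noise_sigma_m < 0:
            raise PafootError("marker noise sigma must be >= 0")

    def config(self) -> SubjectConfig:
        return SubjectConfig(body_mass_kg=self.body_mass_kg, side=self.side)


@dataclass
class GroundTruth:
    """Generator-side truth emitted with every trial."""

    events: GaitEvents
    stance_fraction: float
    joint_angles: dict        # joint -> (T, 3) deg, reported sign convention
    flexion_profiles: dict    # joint -> (T,) deg, imposed increments only
    pa_lengths: np.ndarray    # (T, 5) m, noise-free geometry
    plate_assignment: dict    # plate id -> (T,) str labels on the marker clock

    def to_jsonable(self) -> dict:
        return {
            "events": {"heel_strike": self.events.heel_strike,
                       "toe_off": self.events.toe_off,
                       "next_heel_strike": self.events.next_heel_strike},
            "stance_fraction": self.stance_fraction,
            "joint_angles": {j: a.tolist() for j, a in self.joint_angles.items()},
            "flexion_profiles": {j: p.tolist() for j, p in self.flexion_profiles.items()},
            "pa_lengths": self.pa_lengths.tolist(),
            "plate_assignment": {str(p): list(map(str, a))
                                 for p, a in self.plate_assignment.items()},
        }


# ---------------------------------------------------------------------------
# profile primitives
# ---------------------------------------------------------------------------

def _bump(u: np.ndarray, u0: float, u1: float) -> np.ndarray:
    """Raised-cosine bump: 0 outside [u0, u1], peak 1 at the midpoint,
    zero value and slope at both ends."""
    u = np.asarray(u, dtype=float)
    phase = (u - u0) / (u1 - u0)
    inside = (phase >= 0.0) & (phase <= 1.0)
    return np.where(inside, 0.5 - 0.5 * np.cos(2.0 * np.pi * np.clip(phase, 0, 1)), 0.0)


def _smoothstep_displacement(w: np.ndarray) -> np.ndarray:
    """0→1 displacement with zero velocity and acceleration at both ends."""
    w = np.clip(w, 0.0, 1.0)
    return w - np.sin(2.0 * np.pi * w) / (2.0 * np.pi)


def flexion_profiles(u: np.ndarray, spec: SyntheticTrialSpec) -> dict:
    """Imposed flexion increments (deg) as functions of cycle fraction u.

    Qualitative gait sequence: after heel contact the MTP plantarflexes and
    the midtarsal dorsiflexes; in late stance the MTP dorsiflexes (windlass)
    while the midtarsal and ankle plantarflex; everything returns to neutral
    during swing.
    """
    return {
        "mtp": (-spec.mtp_early_plantarflexion_deg * _bump(u, 0.00, 0.35)
                + spec.mtp_pushoff_dorsiflexion_deg * _bump(u, 0.38, 0.76)),
        "midtarsal": (spec.midtarsal_dorsiflexion_deg * _bump(u, 0.02, 0.45)
                      - spec.midtarsal_pushoff_plantarflexion_deg * _bump(u, 0.45, 0.90)),
        "ankle": (-spec.ankle_early_plantarflexion_deg * _bump(u, 0.00, 0.22)
                  + spec.ankle_mid_dorsiflexion_deg * _bump(u, 0.14, 0.55)
                  - spec.ankle_pushoff_plantarflexion_deg * _bump(u, 0.50, 0.85)),
    }


# ---------------------------------------------------------------------------
# marker synthesis
# ---------------------------------------------------------------------------

def _rotate_about(points: np.ndarray, axis: np.ndarray, pivot: np.ndarray,
                  angles_rad: np.ndarray) -> np.ndarray:
    """Rotate (T, L, 3) points about a fixed axis/pivot by per-frame angles."""
    R = Rotation.from_rotvec(np.outer(angles_rad, axis)).as_matrix()
    return pivot + np.einsum("tij,tlj->tli", R, points - pivot)


def _synthesize_markers(time: np.ndarray, u: np.ndarray, spec: SyntheticTrialSpec):
    """Marker trajectories plus the exact prescribed joint-angle truth."""
    template = build_template_foot(spec.side)
    labels = list(template)
    base = np.stack([template[l] for l in labels])        # (L, 3)
    tpl_series = template_marker_series(spec.side)
    frames0, centers0 = build_segment_frames(tpl_series, spec.side)

    axis_y = {name: frames0[name].basis[0, :, 1] for name in
              ("phalanx", "forefoot", "shank")}
    pivot_mtp = centers0.mtp[0]
    pivot_mt = centers0.midtarsal[0]
    pivot_ankle = 0.5 * (template["ANKL"] + template["ANKM"])

    profiles = flexion_profiles(u, spec)
    rad = {j: np.deg2rad(p) for j, p in profiles.items()}

    T = time.size
    pts = np.broadcast_to(base, (T, len(labels), 3)).copy()
    idx = {l: i for i, l in enumerate(labels)}

    def subset(names):
        return [idx[n] for n in names]

    # MTP hinge: phalanx markers about the FMH-VMH line
    sel = subset(PHALANX_SET)
    pts[:, sel, :] = _rotate_about(pts[:, sel, :], axis_y["phalanx"],
                                   pivot_mtp, rad["mtp"])
    # midtarsal hinge: forefoot + phalanx markers about the TN-VMB line
    sel = subset(FOREFOOT_SET + PHALANX_SET)
    pts[:, sel, :] = _rotate_about(pts[:, sel, :], axis_y["forefoot"],
                                   pivot_mt, rad["midtarsal"])
    # ankle hinge: shank markers, reversed sign (the foot stays planted)
    sel = subset(SHANK_SET)
    pts[:, sel, :] = _rotate_about(pts[:, sel, :], axis_y["shank"],
                                   pivot_ankle, -rad["ankle"])

    # global trajectory: planted through stance, forward + lift + pitch in swing
    s = spec.stance_fraction
    w = np.clip((u - s) / (1.0 - s), 0.0, 1.0)
    w = np.where(u <= s, 0.0, w)
    stride = spec.speed_m_s * spec.cycle_duration_s
    disp = np.zeros((T, 3))
    disp[:, 0] = stride * _smoothstep_displacement(w)
    disp[:, 2] = spec.swing_lift_m * np.sin(np.pi * w) ** 2
    pitch = np.deg2rad(spec.swing_pitch_deg) * np.sin(np.pi * w) ** 2
    pts = _rotate_about(pts, np.array([0.0, -1.0, 0.0]), pivot_ankle, pitch)
    pts = pts + disp[:, None, :]

    # exact ground-truth angles: template offsets plus the imposed increments
    signs = angle_sign_convention(spec.side)
    pairs = {"ankle": ("shank", "hindfoot"), "midtarsal": ("hindfoot", "forefoot"),
             "mtp": ("forefoot", "phalanx")}
    gt_angles = {}
    for joint, (prox, dist) in pairs.items():
        rel0 = frames0[prox].basis[0].T @ frames0[dist].basis[0]
        raw0, _ = euler_angles(rel0, JOINT_SEQUENCES[joint])
        raw = np.broadcast_to(raw0, (T, 3)).copy()
        raw[:, 1] = raw0[1] + profiles[joint]
        gt_angles[joint] = raw * signs

    markers = MarkerSeries(time=time, labels=labels, positions=pts,
                           rate=spec.marker_rate_hz)
    return markers, gt_angles, profiles


# ---------------------------------------------------------------------------
# ground-reaction synthesis
# ---------------------------------------------------------------------------

def _grf_arrays(t: np.ndarray, spec: SyntheticTrialSpec, events: GaitEvents,
                template: dict):
    """Per-plate force/COP/free-moment samples on clock ``t``."""
    bw = spec.body_mass_kg * 9.8
    t_hs, t_to = events.heel_strike, events.toe_off
    x = (t - t_hs) / (t_to - t_hs)           # stance fraction
    active = (x >= 0.0) & (x <= 1.0)
    xc = np.clip(x, 0.0, 1.0)

    # fast contact on/off envelope (3 % of stance) so the 10 N threshold is
    # crossed within a few milliseconds of the true contact events
    def _step(p):
        return 0.5 - 0.5 * np.cos(np.pi * np.clip(p, 0.0, 1.0))
    envelope = _step(xc / 0.03) * _step((1.0 - xc) / 0.03)
    hump = spec.grf_peak_bw - 0.30
    fz_total = bw * envelope * (0.30
                                + hump * _bump(xc, 0.0, 0.5)
                                + hump * _bump(xc, 0.5, 1.0)
                                + (spec.grf_valley_bw - 0.30) * _bump(xc, 0.2, 0.8))
    fx_total = -bw * spec.grf_shear_bw * np.sin(2.0 * np.pi * xc)
    fy_total = bw * 0.02 * np.sin(2.0 * np.pi * xc)
    fz_total = np.where(active, fz_total, 0.0)
    fx_total = np.where(active, fx_total, 0.0)
    fy_total = np.where(active, fy_total, 0.0)

    # rear-plate share: all load at heel strike, none from 75 % stance on
    rear = np.where(xc <= 0.15, 1.0,
                    np.where(xc >= 0.75, 0.0,
                             0.5 + 0.5 * np.cos(np.pi * (xc - 0.15) / 0.60)))

    he = template["HE"]
    mtp_c = 0.5 * (template["FMH"] + template["VMH"])
    mt_c = 0.5 * (template["TN"] + template["VMB"])
    axis = mtp_c - he
    axis = axis / np.linalg.norm(axis)

    def ground(p):
        q = p.copy()
        q[2] = 0.0
        return q

    # rear COP: heel → past the midtarsal center; front COP: just proximal
    # of the MTP center → past it (toes)
    cop2_start = ground(he + 0.02 * axis)
    cop2_end = ground(mt_c + 0.06 * axis)
    cop1_start = ground(mtp_c - 0.06 * axis)
    cop1_end = ground(mtp_c + 0.10 * axis)
    w2 = np.clip(xc / 0.75, 0.0, 1.0)[:, None]
    w1 = np.clip((xc - 0.15) / 0.85, 0.0, 1.0)[:, None]
    cop2 = cop2_start + w2 * (cop2_end - cop2_start)
    cop1 = cop1_start + w1 * (cop1_end - cop1_start)

    mz_total = spec.free_moment_peak_nm * np.sin(np.pi * xc)
    mz_total = np.where(active, mz_total, 0.0)

    def plate(fshare, cop, mz):
        force = np.stack([fx_total * fshare, fy_total * fshare,
                          fz_total * fshare], axis=-1)
        return force, cop, mz

    f2, c2, m2 = plate(rear, cop2, mz_total * rear)
    f1, c1, m1 = plate(1.0 - rear, cop1, -mz_total * (1.0 - rear))
    return (f1, c1, m1), (f2, c2, m2)


def _assignment_labels(markers: MarkerSeries, spec: SyntheticTrialSpec,
                       events: GaitEvents, plates) -> dict:
    """Generator-side plate-to-segment labels on the marker clock."""
    from .foot_geometry import compute_joint_centers  # local to avoid cycle noise
    centers = compute_joint_centers(markers)
    he = markers.get("HE")
    axis = centers.mtp - he
    axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)

    def project(p):
        return np.sum((p - he) * axis, axis=-1)

    out = {}
    for pid, plate, boundary, distal_name, prox_name, distal_side in (
            (1, plates[0], project(centers.mtp), "phalanx", "forefoot", True),
            (2, plates[1], project(centers.midtarsal), "hindfoot", "forefoot", False)):
        idx = np.clip(np.searchsorted(plate.time, markers.time - 0.5 / plate.rate),
                      0, plate.time.size - 1)
        loaded = np.linalg.norm(plate.force[idx], axis=-1) >= 10.0
        s_cop = project(plate.cop[idx])
        distal = s_cop > boundary if distal_side else s_cop < boundary
        out[pid] = np.where(loaded, np.where(distal, distal_name, prox_name),
                            "none").astype(object)
    return out


# ---------------------------------------------------------------------------
# trial generators
# ---------------------------------------------------------------------------

def generate_quiet_standing(spec: SyntheticTrialSpec, duration_s: float = 1.0):
    """Static standing trial: template pose, plate loads summing to body
    weight (60 % rear / 40 % front), optional marker noise."""
    rng = np.random.default_rng(spec.seed + 1)
    n_m = int(round(duration_s * spec.marker_rate_hz))
    markers = template_marker_series(spec.side, n_frames=n_m,
                                     rate=spec.marker_rate_hz)
    if spec.marker_noise_sigma_m > 0:
        markers.positions += rng.normal(0.0, spec.marker_noise_sigma_m,
                                        markers.positions.shape)

    template = build_template_foot(spec.side)
    n_p = int(round(duration_s * spec.plate_rate_hz))
    t_p = np.arange(n_p) / spec.plate_rate_hz
    bw = spec.body_mass_kg * 9.8
    mtp_c = 0.5 * (template["FMH"] + template["VMH"])

    def static_plate(share, under):
        force = np.zeros((n_p, 3))
        force[:, 2] = share * bw
        cop = np.broadcast_to(np.array([under[0], under[1], 0.0]), (n_p, 3)).copy()
        return PlateSeries(time=t_p, force=force, cop=cop,
                           free_moment_z=np.zeros(n_p), rate=spec.plate_rate_hz)

    plates = (static_plate(0.4, mtp_c), static_plate(0.6, template["HE"]))
    bundle = TrialBundle(markers=markers, plates=plates,
                         body_mass_kg=spec.body_mass_kg, side=spec.side)

    frames, _ = build_segment_frames(template_marker_series(spec.side, n_m,
                                                            spec.marker_rate_hz),
                                     spec.side)
    attachments = scale_pa_attachments(template_marker_series(spec.side),
                                       spec.side)
    r_ori, r_via, r_ins = place_pa_points(attachments, frames)
    from .pa_model import pa_length
    lengths = pa_length(r_ori[:, None, :], r_via, r_ins)

    signs = angle_sign_convention(spec.side)
    tpl = template_marker_series(spec.side, n_m, spec.marker_rate_hz)
    frames_t, _ = build_segment_frames(tpl, spec.side)
    pairs = {"ankle": ("shank", "hindfoot"), "midtarsal": ("hindfoot", "forefoot"),
             "mtp": ("forefoot", "phalanx")}
    gt_angles = {}
    for joint, (prox, dist) in pairs.items():
        rel0 = frames_t[prox].basis[0].T @ frames_t[dist].basis[0]
        raw0, _ = euler_angles(rel0, JOINT_SEQUENCES[joint])
        gt_angles[joint] = np.broadcast_to(raw0 * signs, (n_m, 3)).copy()

    truth = GroundTruth(
        events=GaitEvents(0.0, duration_s, None),
        stance_fraction=1.0,
        joint_angles=gt_angles,
        flexion_profiles={j: np.zeros(n_m) for j in pairs},
        pa_lengths=lengths,
        plate_assignment={1: np.array(["forefoot"] * n_m, dtype=object),
                          2: np.array(["hindfoot"] * n_m, dtype=object)},
    )
    return bundle, truth


def generate_gait_trial(spec: SyntheticTrialSpec):
    """One full gait cycle (plus quiet lead-in/out) with ground truth."""
    rng = np.random.default_rng(spec.seed)
    total = spec.cycle_duration_s + 2.0 * spec.lead_s
    n_m = int(round(total * spec.marker_rate_hz)) + 1
    t_m = np.arange(n_m) / spec.marker_rate_hz
    u = np.clip((t_m - spec.lead_s) / spec.cycle_duration_s, 0.0, 1.0)

    markers, gt_angles, profiles = _synthesize_markers(t_m, u, spec)

    # gimbal guard on the prescribed motion
    for joint, a in gt_angles.items():
        if np.any(np.abs(a[:, 0]) >= 90.0):
            raise PafootError(f"prescribed {joint} profile reaches gimbal lock")

    events = GaitEvents(
        heel_strike=spec.lead_s,
        toe_off=spec.lead_s + spec.stance_fraction * spec.cycle_duration_s,
        next_heel_strike=spec.lead_s + spec.cycle_duration_s,
    )

    template = build_template_foot(spec.side)
    n_p = int(round(total * spec.plate_rate_hz)) + 1
    t_p = np.arange(n_p) / spec.plate_rate_hz
    (f1, c1, m1), (f2, c2, m2) = _grf_arrays(t_p, spec, events, template)
    plates = (
        PlateSeries(time=t_p, force=f1, cop=c1, free_moment_z=m1,
                    rate=spec.plate_rate_hz),
        PlateSeries(time=t_p, force=f2, cop=c2, free_moment_z=m2,
                    rate=spec.plate_rate_hz),
    )

    # noise-free aponeurosis lengths from the generated geometry
    frames, _ = build_segment_frames(markers, spec.side)
    attachments = scale_pa_attachments(template_marker_series(spec.side), spec.side)
    r_ori, r_via, r_ins = place_pa_points(attachments, frames)
    from .pa_model import pa_length
    lengths = pa_length(r_ori[:, None, :], r_via, r_ins)

    assignment = _assignment_labels(markers, spec, events, plates)

    if spec.marker_noise_sigma_m > 0:
        markers.positions += rng.normal(0.0, spec.marker_noise_sigma_m,
                                        markers.positions.shape)

    bundle = TrialBundle(markers=markers, plates=plates,
                         body_mass_kg=spec.body_mass_kg, side=spec.side)
    truth = GroundTruth(events=events, stance_fraction=spec.stance_fraction,
                        joint_angles=gt_angles,
                        flexion_profiles={j: np.asarray(p) for j, p in profiles.items()},
                        pa_lengths=lengths, plate_assignment=assignment)
    return bundle, truth


def generate_static_load_case(body_mass_kg: float = 62.8, side: str = "right",
                              force_n: float = 100.0, cop_offset_m: float = 0.05,
                              duration_s: float = 1.0, rate_hz: float = 100.0,
                              plate_rate_hz: float = 1000.0):
    """Zero-velocity pose under a single constant front-plate wrench, with
    hand-computed (pure statics, explicit cross products) joint loads.

    The vertical force is applied ``cop_offset_m`` distal to the MTP joint
    center along the foot's longitudinal axis, so it loads the phalanx.
    Returns ``(bundle, oracle)`` where ``oracle`` maps joint -> (force,
    moment) constants; pass ``force_n=0`` for the gravity-only case.
    """
    n_m = int(round(duration_s * rate_hz))
    markers = template_marker_series(side, n_frames=n_m, rate=rate_hz)
    template = build_template_foot(side)

    he = template["HE"]
    mtp_c = 0.5 * (template["FMH"] + template["VMH"])
    mt_c = 0.5 * (template["TN"] + template["VMB"])
    ankle_c = 0.5 * (template["ANKL"] + template["ANKM"])
    axis = (mtp_c - he) / np.linalg.norm(mtp_c - he)
    cop = mtp_c + cop_offset_m * axis
    cop[2] = 0.0

    n_p = int(round(duration_s * plate_rate_hz))
    t_p = np.arange(n_p) / plate_rate_hz
    force1 = np.zeros((n_p, 3))
    force1[:, 2] = force_n
    plate1 = PlateSeries(time=t_p, force=force1,
                         cop=np.broadcast_to(cop, (n_p, 3)).copy(),
                         free_moment_z=np.zeros(n_p), rate=plate_rate_hz)
    plate2 = PlateSeries.zeros(t_p, plate_rate_hz)
    bundle = TrialBundle(markers=markers, plates=(plate1, plate2),
                         body_mass_kg=body_mass_kg, side=side)

    # explicit statics, solved distal -> proximal
    inertias = build_segment_inertias(body_mass_kg)
    g_vec = np.array([0.0, 0.0, -9.8])
    com_p = segment_com(mtp_c, template["PM"], inertias["phalanx"].com_fraction)
    com_f = segment_com(mt_c, mtp_c, inertias["forefoot"].com_fraction)
    com_h = segment_com(ankle_c, mt_c, inertias["hindfoot"].com_fraction)
    m_p, m_f, m_h = (inertias[s].mass for s in ("phalanx", "forefoot", "hindfoot"))

    f_e1 = np.array([0.0, 0.0, force_n]) if force_n >= 10.0 else np.zeros(3)
    f_pj = -f_e1 - m_p * g_vec
    n_pj = -np.cross(mtp_c - com_p, f_pj) - np.cross(cop - com_p, f_e1)
    f_fj = f_pj - m_f * g_vec
    n_fj = (n_pj - np.cross(mt_c - com_f, f_fj) + np.cross(mtp_c - com_f, f_pj))
    f_hj = f_fj - m_h * g_vec
    n_hj = (n_fj - np.cross(ankle_c - com_h, f_hj) + np.cross(mt_c - com_h, f_fj))

    oracle = {"mtp": (f_pj, n_pj), "midtarsal": (f_fj, n_fj), "ankle": (f_hj, n_hj)}
    return bundle, oracle


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_trial(outdir, spec: SyntheticTrialSpec) -> dict:
    """Write a complete synthetic data set (gait + standing + config +
    ground truth) and return the file paths.  Byte-identical for identical
    (spec, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gait, truth = generate_gait_trial(spec)
    standing, _ = generate_quiet_standing(spec)

    paths = {
        "gait_markers": outdir / "gait_markers.trc",
        "gait_plates": outdir / "gait_plates.csv",
        "static_markers": outdir / "static_markers.trc",
        "static_plates": outdir / "static_plates.csv",
        "ground_truth": outdir / "ground_truth.json",
        "config": outdir / "config.yaml",
    }
    write_trc(gait.markers, paths["gait_markers"])
    write_plates(*gait.plates, paths["gait_plates"])
    write_trc(standing.markers, paths["static_markers"])
    write_plates(*standing.plates, paths["static_plates"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump({"spec": asdict(spec), "truth": truth.to_jsonable()}, fh,
                  indent=1, sort_keys=True)
        fh.write("\n")
    write_config(spec.config(), paths["config"])
    return paths
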