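"""Newton–Euler inverse dynamics of the three-segment foot.

The chain is solved distal→proximal per time step.  For each segment the
force balance gives the proximal joint reaction, and the moment balance —
taken about the segment COM, with the Euler term ``M{ω×(Iω) + Iω̇}``
evaluated in the segment frame where the inertia tensor is constant — gives
the proximal joint moment:

* phalanx   — loads: plate-1 wrench (when the COP is distal to the MTP
  joint), aponeurosis insertion forces, gravity → MTP joint load;
* forefoot  — adds the MTP reaction (sign-reversed), both plate wrenches,
  aponeurosis via-point forces → midtarsal joint load;
* hindfoot  — adds the midtarsal reaction, the plate-2 wrench,
  aponeurosis origin forces → ankle joint load.

Because each aponeurosis slip applies a zero net wrench to the foot, the
ankle load is identical with and without the aponeurosis; only the
intra-foot (MTP, midtarsal) moments change.  Joint moments are re-expressed
in the proximal segment frame (shank for the ankle, hindfoot for the
midtarsal, forefoot for the MTP) to match the joint angles; joint power is
the dot product of the joint moment and the relative angular velocity in
that same frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import PafootError
from .foot_geometry import (JointCenters, PAAttachmentSet, build_segment_frames,
                            place_pa_points, scale_pa_attachments)
from .inertial_model import SEGMENTS, build_segment_inertias, segment_com
from .io_formats import MarkerSeries, PlateSeries, SubjectConfig, TrialBundle
from .kinematics import (GaitEvents, JointAngleSeries, angle_sign_convention,
                         com_acceleration, detect_contact_events,
                         filter_and_decimate_plate, filter_markers,
                         joint_angle_series, segment_motion)
from .pa_model import PAForceState, PASprings, build_pa_springs, evaluate_pa

#: distal joint of each segment's proximal joint, solved in this order
JOINT_OF_SEGMENT = {"phalanx": "mtp", "forefoot": "midtarsal", "hindfoot": "ankle"}
#: frame in which each joint's moment (and angle) is expressed
PROXIMAL_FRAME_OF_JOINT = {"mtp": "forefoot", "midtarsal": "hindfoot", "ankle": "shank"}
DISTAL_FRAME_OF_JOINT = {"mtp": "phalanx", "midtarsal": "forefoot", "ankle": "hindfoot"}

#: fraction of stance, from its end, searched for the push-off instant
PUSHOFF_SEARCH_FRACTION = 0.4


# ---------------------------------------------------------------------------
# external wrenches
# ---------------------------------------------------------------------------

@dataclass
class ExternalWrench:
    """A plate's wrench resolved onto foot segments over time."""

    plate: int
    force: np.ndarray        # (T, 3) N
    cop: np.ndarray          # (T, 3) m
    moment: np.ndarray       # (T, 3) N·m, free moment at the COP
    segment: np.ndarray      # (T,) str in {phalanx, forefoot, hindfoot, none}

    def on_segment(self, segment: str):
        """Force/COP/moment arrays masked to the frames assigned to ``segment``."""
        mask = (self.segment == segment)[:, None]
        return self.force * mask, self.cop, self.moment * mask


def assign_plate_wrenches(plate1: PlateSeries, plate2: PlateSeries,
                          centers: JointCenters, hindfoot_origin: np.ndarray,
                          threshold_n: float = 10.0) -> tuple[ExternalWrench, ExternalWrench]:
    """Assign each plate's wrench to a foot segment per time step.

    The COP is projected onto the foot's longitudinal axis (hindfoot origin →
    MTP center).  Plate 1 (front) loads the phalanx when its COP projects
    distal to the MTP joint center, otherwise the forefoot; plate 2 (rear)
    loads the hindfoot when its COP projects proximal to the midtarsal joint
    center, otherwise the forefoot.  A plate below the force threshold is
    unloaded: zero wrench, assigned to no segment.
    """
    axis = centers.mtp - hindfoot_origin
    axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)

    def project(p):
        return np.sum((p - hindfoot_origin) * axis, axis=-1)

    s_mtp = project(centers.mtp)
    s_midtarsal = project(centers.midtarsal)

    def resolve(plate: PlateSeries, pid: int, distal_name: str, prox_name: str,
                s_boundary: np.ndarray, distal_side: bool) -> ExternalWrench:
        loaded = np.linalg.norm(plate.force, axis=-1) >= threshold_n
        if np.any(loaded & ~np.all(np.isfinite(plate.cop), axis=-1)):
            raise PafootError(f"plate {pid}: loaded frames with non-finite COP")
        s_cop = project(plate.cop)
        if distal_side:
            distal = s_cop > s_boundary
        else:
            distal = s_cop < s_boundary
        segment = np.where(loaded, np.where(distal, distal_name, prox_name), "none")
        mask = loaded[:, None]
        moment = np.zeros_like(plate.force)
        moment[:, 2] = plate.free_moment_z
        return ExternalWrench(plate=pid, force=plate.force * mask,
                              cop=plate.cop, moment=moment * mask,
                              segment=segment.astype(object))

    w1 = resolve(plate1, 1, "phalanx", "forefoot", s_mtp, distal_side=True)
    w2 = resolve(plate2, 2, "hindfoot", "forefoot", s_midtarsal, distal_side=False)
    return w1, w2


# ---------------------------------------------------------------------------
# segment solvers
# ---------------------------------------------------------------------------

@dataclass
class JointLoad:
    """Reaction force and moment at one joint, all time steps."""

    joint: str
    force: np.ndarray             # (T, 3) N, lab frame
    moment: np.ndarray            # (T, 3) N·m, lab frame, about the joint center
    moment_prox: np.ndarray | None = None       # raw proximal-frame components
    moment_reported: np.ndarray | None = None   # +eversion/+dorsiflexion/+abduction
    moment_norm: np.ndarray | None = None       # reported / body mass, N·m/kg


def _euler_term(basis: np.ndarray, inertia: np.ndarray, omega: np.ndarray,
                alpha: np.ndarray) -> np.ndarray:
    """Lab-frame rate of change of angular momentum, ``M{ω×(Iω) + Iω̇}``,
    with ω, ω̇ rotated into the segment frame where I is constant."""
    w_s = np.einsum("tji,tj->ti", basis, omega)
    a_s = np.einsum("tji,tj->ti", basis, alpha)
    term_s = np.cross(w_s, w_s @ inertia.T) + a_s @ inertia.T
    return np.einsum("tij,tj->ti", basis, term_s)


def _solve_segment(mass, inertia, basis, com, com_acc, omega, alpha, g_vec,
                   point_forces, pure_moments, r_joint, joint_name) -> JointLoad:
    """Generic Newton–Euler balance of one segment about its COM.

    ``point_forces`` is a list of ``(force (T,[5,]3), position (T,[5,]3))``
    pairs of everything applied to the segment except gravity and the
    unknown proximal joint load; ``pure_moments`` are couples (free moments,
    transferred joint moments)."""
    T = com.shape[0]
    f_sum = np.zeros((T, 3))
    n_sum = np.zeros((T, 3))
    for force, pos in point_forces:
        if force.ndim == 3:      # per-slip attachment forces
            f_sum += force.sum(axis=1)
            n_sum += np.cross(pos - com[:, None, :], force).sum(axis=1)
        else:
            f_sum += force
            n_sum += np.cross(pos - com, force)
    for couple in pure_moments:
        n_sum += couple
    f_joint = mass * com_acc - f_sum - mass * g_vec
    euler = _euler_term(basis, inertia, omega, alpha)
    n_joint = euler - np.cross(r_joint - com, f_joint) - n_sum
    return JointLoad(joint=joint_name, force=f_joint, moment=n_joint)


def solve_phalanx(inertia, frame, com, com_acc, motion, g_vec,
                  wrench1: ExternalWrench, pa: PAForceState, r_ins,
                  r_mtp) -> JointLoad:
    """MTP joint load from the phalanx free body."""
    f1, cop1, n1 = wrench1.on_segment("phalanx")
    return _solve_segment(
        inertia.mass, inertia.inertia, frame.basis, com, com_acc,
        motion.omega, motion.alpha, g_vec,
        point_forces=[(f1, cop1), (pa.f_ins, r_ins)],
        pure_moments=[n1], r_joint=r_mtp, joint_name="mtp")


def solve_forefoot(inertia, frame, com, com_acc, motion, g_vec,
                   mtp_load: JointLoad, wrench1: ExternalWrench,
                   wrench2: ExternalWrench, pa: PAForceState, r_via,
                   r_mtp, r_midtarsal) -> JointLoad:
    """Midtarsal joint load; the MTP reaction enters sign-reversed at the
    MTP joint center with its moment transferred."""
    f1, cop1, n1 = wrench1.on_segment("forefoot")
    f2, cop2, n2 = wrench2.on_segment("forefoot")
    return _solve_segment(
        inertia.mass, inertia.inertia, frame.basis, com, com_acc,
        motion.omega, motion.alpha, g_vec,
        point_forces=[(-mtp_load.force, r_mtp), (f1, cop1), (f2, cop2),
                      (pa.f_via, r_via)],
        pure_moments=[-mtp_load.moment, n1, n2],
        r_joint=r_midtarsal, joint_name="midtarsal")


def solve_hindfoot(inertia, frame, com, com_acc, motion, g_vec,
                   midtarsal_load: JointLoad, wrench2: ExternalWrench,
                   pa: PAForceState, r_ori, r_midtarsal, r_ankle) -> JointLoad:
    """Ankle joint load; aponeurosis origin forces act on the calcaneus."""
    f2, cop2, n2 = wrench2.on_segment("hindfoot")
    r_ori5 = r_ori[:, None, :] * np.ones((1, pa.f_ori.shape[1], 1))
    return _solve_segment(
        inertia.mass, inertia.inertia, frame.basis, com, com_acc,
        motion.omega, motion.alpha, g_vec,
        point_forces=[(-midtarsal_load.force, r_midtarsal), (f2, cop2),
                      (pa.f_ori, r_ori5)],
        pure_moments=[-midtarsal_load.moment, n2],
        r_joint=r_ankle, joint_name="ankle")


def moment_to_proximal_frame(n_lab: np.ndarray, proximal_basis: np.ndarray) -> np.ndarray:
    """Express a lab-frame moment in the proximal segment's axes."""
    return np.einsum("tji,tj->ti", proximal_basis, n_lab)


# ---------------------------------------------------------------------------
# power / work / aponeurosis contribution
# ---------------------------------------------------------------------------

def joint_power(n_prox: np.ndarray, omega_rel_prox: np.ndarray):
    """Joint power and per-axis components, W.

    ``P = n · ω_rel`` with both expressed in the proximal frame; the dot
    product is frame-invariant, per-axis components are not.
    """
    axes = n_prox * omega_rel_prox
    return axes.sum(axis=-1), axes


def joint_work(power: np.ndarray, time: np.ndarray,
               window: tuple[float, float] | None = None) -> tuple[float, float]:
    """Positive and negative work by trapezoidal integration over the cycle.

    Splitting P pointwise before integrating keeps ``W_pos + W_neg`` exactly
    equal to the net ∫P dt (the trapezoid rule is linear in the integrand).
    """
    power = np.asarray(power, dtype=float)
    time = np.asarray(time, dtype=float)
    if window is not None:
        mask = (time >= window[0]) & (time <= window[1])
        power, time = power[mask], time[mask]
    w_pos = float(np.trapezoid(np.maximum(power, 0.0), time))
    w_neg = float(np.trapezoid(np.minimum(power, 0.0), time))
    return w_pos, w_neg


def find_pushoff_index(moment_y_raw: np.ndarray, time: np.ndarray,
                       events: GaitEvents) -> int:
    """Instant of peak plantarflexion moment in late stance.

    Raw y components are positive for dorsiflexion, so the plantarflexion
    peak is the minimum, searched over the last 40 % of stance.
    """
    t_start = events.heel_strike + (1.0 - PUSHOFF_SEARCH_FRACTION) * \
        (events.toe_off - events.heel_strike)
    mask = (time >= t_start) & (time <= events.toe_off)
    if not mask.any():
        raise PafootError("no samples in the push-off search window")
    idx = np.nonzero(mask)[0]
    return int(idx[np.argmin(moment_y_raw[mask])])


def pa_contribution(n_with: np.ndarray, n_without: np.ndarray, index: int,
                    min_moment: float = 1e-6):
    """% of the net joint moment generated by the aponeurosis at one instant.

    ``100 · (n_without − n_with) / n_without`` on the flexion (y) component;
    undefined (NaN) when the net moment is numerically zero.
    """
    denom = n_without[index]
    if abs(denom) < min_moment:
        return float("nan")
    return float(100.0 * (denom - n_with[index]) / denom)


# ---------------------------------------------------------------------------
# full-trial pipeline
# ---------------------------------------------------------------------------

@dataclass
class TrialResults:
    """Everything one inverse-dynamics pass produces."""

    time: np.ndarray
    side: str
    body_mass_kg: float
    with_pa: bool
    events: GaitEvents | None
    angles: JointAngleSeries
    loads: dict                     # joint -> JointLoad
    power: dict                     # joint -> {"total": (T,), "axes": (T, 3)}
    work: dict                      # joint -> {"positive": J, "negative": J}
    pa_state: PAForceState
    pa_springs: PASprings
    attachments: PAAttachmentSet
    wrenches: tuple                 # (ExternalWrench, ExternalWrench)
    frames: dict = field(repr=False, default=None)
    centers: JointCenters = field(repr=False, default=None)
    motions: dict = field(repr=False, default=None)
    coms: dict = field(repr=False, default=None)
    config: SubjectConfig = None

    def angles_table(self) -> pd.DataFrame:
        rows = {"time_s": self.time}
        for joint, a in self.angles.angles.items():
            if joint == "mtp":
                rows["mtp_flexion_deg"] = a[:, 1]
            else:
                rows[f"{joint}_inversion_eversion_deg"] = a[:, 0]
                rows[f"{joint}_flexion_deg"] = a[:, 1]
                rows[f"{joint}_abduction_deg"] = a[:, 2]
        return pd.DataFrame(rows)

    def moments_table(self) -> pd.DataFrame:
        rows = {"time_s": self.time}
        for joint, load in self.loads.items():
            for i, axis in enumerate(("x", "y", "z")):
                rows[f"{joint}_moment_{axis}_nm"] = load.moment_reported[:, i]
                rows[f"{joint}_moment_{axis}_nm_per_kg"] = load.moment_norm[:, i]
        return pd.DataFrame(rows)

    def power_table(self) -> pd.DataFrame:
        rows = {"time_s": self.time}
        for joint, p in self.power.items():
            rows[f"{joint}_power_w_per_kg"] = p["total"] / self.body_mass_kg
        return pd.DataFrame(rows)

    def pa_table(self) -> pd.DataFrame:
        rows = {"time_s": self.time}
        for i in range(self.pa_state.lengths.shape[1]):
            rows[f"pa{i + 1}_length_m"] = self.pa_state.lengths[:, i]
            rows[f"pa{i + 1}_force_n"] = self.pa_state.tension[:, i]
        rows["pa_net_force_n"] = self.pa_state.tension.sum(axis=1)
        return pd.DataFrame(rows)

    def work_table(self) -> pd.DataFrame:
        rows = []
        for joint, w in self.work.items():
            rows.append({"joint": joint, "work_positive_j": w["positive"],
                         "work_negative_j": w["negative"]})
        return pd.DataFrame(rows)


def _static_marker_series(static) -> MarkerSeries:
    return static.markers if isinstance(static, TrialBundle) else static


def run_trial(gait: TrialBundle, static, config: SubjectConfig,
              with_pa: bool = True, events: GaitEvents | None = None) -> TrialResults:
    """One full inverse-dynamics pass over a gait trial.

    ``static`` (a TrialBundle or MarkerSeries of quiet standing) calibrates
    the aponeurosis; ``with_pa=False`` zeroes all aponeurosis forces but
    changes nothing else.  If ``events`` is omitted, stance is detected from
    the plates and per-cycle quantities use the stance window only.
    """
    side = config.side
    dt = 1.0 / gait.markers.rate
    markers = filter_markers(gait.markers, config.filter_cutoff_hz, config.filter_order)
    plate1 = filter_and_decimate_plate(gait.plates[0], markers.time,
                                       config.filter_cutoff_hz, config.filter_order)
    plate2 = filter_and_decimate_plate(gait.plates[1], markers.time,
                                       config.filter_cutoff_hz, config.filter_order)

    static_markers = _static_marker_series(static)
    attachments = scale_pa_attachments(static_markers, side)
    springs = build_pa_springs(
        static_markers, attachments, config.body_mass_kg,
        strain=config.pushoff_strain, force_bw=config.pushoff_force_bw,
        fraction=config.natural_length_fraction, g=config.gravity, side=side)

    frames, centers = build_segment_frames(markers, side)
    r_ori, r_via, r_ins = place_pa_points(attachments, frames)
    pa_state = evaluate_pa(r_ori, r_via, r_ins, springs)
    if not with_pa:
        pa_state = replace(pa_state,
                           tension=np.zeros_like(pa_state.tension),
                           f_ins=np.zeros_like(pa_state.f_ins),
                           f_ori=np.zeros_like(pa_state.f_ori),
                           f_via=np.zeros_like(pa_state.f_via))

    inertias = build_segment_inertias(
        config.body_mass_kg, config.foot_mass_fraction,
        mass_inertia_scale=config.mass_inertia_scale)
    endpoints = {
        "phalanx": (centers.mtp, markers.get("PM")),
        "forefoot": (centers.midtarsal, centers.mtp),
        "hindfoot": (centers.ankle, centers.midtarsal),
    }
    coms = {seg: segment_com(*endpoints[seg], inertias[seg].com_fraction)
            for seg in SEGMENTS}
    accels = {seg: com_acceleration(coms[seg], dt) for seg in SEGMENTS}
    motions = {seg: segment_motion(frames[seg], dt) for seg in SEGMENTS}
    motions["shank"] = segment_motion(frames["shank"], dt)

    wrench1, wrench2 = assign_plate_wrenches(
        plate1, plate2, centers, frames["hindfoot"].origin,
        threshold_n=config.contact_threshold_n)

    g_vec = np.array([0.0, 0.0, -config.gravity])
    mtp_load = solve_phalanx(inertias["phalanx"], frames["phalanx"],
                             coms["phalanx"], accels["phalanx"],
                             motions["phalanx"], g_vec, wrench1, pa_state,
                             r_ins, centers.mtp)
    midtarsal_load = solve_forefoot(inertias["forefoot"], frames["forefoot"],
                                    coms["forefoot"], accels["forefoot"],
                                    motions["forefoot"], g_vec, mtp_load,
                                    wrench1, wrench2, pa_state, r_via,
                                    centers.mtp, centers.midtarsal)
    ankle_load = solve_hindfoot(inertias["hindfoot"], frames["hindfoot"],
                                coms["hindfoot"], accels["hindfoot"],
                                motions["hindfoot"], g_vec, midtarsal_load,
                                wrench2, pa_state, r_ori, centers.midtarsal,
                                centers.ankle)

    signs = angle_sign_convention(side)
    loads = {}
    for load in (mtp_load, midtarsal_load, ankle_load):
        prox = frames[PROXIMAL_FRAME_OF_JOINT[load.joint]]
        load.moment_prox = moment_to_proximal_frame(load.moment, prox.basis)
        load.moment_reported = load.moment_prox * signs
        load.moment_norm = load.moment_reported / config.body_mass_kg
        loads[load.joint] = load

    static_frames, _ = build_segment_frames(static_markers, side)
    angles = joint_angle_series(
        frames, markers.time, side,
        quiet_standing={"frames": static_frames, "time": static_markers.time})

    if events is None:
        try:
            # detect on the raw plate records: the 10 Hz kinetic filter would
            # smear the low-threshold crossing by tens of milliseconds
            hs, to = detect_contact_events(gait.plates[0], gait.plates[1],
                                           config.contact_threshold_n)
            events = GaitEvents(heel_strike=hs, toe_off=to)
        except PafootError:
            events = None

    power, work = {}, {}
    if events is not None:
        t_end = events.next_heel_strike if events.next_heel_strike is not None \
            else events.toe_off
        window = (events.heel_strike, t_end)
    else:
        window = None
    for joint, load in loads.items():
        prox = frames[PROXIMAL_FRAME_OF_JOINT[joint]]
        omega_rel = motions[DISTAL_FRAME_OF_JOINT[joint]].omega - \
            motions[PROXIMAL_FRAME_OF_JOINT[joint]].omega
        omega_rel_prox = moment_to_proximal_frame(omega_rel, prox.basis)
        total, axes = joint_power(load.moment_prox, omega_rel_prox)
        power[joint] = {"total": total, "axes": axes}
        w_pos, w_neg = joint_work(total, markers.time, window)
        work[joint] = {"positive": w_pos, "negative": w_neg}

    return TrialResults(
        time=markers.time, side=side, body_mass_kg=config.body_mass_kg,
        with_pa=with_pa, events=events, angles=angles, loads=loads,
        power=power, work=work, pa_state=pa_state, pa_springs=springs,
        attachments=attachments, wrenches=(wrench1, wrench2), frames=frames,
        centers=centers, motions=motions, coms=coms, config=config)


@dataclass
class AnalysisResult:
    """Paired with/without-aponeurosis runs plus the %PA contributions."""

    with_pa: TrialResults
    without_pa: TrialResults
    contributions: dict    # joint -> {"pushoff_pct", "toeoff_pct", "pushoff_time_s"}

    def contributions_table(self) -> pd.DataFrame:
        rows = []
        for joint, c in self.contributions.items():
            rows.append({"joint": joint, **c})
        return pd.DataFrame(rows)


def analyze_trial(gait: TrialBundle, static, config: SubjectConfig,
                  events: GaitEvents | None = None) -> AnalysisResult:
    """Run the chain with and without the aponeurosis on identical inputs
    and quantify its contribution to the MTP and midtarsal flexion moments
    at push-off (and, for reference, at the toe-off sample)."""
    res_with = run_trial(gait, static, config, with_pa=True, events=events)
    res_without = run_trial(gait, static, config, with_pa=False, events=events)
    ev = res_without.events
    contributions = {}
    if ev is not None:
        for joint in ("mtp", "midtarsal"):
            n_w = res_with.loads[joint].moment_prox[:, 1]
            n_wo = res_without.loads[joint].moment_prox[:, 1]
            idx = find_pushoff_index(n_wo, res_without.time, ev)
            idx_to = int(np.argmin(np.abs(res_without.time - ev.toe_off)))
            contributions[joint] = {
                "pushoff_pct": pa_contribution(n_w, n_wo, idx),
                "toeoff_pct": pa_contribution(n_w, n_wo, idx_to),
                "pushoff_time_s": float(res_without.time[idx]),
            }
    return AnalysisResult(with_pa=res_with, without_pa=res_without,
                          contributions=contributions)


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------

MASS_SCALES = (0.5, 1.0, 1.5)
LENGTH_FRACTIONS = (0.96, 0.98, 1.00)
STRAINS = (0.04, 0.07, 0.10)


def run_sensitivity(gait: TrialBundle, static, config: SubjectConfig,
                    mass_scales=MASS_SCALES, fractions=LENGTH_FRACTIONS,
                    strains=STRAINS, events: GaitEvents | None = None) -> pd.DataFrame:
    """Joint-moment sensitivity over the parameter grid.

    Grid: mass/inertia × {0.5, 1.0, 1.5}; natural-length fraction
    {0.96, 0.98, 1.00}; calibration strain {0.04, 0.07, 0.10}.  Each row
    holds the per-axis extrema of the reported joint moments, the peak net
    aponeurosis force, and the %PA contributions.  The aponeurosis-free
    reference run is recomputed once per mass scale (it does not depend on
    the spring parameters).
    """
    rows = []
    for m_scale in mass_scales:
        cfg_base = replace(config, mass_inertia_scale=m_scale)
        res_wo = run_trial(gait, static, cfg_base, with_pa=False, events=events)
        for fraction in fractions:
            for strain in strains:
                cfg = replace(cfg_base, natural_length_fraction=fraction,
                              pushoff_strain=strain)
                res = run_trial(gait, static, cfg, with_pa=True, events=events)
                row = {"mass_scale": m_scale,
                       "natural_length_fraction": fraction,
                       "strain": strain,
                       "pa_force_peak_n": float(res.pa_state.tension.sum(axis=1).max())}
                for joint, load in res.loads.items():
                    for i, axis in enumerate(("x", "y", "z")):
                        row[f"{joint}_moment_{axis}_max_nm"] = float(load.moment_reported[:, i].max())
                        row[f"{joint}_moment_{axis}_min_nm"] = float(load.moment_reported[:, i].min())
                ev = res_wo.events
                for joint in ("mtp", "midtarsal"):
                    if ev is None:
                        row[f"{joint}_pa_contribution_pushoff_pct"] = float("nan")
                        row[f"{joint}_pa_contribution_toeoff_pct"] = float("nan")
                        continue
                    n_w = res.loads[joint].moment_prox[:, 1]
                    n_wo = res_wo.loads[joint].moment_prox[:, 1]
                    idx = find_pushoff_index(n_wo, res_wo.time, ev)
                    idx_to = int(np.argmin(np.abs(res_wo.time - ev.toe_off)))
                    row[f"{joint}_pa_contribution_pushoff_pct"] = \
                        pa_contribution(n_w, n_wo, idx)
                    row[f"{joint}_pa_contribution_toeoff_pct"] = \
                        pa_contribution(n_w, n_wo, idx_to)
                rows.append(row)
    return pd.DataFrame(rows)
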