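"""Signal filtering, joint-angle extraction and rigid-body differentiation.

Joint angles are intrinsic Euler decompositions of the relative rotation
``R = B_prox^T B_dist``: the ankle (shank→hindfoot) uses the y-x-z sequence,
the midtarsal (hindfoot→forefoot) and MTP (forefoot→phalanx) joints use
z-x-y, so the dominant flexion axis is the final rotation.  Angles about
(x, y, z) represent inversion–eversion, plantarflexion–dorsiflexion and
adduction–abduction; the reporting convention is positive eversion,
dorsiflexion and abduction (see :func:`angle_sign_convention`).  The MTP
joint is treated as a flexion hinge, so only its y angle is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.spatial.transform import Rotation

from .errors import PafootError
from .foot_geometry import SegmentFrame
from .io_formats import MarkerSeries, PlateSeries

#: scipy sequence strings for the intrinsic conventions, per joint
JOINT_SEQUENCES = {"ankle": "YXZ", "midtarsal": "ZXY", "mtp": "ZXY"}

#: |middle angle| (deg) beyond which a frame is flagged as near gimbal lock
GIMBAL_LIMIT_DEG = 89.9


# ---------------------------------------------------------------------------
# zero-lag filtering
# ---------------------------------------------------------------------------

def zero_lag_butterworth(series: np.ndarray, fs_hz: float, cutoff_hz: float = 10.0,
                         order: int = 4, axis: int = 0) -> np.ndarray:
    """Forward–backward (zero phase lag) low-pass Butterworth filter.

    The filter is designed at ``order`` and applied twice, so the magnitude
    response at the cutoff is (1/√2)² = 0.5.  Endpoints are padded with odd
    reflection; the cascade is run as second-order sections, which keeps the
    DC gain exact to machine precision even at high sample-rate/cutoff
    ratios.
    """
    series = np.asarray(series, dtype=float)
    if fs_hz <= 2.0 * cutoff_hz:
        raise PafootError(
            f"sampling rate {fs_hz} Hz too low for a {cutoff_hz} Hz cutoff")
    sos = butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if series.shape[axis] <= padlen:
        raise PafootError(
            f"series of length {series.shape[axis]} too short to filter "
            f"(needs > {padlen} samples)")
    return sosfiltfilt(sos, series, axis=axis, padtype="odd")


def filter_markers(markers: MarkerSeries, cutoff_hz: float = 10.0,
                   order: int = 4) -> MarkerSeries:
    return replace(markers, positions=zero_lag_butterworth(
        markers.positions, markers.rate, cutoff_hz, order, axis=0))


def filter_and_decimate_plate(plate: PlateSeries, marker_time: np.ndarray,
                              cutoff_hz: float = 10.0, order: int = 4) -> PlateSeries:
    """Low-pass a plate record, then pick the samples nearest the marker
    clock so kinetics run on a single time base."""
    force = zero_lag_butterworth(plate.force, plate.rate, cutoff_hz, order, axis=0)
    cop = zero_lag_butterworth(plate.cop, plate.rate, cutoff_hz, order, axis=0)
    mz = zero_lag_butterworth(plate.free_moment_z, plate.rate, cutoff_hz, order, axis=0)
    idx = np.clip(np.searchsorted(plate.time, marker_time - 0.5 / plate.rate),
                  0, plate.time.size - 1)
    rate = 1.0 / np.median(np.diff(marker_time))
    return PlateSeries(time=np.asarray(marker_time, dtype=float),
                       force=force[idx], cop=cop[idx],
                       free_moment_z=mz[idx], rate=rate)


# ---------------------------------------------------------------------------
# relative orientation and Euler angles
# ---------------------------------------------------------------------------

def relative_rotation(proximal: SegmentFrame | np.ndarray,
                      distal: SegmentFrame | np.ndarray) -> np.ndarray:
    """Rotation of the distal frame expressed in the proximal frame,
    ``R = B_prox^T B_dist``, shape (T, 3, 3)."""
    bp = proximal.basis if isinstance(proximal, SegmentFrame) else np.asarray(proximal)
    bd = distal.basis if isinstance(distal, SegmentFrame) else np.asarray(distal)
    return np.einsum("tji,tjk->tik", bp, bd)


def euler_angles(R_rel: np.ndarray, sequence: str):
    """Decompose relative rotations into intrinsic Euler angles (degrees).

    Returns ``(angles, gimbal)``: ``angles`` has shape (T, 3) ordered as
    (x, y, z) regardless of the sequence; ``gimbal`` flags frames whose
    middle (x) angle exceeds ±89.9°.
    """
    sequence = sequence.upper()
    if sequence not in ("YXZ", "ZXY"):
        raise PafootError(f"unsupported Euler sequence {sequence!r}")
    R_rel = np.asarray(R_rel, dtype=float)
    squeeze = R_rel.ndim == 2
    if squeeze:
        R_rel = R_rel[None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns at exact gimbal lock
        seq_angles = Rotation.from_matrix(R_rel).as_euler(sequence, degrees=True)
    order = {axis: i for i, axis in enumerate(sequence)}
    angles = np.stack([seq_angles[:, order["X"]],
                       seq_angles[:, order["Y"]],
                       seq_angles[:, order["Z"]]], axis=-1)
    gimbal = np.abs(angles[:, 0]) > GIMBAL_LIMIT_DEG
    if squeeze:
        return angles[0], gimbal[0]
    return angles, gimbal


def compose_euler(angles_xyz, sequence: str) -> np.ndarray:
    """Inverse of :func:`euler_angles`: build rotation matrices from
    (x, y, z)-ordered intrinsic angles in degrees."""
    sequence = sequence.upper()
    angles_xyz = np.atleast_2d(np.asarray(angles_xyz, dtype=float))
    lookup = {"X": 0, "Y": 1, "Z": 2}
    seq_ordered = np.stack([angles_xyz[:, lookup[axis]] for axis in sequence], axis=-1)
    return Rotation.from_euler(sequence, seq_ordered, degrees=True).as_matrix()


def angle_sign_convention(side: str) -> np.ndarray:
    """Per-axis signs mapping raw (x, y, z) Euler components to the reported
    +eversion / +dorsiflexion / +abduction convention.

    With segment y lateral (right foot) the raw decomposition already gives
    positive eversion and dorsiflexion but positive *adduction*; the mirrored
    left-foot frames flip the x reading instead.
    """
    return np.array([1.0, 1.0, -1.0]) if side == "right" else np.array([-1.0, 1.0, 1.0])


@dataclass
class JointAngleSeries:
    """Per-joint angle trajectories in the reported sign convention."""

    time: np.ndarray
    angles: dict              # joint -> (T, 3) deg, (x: inv/ev, y: pf/df, z: add/abd)
    sequences: dict           # joint -> sequence tag
    gimbal: dict              # joint -> (T,) bool
    quiet_standing: dict | None = None   # joint -> (3,) deg reference angles


def joint_angle_series(frames: dict, time: np.ndarray, side: str = "right",
                       quiet_standing: dict | None = None) -> JointAngleSeries:
    """Angles of the ankle, midtarsal and MTP joints from segment frames."""
    pairs = {"ankle": ("shank", "hindfoot"),
             "midtarsal": ("hindfoot", "forefoot"),
             "mtp": ("forefoot", "phalanx")}
    signs = angle_sign_convention(side)
    angles, gimbal = {}, {}
    for joint, (prox, dist) in pairs.items():
        raw, flags = euler_angles(relative_rotation(frames[prox], frames[dist]),
                                  JOINT_SEQUENCES[joint])
        angles[joint] = raw * signs
        gimbal[joint] = flags
    qs = None
    if quiet_standing is not None:
        qs_angles = joint_angle_series(quiet_standing["frames"],
                                       quiet_standing["time"], side)
        qs = {j: a.mean(axis=0) for j, a in qs_angles.angles.items()}
    return JointAngleSeries(time=np.asarray(time), angles=angles,
                            sequences=dict(JOINT_SEQUENCES), gimbal=gimbal,
                            quiet_standing=qs)


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def angular_velocity(basis: np.ndarray, dt: float) -> np.ndarray:
    """Lab-frame angular velocity from a basis time series.

    ω is the axial vector of the skew-symmetric part of Ṁ·Mᵀ with Ṁ by
    central differences (second-order one-sided at the ends).
    """
    basis = np.asarray(basis, dtype=float)
    if basis.shape[0] < 3:
        raise PafootError("angular velocity needs at least 3 time steps")
    mdot = np.gradient(basis, dt, axis=0, edge_order=2)
    omega_mat = np.einsum("tij,tkj->tik", mdot, basis)
    skew = 0.5 * (omega_mat - np.transpose(omega_mat, (0, 2, 1)))
    return np.stack([skew[:, 2, 1], skew[:, 0, 2], skew[:, 1, 0]], axis=-1)


def angular_acceleration(omega: np.ndarray, dt: float) -> np.ndarray:
    return np.gradient(np.asarray(omega, dtype=float), dt, axis=0, edge_order=2)


def com_acceleration(com: np.ndarray, dt: float) -> np.ndarray:
    """Second derivative of COM trajectories by repeated central differences
    (exact for quadratic paths, including the one-sided endpoints)."""
    com = np.asarray(com, dtype=float)
    if com.shape[0] < 3:
        raise PafootError("COM acceleration needs at least 3 time steps")
    vel = np.gradient(com, dt, axis=0, edge_order=2)
    return np.gradient(vel, dt, axis=0, edge_order=2)


@dataclass
class SegmentMotion:
    """Angular velocity/acceleration of one segment (lab frame)."""

    omega: np.ndarray   # (T, 3) rad/s
    alpha: np.ndarray   # (T, 3) rad/s^2


def segment_motion(frame: SegmentFrame, dt: float) -> SegmentMotion:
    omega = angular_velocity(frame.basis, dt)
    return SegmentMotion(omega=omega, alpha=angular_acceleration(omega, dt))


# ---------------------------------------------------------------------------
# gait events and cycle normalization
# ---------------------------------------------------------------------------

@dataclass
class GaitEvents:
    heel_strike: float
    toe_off: float
    next_heel_strike: float | None = None

    @property
    def stance_fraction(self) -> float | None:
        if self.next_heel_strike is None:
            return None
        return (self.toe_off - self.heel_strike) / (self.next_heel_strike - self.heel_strike)


def detect_contact_events(plate1: PlateSeries, plate2: PlateSeries,
                          threshold_n: float = 10.0) -> tuple[float, float]:
    """Heel strike and toe off from the combined vertical plate force
    crossing ``threshold_n`` (first rising / last falling edge)."""
    fz = plate1.force[:, 2] + plate2.force[:, 2]
    loaded = fz > threshold_n
    if not loaded.any():
        raise PafootError("no plate contact above threshold")
    idx = np.nonzero(loaded)[0]
    return float(plate1.time[idx[0]]), float(plate1.time[idx[-1]])


def gait_cycle_normalize(time: np.ndarray, series: np.ndarray,
                         events: GaitEvents, n_points: int = 101) -> np.ndarray:
    """Linearly resample a series onto 0–100 % of the gait cycle."""
    if events.next_heel_strike is None:
        raise PafootError("cycle normalization needs the next heel strike")
    grid = np.linspace(events.heel_strike, events.next_heel_strike, n_points)
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        return np.interp(grid, time, series)
    flat = series.reshape(series.shape[0], -1)
    out = np.stack([np.interp(grid, time, flat[:, j]) for j in range(flat.shape[1])],
                   axis=-1)
    return out.reshape((n_points,) + series.shape[1:])
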