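"""Five-spring plantar aponeurosis model.

Each slip (PA1–PA5, medial to lateral) is an independent tension-only linear
spring running from the shared calcaneal origin over a fixed frictionless
via point on the forefoot's plantar surface to its phalangeal insertion.
Its length is the two-leg polyline

    L_i = |r_ins - r_via| + |r_via - r_ori|,

its tension is ``f_i = max(0, k_i (L_i - L0_i))`` with natural length
``L0_i = c · Lqs_i`` (``c`` = 0.98 by default, ``Lqs_i`` the quiet-standing
length), and its stiffness is calibrated so that at a push-off strain of
ε = 0.07 the five slips jointly transmit 1.5 body weights:

    k_i = g · 1.5 · BW / (5 · ε · c · Lqs_i).

The tension acts along the polyline legs: the insertion and origin are each
pulled toward the via point, and the via point receives the closing force,
so every slip applies a zero net force *and* zero net moment to the foot as
a whole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, PafootError
from .foot_geometry import PAAttachmentSet, build_segment_frames, place_pa_points
from .io_formats import MarkerSeries

#: minimum attachment/via separation (m) for a defined force direction
MIN_SEPARATION = 1e-9


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def pa_length(r_ori: np.ndarray, r_via: np.ndarray, r_ins: np.ndarray) -> np.ndarray:
    """Polyline length origin → via → insertion; broadcasts over leading axes."""
    r_ori, r_via, r_ins = (np.asarray(a, dtype=float) for a in (r_ori, r_via, r_ins))
    return (np.linalg.norm(r_ins - r_via, axis=-1)
            + np.linalg.norm(r_via - r_ori, axis=-1))


def quiet_standing_lengths(static_markers: MarkerSeries,
                           attachments: PAAttachmentSet,
                           side: str = "right") -> np.ndarray:
    """Per-slip mean length over the quiet-standing frames, shape (5,)."""
    frames, _ = build_segment_frames(static_markers, side)
    r_ori, r_via, r_ins = place_pa_points(attachments, frames)
    lengths = pa_length(r_ori[:, None, :], r_via, r_ins)   # (T, 5)
    return lengths.mean(axis=0)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def natural_length(Lqs, fraction: float = 0.98):
    """Natural length as a fraction of the quiet-standing length (the arch
    flattens slightly under body weight, so the standing aponeurosis is
    already a little stretched)."""
    Lqs = np.asarray(Lqs, dtype=float)
    if np.any(Lqs <= 0) or fraction <= 0:
        raise PafootError("natural_length requires positive lengths and fraction")
    return fraction * Lqs


def calibrate_stiffness(body_mass_kg: float, Lqs, strain: float = 0.07,
                        force_bw: float = 1.5, fraction: float = 0.98,
                        g: float = 9.8):
    """Per-slip stiffness (N/m).

    Inverts the tension law at push-off: five slips, each stretched by
    ``strain`` of its natural length ``fraction·Lqs``, must jointly carry
    ``force_bw`` body weights.
    """
    Lqs = np.asarray(Lqs, dtype=float)
    if body_mass_kg <= 0 or strain <= 0 or force_bw <= 0 or fraction <= 0 \
            or np.any(Lqs <= 0):
        raise PafootError("calibrate_stiffness requires strictly positive inputs")
    return (g * force_bw * body_mass_kg) / (5.0 * strain * fraction * Lqs)


@dataclass
class PASprings:
    """Calibrated spring set (arrays of length 5, medial→lateral)."""

    k: np.ndarray     # N/m
    L0: np.ndarray    # m
    Lqs: np.ndarray   # m

    def __post_init__(self):
        self.k = np.atleast_1d(np.asarray(self.k, dtype=float))
        self.L0 = np.atleast_1d(np.asarray(self.L0, dtype=float))
        self.Lqs = np.atleast_1d(np.asarray(self.Lqs, dtype=float))
        if np.any(self.k <= 0) or np.any(self.L0 <= 0):
            raise PafootError("spring stiffnesses and natural lengths must be > 0")


def build_pa_springs(static_markers: MarkerSeries, attachments: PAAttachmentSet,
                     body_mass_kg: float, strain: float = 0.07,
                     force_bw: float = 1.5, fraction: float = 0.98,
                     g: float = 9.8, side: str = "right") -> PASprings:
    Lqs = quiet_standing_lengths(static_markers, attachments, side)
    return PASprings(
        k=calibrate_stiffness(body_mass_kg, Lqs, strain, force_bw, fraction, g),
        L0=natural_length(Lqs, fraction),
        Lqs=Lqs,
    )


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def pa_tension(L, L0, k):
    """Tension-only linear spring law: slack slips exert exactly zero."""
    L, L0, k = (np.asarray(a, dtype=float) for a in (L, L0, k))
    return np.maximum(0.0, k * (L - L0))


def pa_force_vectors(r_ori: np.ndarray, r_via: np.ndarray, r_ins: np.ndarray,
                     f_pa: np.ndarray):
    """Tension force vectors on the insertion, origin and via point.

    The endpoint forces point from their attachment toward the via point;
    the via force closes the triangle, so per slip the three forces (and
    their moments about any point) sum to zero.
    Returns ``(f_ins, f_ori, f_via)`` broadcast over leading axes.
    """
    r_ori, r_via, r_ins = (np.asarray(a, dtype=float) for a in (r_ori, r_via, r_ins))
    f_pa = np.asarray(f_pa, dtype=float)
    leg_ins = r_via - r_ins
    leg_ori = r_via - r_ori
    d_ins = np.linalg.norm(leg_ins, axis=-1, keepdims=True)
    d_ori = np.linalg.norm(leg_ori, axis=-1, keepdims=True)
    if np.any(d_ins <= MIN_SEPARATION) or np.any(d_ori <= MIN_SEPARATION):
        raise DegenerateGeometryError(
            "via point coincides with an attachment; force direction undefined")
    f_ins = f_pa[..., None] * leg_ins / d_ins
    f_ori = f_pa[..., None] * leg_ori / d_ori
    f_via = -f_ins - f_ori
    return f_ins, f_ori, f_via


@dataclass
class PAForceState:
    """Per-slip lengths, tensions and attachment force vectors over time."""

    lengths: np.ndarray   # (T, 5) m
    tension: np.ndarray   # (T, 5) N
    f_ins: np.ndarray     # (T, 5, 3) N, on the phalanx insertions
    f_ori: np.ndarray     # (T, 5, 3) N, on the calcaneal origin
    f_via: np.ndarray     # (T, 5, 3) N, on the forefoot via points

    @classmethod
    def zeros(cls, n_frames: int, n_springs: int = 5) -> "PAForceState":
        z = np.zeros((n_frames, n_springs))
        zv = np.zeros((n_frames, n_springs, 3))
        return cls(lengths=z.copy(), tension=z,
                   f_ins=zv.copy(), f_ori=zv.copy(), f_via=zv.copy())


def evaluate_pa(r_ori: np.ndarray, r_via: np.ndarray, r_ins: np.ndarray,
                springs: PASprings) -> PAForceState:
    """Lengths, tensions and force vectors for placed attachment points.

    ``r_ori`` (T, 3) is shared by all slips; ``r_via``/``r_ins`` are (T, 5, 3).
    """
    r_ori5 = np.asarray(r_ori, dtype=float)[:, None, :]
    lengths = pa_length(r_ori5, r_via, r_ins)
    tension = pa_tension(lengths, springs.L0[None, :], springs.k[None, :])
    f_ins, f_ori, f_via = pa_force_vectors(r_ori5, r_via, r_ins, tension)
    return PAForceState(lengths=lengths, tension=tension,
                        f_ins=f_ins, f_ori=f_ori, f_via=f_via)
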