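"""Joint centers, segment coordinate frames, and aponeurosis attachment
geometry.

Segment frames follow the anatomical-landmark definitions of the model:

* hindfoot — y is the normal of the plane through CA, HE and the midtarsal
  joint center; z is the CA–HE axis orthogonalized against y; origin HE;
* forefoot — y is the TN→VMB axis; z is the normal of the TN/VMB/MTP-joint
  plane orthogonalized against y; origin VMB;
* phalanx — y is the FMH→VMH axis; z is the normal of the FMH/VMH/PM plane
  orthogonalized against y; origin VMH;
* shank — z is the ankle-center→knee-center axis (kept exact); y is the
  malleolar medio-lateral axis orthogonalized against z; origin ankle center.

In every case x = y × z, giving right-handed orthonormal bases.  Axis
polarities (the landmark definitions fix directions only up to sign) are
resolved anatomically: z points dorsally (toward CA for the hindfoot,
proximally for the shank) and y points toward the *lateral* side for right
feet and toward the *medial* side for left feet.  The mirrored left-foot rule
keeps dorsiflexion positive about y on both sides; see
:func:`pafoot.kinematics.angle_sign_convention` for how reported angle signs
are derived from this convention.

Attachment coordinates of the five aponeurosis slips are stored in
*anatomical axes* (x anterior, y medial, z dorsal, the axes in which the
normalized attachment table is published).  Because the segment frames above
have x posterior and y lateral (right foot), anatomical coordinates map into
segment axes through the proper rotation ``diag(-1, -1, +1)`` (for left feet
the anatomical y is mirrored first, which composes to ``diag(-1, +1, +1)``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import DegenerateGeometryError
from .io_formats import MarkerSeries

#: minimum triangle area (m^2) accepted when a plane defines an axis
MIN_PLANE_AREA = 1e-9

#: anatomical (x ant, y med, z dors) -> segment-frame axes (x post, y lat, z dors)
ANATOMICAL_TO_SEGMENT = np.diag([-1.0, -1.0, 1.0])


# ---------------------------------------------------------------------------
# vector helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n <= 0) or not np.all(np.isfinite(n)):
        raise DegenerateGeometryError("zero-length or non-finite axis vector")
    return v / n


def _signed(v: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Flip each row of ``v`` so that it has positive dot product with ``ref``."""
    s = np.sign(np.sum(v * ref, axis=-1, keepdims=True))
    if np.any(s == 0):
        raise DegenerateGeometryError("axis polarity reference is orthogonal to axis")
    return v * s


def _plane_normal(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Unit normal of the plane through points a, b, c (rows over time)."""
    n = np.cross(b - a, c - a)
    area = 0.5 * np.linalg.norm(n, axis=-1)
    if np.any(area < MIN_PLANE_AREA):
        raise DegenerateGeometryError(
            f"plane-defining points are (nearly) collinear: min area {area.min():.3e} m^2"
        )
    return _unit(n)


# ---------------------------------------------------------------------------
# joint centers
# ---------------------------------------------------------------------------

@dataclass
class JointCenters:
    """Lab-frame joint center trajectories (T, 3), meters."""

    ankle: np.ndarray      # midpoint ANKL / ANKM
    midtarsal: np.ndarray  # midpoint TN / VMB
    mtp: np.ndarray        # midpoint FMH / VMH


def compute_joint_centers(markers: MarkerSeries) -> JointCenters:
    """Each joint center is the exact midpoint of its defining marker pair."""
    markers.require(("ANKL", "ANKM", "TN", "VMB", "FMH", "VMH"))
    mid = lambda a, b: 0.5 * (markers.get(a) + markers.get(b))
    return JointCenters(
        ankle=mid("ANKL", "ANKM"),
        midtarsal=mid("TN", "VMB"),
        mtp=mid("FMH", "VMH"),
    )


# ---------------------------------------------------------------------------
# segment frames
# ---------------------------------------------------------------------------

@dataclass
class SegmentFrame:
    """Origin plus right-handed orthonormal basis per time step.

    ``basis[t]`` has the segment's x, y, z axes (lab-frame components) as
    *columns*, i.e. it maps segment coordinates to lab coordinates.
    """

    name: str
    origin: np.ndarray   # (T, 3)
    basis: np.ndarray    # (T, 3, 3)

    def __post_init__(self):
        eye = np.eye(3)
        btb = np.einsum("tij,tik->tjk", self.basis, self.basis)
        if not np.allclose(btb, eye, atol=1e-10):
            raise DegenerateGeometryError(f"{self.name}: basis not orthonormal")
        if not np.allclose(np.linalg.det(self.basis), 1.0, atol=1e-10):
            raise DegenerateGeometryError(f"{self.name}: basis not right-handed")

    def to_lab(self, local: np.ndarray) -> np.ndarray:
        """Map points from segment coordinates to the lab frame."""
        return self.origin[:, None, :] + np.einsum(
            "tij,pj->tpi", self.basis, np.atleast_2d(local)
        )


def _assemble(name, origin, y, z_raw, z_ref) -> SegmentFrame:
    """Keep y exact, Gram-Schmidt z against it, x = y × z."""
    z = z_raw - np.sum(z_raw * y, axis=-1, keepdims=True) * y
    z = _signed(_unit(z), z_ref)
    x = np.cross(y, z)
    basis = np.stack([x, y, z], axis=-1)
    return SegmentFrame(name=name, origin=origin, basis=basis)


def _lateral_reference(markers: MarkerSeries) -> np.ndarray:
    """Unit vector pointing toward the lateral side of the foot (both sides:
    the fifth ray lies lateral to the navicular)."""
    return _unit(markers.get("VMB") - markers.get("TN"))


def _y_reference(markers: MarkerSeries, side: str) -> np.ndarray:
    lat = _lateral_reference(markers)
    return lat if side == "right" else -lat


def _dorsal_reference(markers: MarkerSeries, centers: JointCenters, side: str) -> np.ndarray:
    """Pose-following dorsal direction estimate used to fix z-axis signs."""
    anterior = _unit(centers.mtp - centers.midtarsal)
    lat = _lateral_reference(markers)
    dorsal = np.cross(lat, anterior)
    return dorsal if side == "right" else -dorsal


def build_hindfoot_frame(markers: MarkerSeries, centers: JointCenters,
                         side: str = "right") -> SegmentFrame:
    markers.require(("CA", "HE"))
    ca, he = markers.get("CA"), markers.get("HE")
    y = _signed(_plane_normal(ca, he, centers.midtarsal), _y_reference(markers, side))
    return _assemble("hindfoot", he, y, ca - he, ca - he)


def build_forefoot_frame(markers: MarkerSeries, centers: JointCenters,
                         side: str = "right") -> SegmentFrame:
    tn, vmb = markers.get("TN"), markers.get("VMB")
    y = _signed(_unit(vmb - tn), _y_reference(markers, side))
    z_raw = _plane_normal(tn, vmb, centers.mtp)
    return _assemble("forefoot", vmb, y, z_raw,
                     _dorsal_reference(markers, centers, side))


def build_phalanx_frame(markers: MarkerSeries, centers: JointCenters,
                        side: str = "right") -> SegmentFrame:
    markers.require(("PM",))
    fmh, vmh, pm = markers.get("FMH"), markers.get("VMH"), markers.get("PM")
    y = _signed(_unit(vmh - fmh), _y_reference(markers, side))
    z_raw = _plane_normal(fmh, vmh, pm)
    return _assemble("phalanx", vmh, y, z_raw,
                     _dorsal_reference(markers, centers, side))


def build_shank_frame(markers: MarkerSeries, side: str = "right") -> SegmentFrame:
    """Shank frame: z exact along ankle-center→knee-center, y from the
    malleolar pair orthogonalized against z, x = y × z, origin ankle center."""
    markers.require(("ANKL", "ANKM", "KNEL", "KNEM"))
    ankle = 0.5 * (markers.get("ANKL") + markers.get("ANKM"))
    knee = 0.5 * (markers.get("KNEL") + markers.get("KNEM"))
    z = _unit(knee - ankle)
    ml = markers.get("ANKL") - markers.get("ANKM")   # points lateral
    y_raw = ml if side == "right" else -ml
    y = y_raw - np.sum(y_raw * z, axis=-1, keepdims=True) * z
    y = _unit(y)
    x = np.cross(y, z)
    return SegmentFrame(name="shank", origin=ankle,
                        basis=np.stack([x, y, z], axis=-1))


def build_segment_frames(markers: MarkerSeries, side: str = "right"):
    """All four frames plus the joint centers for a trial."""
    centers = compute_joint_centers(markers)
    frames = {
        "hindfoot": build_hindfoot_frame(markers, centers, side),
        "forefoot": build_forefoot_frame(markers, centers, side),
        "phalanx": build_phalanx_frame(markers, centers, side),
        "shank": build_shank_frame(markers, side),
    }
    return frames, centers


# ---------------------------------------------------------------------------
# aponeurosis attachments
# ---------------------------------------------------------------------------

def load_attachment_table() -> dict:
    """Normalized attachment coordinates (right foot, anatomical axes)."""
    text = resources.files("pafoot.data").joinpath("pa_attachments.json").read_text()
    raw = json.loads(text)
    return {
        "insertions": np.asarray(raw["insertions"], dtype=float),
        "via_points": np.asarray(raw["via_points"], dtype=float),
        "origin": np.asarray(raw["origin"], dtype=float),
    }


@dataclass
class PAAttachmentSet:
    """Subject-scaled attachment coordinates of the five aponeurosis slips.

    ``*_anatomical`` are the published normalized coordinates times ``scale``
    (anatomical axes: x anterior, y medial, z dorsal; left feet mirrored).
    ``insertion_local`` / ``via_local`` / ``origin_local`` are the same points
    expressed in the phalanx / forefoot / hindfoot frame axes and are what
    :func:`place_pa_points` maps to the lab frame.
    """

    scale: float
    side: str
    insertion_anatomical: np.ndarray  # (5, 3) m
    via_anatomical: np.ndarray        # (5, 3) m
    origin_anatomical: np.ndarray     # (3,)  m, shared by all five slips
    insertion_local: np.ndarray       # (5, 3) m, phalanx frame (origin VMH)
    via_local: np.ndarray             # (5, 3) m, forefoot frame (origin VMB)
    origin_local: np.ndarray          # (3,)  m, hindfoot frame (origin HE)

    @property
    def n_springs(self) -> int:
        return self.insertion_local.shape[0]


def scale_pa_attachments(static_markers: MarkerSeries, side: str = "right",
                         table: dict | None = None) -> PAAttachmentSet:
    """Scale the normalized attachment table to a subject.

    The scale is the quiet-standing mean of |ANKL − VMH|.  Left feet mirror
    the table's medio-lateral (y) coordinate.
    """
    if table is None:
        table = load_attachment_table()
    static_markers.require(("ANKL", "VMH"))
    scale = float(np.mean(np.linalg.norm(
        static_markers.get("ANKL") - static_markers.get("VMH"), axis=-1)))
    if not np.isfinite(scale) or scale <= 0:
        raise DegenerateGeometryError(f"invalid attachment scale {scale}")

    mirror = np.array([1.0, -1.0, 1.0]) if side == "left" else np.ones(3)
    ins_anat = table["insertions"] * mirror * scale
    via_anat = table["via_points"] * mirror * scale
    ori_anat = table["origin"] * mirror * scale
    A = ANATOMICAL_TO_SEGMENT
    return PAAttachmentSet(
        scale=scale, side=side,
        insertion_anatomical=ins_anat, via_anatomical=via_anat,
        origin_anatomical=ori_anat,
        insertion_local=ins_anat @ A.T, via_local=via_anat @ A.T,
        origin_local=A @ ori_anat,
    )


def place_pa_points(attachments: PAAttachmentSet, frames: dict):
    """Lab-frame attachment trajectories.

    Returns ``(r_ori, r_via, r_ins)`` with shapes (T, 3), (T, 5, 3), (T, 5, 3);
    each point is ``origin + basis · p_local`` of its host frame.
    """
    r_ins = frames["phalanx"].to_lab(attachments.insertion_local)
    r_via = frames["forefoot"].to_lab(attachments.via_local)
    r_ori = frames["hindfoot"].to_lab(attachments.origin_local[None, :])[:, 0, :]
    return r_ori, r_via, r_ins
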