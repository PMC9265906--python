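"""Subject scaling of the CT-derived relative inertial constants.

The total foot mass is taken as a fixed fraction of body mass (default
0.0145).  Per-segment masses are fixed percentages of the foot mass; each
segment's COM lies on the line from its proximal to its distal joint center
at a fixed fraction of segment length; and the inertia tensor about the COM,
expressed in the segment frame, scales with mass as ``I = I_rel · m^(5/3)``
(the relative tensors are normalized by the 5/3 power of segment mass, the
exponent that makes a shape-preserving, constant-density family exactly
self-similar).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import ConfigError, PafootError

SEGMENTS = ("phalanx", "forefoot", "hindfoot")


# ---------------------------------------------------------------------------
# relative table
# ---------------------------------------------------------------------------

@dataclass
class RelativeInertialTable:
    """Relative (size-normalized) inertial constants per segment."""

    mass_pct: dict     # segment -> % of foot mass
    com_pct: dict      # segment -> % of segment length from the proximal joint
    tensor: dict       # segment -> (3, 3) symmetric, kg·m²·kg^(-5/3)

    def __post_init__(self):
        total = sum(self.mass_pct[s] for s in SEGMENTS)
        if abs(total - 100.0) > 0.1:
            raise ConfigError(f"relative segment masses sum to {total} %, not 100 %")
        for seg in SEGMENTS:
            T = np.asarray(self.tensor[seg], dtype=float)
            if not np.allclose(T, T.T):
                raise ConfigError(f"{seg}: relative tensor not symmetric")
            if np.any(np.diag(T) <= 0):
                raise ConfigError(f"{seg}: relative tensor diagonal must be > 0")
            self.tensor[seg] = T


def _symmetric_from_lower(entries: dict) -> np.ndarray:
    T = np.array([
        [entries["Ixx"], entries["Iyx"], entries["Izx"]],
        [entries["Iyx"], entries["Iyy"], entries["Izy"]],
        [entries["Izx"], entries["Izy"], entries["Izz"]],
    ], dtype=float)
    return T


def load_relative_inertia(path=None) -> RelativeInertialTable:
    """Load the shipped relative-inertia table (or an override file of the
    same JSON schema)."""
    if path is None:
        text = resources.files("pafoot.data").joinpath("relative_inertia.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)["segments"]
    return RelativeInertialTable(
        mass_pct={s: float(raw[s]["relative_mass_pct"]) for s in SEGMENTS},
        com_pct={s: float(raw[s]["relative_com_pct"]) for s in SEGMENTS},
        tensor={s: _symmetric_from_lower(raw[s]["tensor"]) for s in SEGMENTS},
    )


# ---------------------------------------------------------------------------
# scaling operations
# ---------------------------------------------------------------------------

def foot_mass(body_mass_kg: float, fraction: float = 0.0145) -> float:
    if body_mass_kg <= 0 or fraction <= 0:
        raise PafootError("foot_mass requires positive body mass and fraction")
    return body_mass_kg * fraction


def segment_masses(foot_mass_kg: float, table: RelativeInertialTable) -> dict:
    """Segment masses (kg); they sum to the foot mass exactly."""
    if foot_mass_kg <= 0:
        raise PafootError("segment_masses requires a positive foot mass")
    return {s: foot_mass_kg * table.mass_pct[s] / 100.0 for s in SEGMENTS}


def segment_inertia(mass_kg: float, relative_tensor: np.ndarray) -> np.ndarray:
    """Inertia tensor about the COM in the segment frame, kg·m²."""
    if mass_kg <= 0:
        raise PafootError("segment_inertia requires a positive mass")
    I = np.asarray(relative_tensor, dtype=float) * mass_kg ** (5.0 / 3.0)
    I = 0.5 * (I + I.T)
    eig = np.linalg.eigvalsh(I)
    if np.any(eig <= 0):
        raise PafootError("scaled inertia tensor is not positive definite")
    return I


def segment_com(prox_joint: np.ndarray, dist_point: np.ndarray,
                com_fraction: float) -> np.ndarray:
    """COM on the proximal→distal line at ``com_fraction`` of its length."""
    prox = np.asarray(prox_joint, dtype=float)
    dist = np.asarray(dist_point, dtype=float)
    return prox + com_fraction * (dist - prox)


@dataclass
class SegmentInertia:
    """Scaled inertial parameters of one segment."""

    mass: float               # kg
    com_fraction: float       # proximal→distal, dimensionless
    inertia: np.ndarray       # (3, 3) kg·m², segment frame, about the COM


def build_segment_inertias(body_mass_kg: float, foot_mass_fraction: float = 0.0145,
                           table: RelativeInertialTable | None = None,
                           mass_inertia_scale: float = 1.0) -> dict:
    """All three segments scaled to a subject.

    ``mass_inertia_scale`` multiplies both the masses and the tensors
    directly (it perturbs the final parameters, the 5/3 rule is not
    re-applied), as the sensitivity analysis prescribes.
    """
    if table is None:
        table = load_relative_inertia()
    if mass_inertia_scale <= 0:
        raise PafootError("mass_inertia_scale must be > 0")
    m_foot = foot_mass(body_mass_kg, foot_mass_fraction)
    masses = segment_masses(m_foot, table)
    out = {}
    for seg in SEGMENTS:
        inertia = segment_inertia(masses[seg], table.tensor[seg])
        out[seg] = SegmentInertia(
            mass=masses[seg] * mass_inertia_scale,
            com_fraction=table.com_pct[seg] / 100.0,
            inertia=inertia * mass_inertia_scale,
        )
    return out
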