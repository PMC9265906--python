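"""Trial containers and file readers/writers.

The lab frame is fixed throughout the package: right-handed, ``x`` along the
walking direction, ``z`` vertical up (so ``y`` points to the subject's left).
All readers convert to SI on ingestion (positions m, forces N, moments N·m);
marker labels are upper-cased.

Reference dialects:

* markers — TRC (tab-separated, ``DataRate``/``Units`` header, X/Y/Z triplets
  per label);
* force plates — long CSV with columns
  ``time, plate, fx, fy, fz, copx, copy, copz, mz`` (plate id 1 = front,
  2 = rear);
* subject configuration — YAML with units in the key names;
* results — tidy CSV tables plus a JSON run log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, MissingMarkerError

#: the 14 foot landmarks of the marker protocol
FOOT_MARKERS = (
    "PM", "FMH", "SMH", "VMH", "FMB", "SMB", "VMB",
    "TN", "ST", "PT", "CA", "HE", "ANKL", "ANKM",
)
#: shank landmarks (femoral epicondyle pair) needed for the shank frame
SHANK_MARKERS = ("KNEL", "KNEM")
#: full set a trial must provide
REQUIRED_MARKERS = FOOT_MARKERS + SHANK_MARKERS

PLATE_COLUMNS = ("time", "plate", "fx", "fy", "fz", "copx", "copy", "copz", "mz")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MarkerSeries:
    """Labeled 3D landmark trajectories in the lab frame (meters)."""

    time: np.ndarray            # (T,) seconds, strictly increasing
    labels: list[str]
    positions: np.ndarray       # (T, L, 3) meters
    rate: float                 # Hz

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.labels = [str(l).upper() for l in self.labels]
        if self.positions.shape != (self.time.size, len(self.labels), 3):
            raise FormatError(
                f"marker array shape {self.positions.shape} inconsistent with "
                f"{self.time.size} frames x {len(self.labels)} labels"
            )
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise FormatError("marker time base is not strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise FormatError("marker positions contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.time.size

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label.upper())
        except ValueError:
            raise MissingMarkerError([label.upper()]) from None

    def get(self, label: str) -> np.ndarray:
        """Trajectory of one landmark, shape (T, 3)."""
        return self.positions[:, self.index(label), :]

    def require(self, labels=REQUIRED_MARKERS) -> None:
        missing = [l for l in labels if l.upper() not in self.labels]
        if missing:
            raise MissingMarkerError(missing)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MarkerSeries":
        """Apply one rigid transform ``x -> R x + t`` to every marker."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return replace(self, positions=self.positions @ R.T + t)


@dataclass
class PlateSeries:
    """One force plate's record: resultant force, COP, vertical free moment."""

    time: np.ndarray            # (N,) s
    force: np.ndarray           # (N, 3) N
    cop: np.ndarray             # (N, 3) m
    free_moment_z: np.ndarray   # (N,) N·m, vertical free moment about the COP
    rate: float                 # Hz

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.cop = np.asarray(self.cop, dtype=float)
        self.free_moment_z = np.asarray(self.free_moment_z, dtype=float)
        n = self.time.size
        if self.force.shape != (n, 3) or self.cop.shape != (n, 3) \
                or self.free_moment_z.shape != (n,):
            raise FormatError("plate arrays have inconsistent shapes")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise FormatError("plate time base is not strictly increasing")

    @classmethod
    def zeros(cls, time: np.ndarray, rate: float) -> "PlateSeries":
        n = np.asarray(time).size
        return cls(time=np.asarray(time, dtype=float),
                   force=np.zeros((n, 3)), cop=np.zeros((n, 3)),
                   free_moment_z=np.zeros(n), rate=rate)


@dataclass
class TrialBundle:
    """One trial: marker trajectories plus the two force-plate records."""

    markers: MarkerSeries
    plates: tuple[PlateSeries, PlateSeries]   # (plate 1 front, plate 2 rear)
    body_mass_kg: float | None = None
    side: str = "right"

    def __post_init__(self):
        self.markers.require(REQUIRED_MARKERS)


# ---------------------------------------------------------------------------
# subject / analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class SubjectConfig:
    """Subject anthropometry and model parameters.

    Defaults reproduce the reference calibration: the foot carries 1.45 % of
    body mass; each aponeurosis slip has natural length 0.98 of its
    quiet-standing length and is calibrated so that at 7 % push-off strain
    the five slips jointly transmit 1.5 body weights.
    """

    body_mass_kg: float
    side: str = "right"
    foot_mass_fraction: float = 0.0145
    natural_length_fraction: float = 0.98
    pushoff_strain: float = 0.07
    pushoff_force_bw: float = 1.5
    filter_order: int = 4
    filter_cutoff_hz: float = 10.0
    gravity: float = 9.8                     # m/s^2, as used in the calibration
    contact_threshold_n: float = 10.0
    mass_inertia_scale: float = 1.0          # sensitivity-analysis multiplier

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ConfigError(f"side must be 'left' or 'right', got {self.side!r}")
        positive = {
            "body_mass_kg": self.body_mass_kg,
            "foot_mass_fraction": self.foot_mass_fraction,
            "natural_length_fraction": self.natural_length_fraction,
            "pushoff_strain": self.pushoff_strain,
            "pushoff_force_bw": self.pushoff_force_bw,
            "filter_order": self.filter_order,
            "filter_cutoff_hz": self.filter_cutoff_hz,
            "gravity": self.gravity,
            "contact_threshold_n": self.contact_threshold_n,
            "mass_inertia_scale": self.mass_inertia_scale,
        }
        for name, value in positive.items():
            if not np.isfinite(value) or value <= 0:
                raise ConfigError(f"{name} must be strictly positive, got {value}")
        if self.natural_length_fraction > 1.0:
            raise ConfigError("natural_length_fraction must lie in (0, 1]")

    # -- YAML round trip ---------------------------------------------------

    _YAML_KEYS = {
        "body_mass_kg": "body_mass_kg",
        "side": "side",
        "foot_mass_fraction": "foot_mass_fraction",
        "natural_length_fraction": "pa_natural_length_fraction",
        "pushoff_strain": "pa_pushoff_strain",
        "pushoff_force_bw": "pa_pushoff_force_bw",
        "filter_order": "filter_order",
        "filter_cutoff_hz": "filter_cutoff_hz",
        "gravity": "gravity_m_s2",
        "contact_threshold_n": "contact_threshold_n",
        "mass_inertia_scale": "mass_inertia_scale",
    }

    def to_dict(self) -> dict:
        return {yk: getattr(self, attr) for attr, yk in self._YAML_KEYS.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectConfig":
        inverse = {yk: attr for attr, yk in cls._YAML_KEYS.items()}
        kwargs = {}
        for key, value in d.items():
            if key not in inverse:
                raise ConfigError(f"unknown configuration key {key!r}")
            kwargs[inverse[key]] = value
        if "body_mass_kg" not in kwargs:
            raise ConfigError("configuration must provide body_mass_kg")
        return cls(**kwargs)


def read_config(path) -> SubjectConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a YAML mapping")
    return SubjectConfig.from_dict(data)


def write_config(config: SubjectConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# TRC marker files
# ---------------------------------------------------------------------------

def read_trc(path, require_labels=REQUIRED_MARKERS) -> MarkerSeries:
    """Read a TRC marker file.

    Positions are converted to meters (``Units`` header of ``mm`` or ``m``),
    labels are upper-cased and the time vector is rebuilt from the header
    ``DataRate``. ``require_labels`` (default: the full landmark set) is
    checked after reading; pass ``None`` to skip.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 5:
        raise FormatError(f"{path}: truncated TRC file")

    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_keys, header_vals))
    try:
        rate = float(header["DataRate"])
        units = header["Units"].strip().lower()
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: malformed TRC header: {exc}") from None
    if units not in ("mm", "m"):
        raise FormatError(f"{path}: unsupported Units {units!r}")
    to_m = 1e-3 if units == "mm" else 1.0

    label_cells = lines[3].split("\t")[2:]
    labels = [c.strip().upper() for c in label_cells if c.strip()]
    if not labels:
        raise FormatError(f"{path}: no marker labels found")

    rows = []
    for line in lines[5:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        rows.append([float(c) for c in cells[2:2 + 3 * len(labels)]])
    if not rows:
        raise FormatError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    if data.shape[1] != 3 * len(labels):
        raise FormatError(
            f"{path}: expected {3 * len(labels)} coordinate columns, "
            f"got {data.shape[1]}"
        )
    positions = data.reshape(len(rows), len(labels), 3) * to_m
    time = np.arange(len(rows)) / rate

    series = MarkerSeries(time=time, labels=labels, positions=positions, rate=rate)
    if require_labels is not None:
        series.require(require_labels)
    return series


def write_trc(series: MarkerSeries, path, units: str = "m") -> None:
    """Write a MarkerSeries as TRC. The default meter units with ``%.17g``
    formatting make a write/read round trip reproduce the arrays exactly
    (a mm round trip is exact only to the 1000×-scaling ulp)."""
    if units not in ("mm", "m"):
        raise FormatError(f"unsupported Units {units!r}")
    scale = 1e3 if units == "mm" else 1.0
    path = Path(path)
    T, L = series.n_frames, len(series.labels)
    g = "%.17g"
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{g % series.rate}\t{g % series.rate}\t{T}\t{L}\t{units}\t"
        f"{g % series.rate}\t1\t{T}",
        "Frame#\tTime\t" + "\t\t\t".join(series.labels) + "\t\t",
        "\t\t" + "\t".join(
            f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(L)
        ),
        "",
    ]
    flat = (series.positions * scale).reshape(T, 3 * L)
    for i in range(T):
        coords = "\t".join(g % v for v in flat[i])
        lines.append(f"{i + 1}\t{g % series.time[i]}\t{coords}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# force-plate CSV
# ---------------------------------------------------------------------------

def read_plates(path) -> tuple[PlateSeries, PlateSeries]:
    """Read the two-plate CSV record.

    Returns ``(plate1, plate2)`` each sorted by time; a plate with no rows
    becomes a zero-wrench series on the other plate's time base (an absent
    plate is an unloaded plate).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: plate CSV lacks columns {missing}")
    ids = set(df["plate"].unique().tolist())
    if not ids:
        raise FormatError(f"{path}: plate CSV has no rows")
    if not ids <= {1, 2}:
        raise FormatError(f"{path}: plate id(s) {sorted(ids - {1, 2})} outside {{1, 2}}")

    def build(sub: pd.DataFrame) -> PlateSeries:
        sub = sub.sort_values("time")
        t = sub["time"].to_numpy(dtype=float)
        dt = np.diff(t)
        rate = 1.0 / np.median(dt) if dt.size else 0.0
        return PlateSeries(
            time=t,
            force=sub[["fx", "fy", "fz"]].to_numpy(dtype=float),
            cop=sub[["copx", "copy", "copz"]].to_numpy(dtype=float),
            free_moment_z=sub["mz"].to_numpy(dtype=float),
            rate=rate,
        )

    series = {pid: build(df[df["plate"] == pid]) for pid in sorted(ids)}
    if 1 not in series:
        series[1] = PlateSeries.zeros(series[2].time, series[2].rate)
    if 2 not in series:
        series[2] = PlateSeries.zeros(series[1].time, series[1].rate)
    return series[1], series[2]


def write_plates(plate1: PlateSeries, plate2: PlateSeries, path) -> None:
    frames = []
    for pid, p in ((1, plate1), (2, plate2)):
        frames.append(pd.DataFrame({
            "time": p.time, "plate": pid,
            "fx": p.force[:, 0], "fy": p.force[:, 1], "fz": p.force[:, 2],
            "copx": p.cop[:, 0], "copy": p.cop[:, 1], "copz": p.cop[:, 2],
            "mz": p.free_moment_z,
        }))
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def write_run_log(entries: dict, path) -> None:
    """JSON log of every effective parameter of a run."""
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
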