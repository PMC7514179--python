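"""Trial containers and file I/O.

A trial is one continuous recording of full-body marker kinematics
(``MarkerFrameSeries``): an array of lab-frame coordinates in meters,
shape ``(n_frames, n_markers * 3)`` with marker-major column order
``[m0_X, m0_Y, m0_Z, m1_X, ...]``, plus the metadata needed downstream
(subject, age group, dual-task condition, body height, which foot is in
front, sampling rate).  Missing marker-frames are encoded as NaN.

Axis convention (configurable upstream of mirroring): X = mediolateral,
Y = anteroposterior, Z = vertical.

On disk a trial is a wide CSV (``time`` column plus ``<MARKER>_X/_Y/_Z``
columns; missing samples are empty cells) with a JSON sidecar holding
the metadata.  C3D files are read through :mod:`ezc3d` when it is
installed (``pip install pmsway[c3d]``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

AXES = ("X", "Y", "Z")
#: index of the mediolateral axis within each marker's (X, Y, Z) triplet
ML_AXIS = 0

GROUPS = ("young", "old")
CONDITIONS = ("ST", "DT1", "DT2", "DT3", "DT4")


@dataclass
class TrialMeta:
    """Per-trial metadata carried through the whole pipeline."""

    subject_id: str
    group: str
    condition: str
    height_m: float
    front_foot: str = "right"

    def __post_init__(self) -> None:
        if self.height_m <= 0:
            raise ValueError(f"height must be positive, got {self.height_m}")
        if self.front_foot not in ("left", "right"):
            raise ValueError(f"front_foot must be 'left' or 'right', got {self.front_foot!r}")


@dataclass
class MarkerFrameSeries:
    """One trial's marker coordinates over time.

    ``coords`` is ``(n_frames, n_markers * 3)`` in meters; NaN marks a
    missing sample.  ``marker_labels`` orders the column triplets.
    """

    marker_labels: list[str]
    coords: np.ndarray
    rate_hz: float
    meta: TrialMeta

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 * len(self.marker_labels):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{len(self.marker_labels)} markers"
            )
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_markers(self) -> int:
        return len(self.marker_labels)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.rate_hz

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_frames, n_markers)``, True where a marker-frame is missing."""
        return np.isnan(self.coords).reshape(self.n_frames, self.n_markers, 3).any(axis=2)

    def marker_columns(self, label: str) -> slice:
        """Column slice of one marker's X/Y/Z triplet."""
        i = self.marker_labels.index(label)
        return slice(3 * i, 3 * i + 3)

    def copy_with(self, **changes) -> "MarkerFrameSeries":
        out = replace(self, **changes)
        if "coords" not in changes:
            out.coords = self.coords.copy()
        return out

    def column_labels(self) -> list[str]:
        return [f"{m}_{a}" for m in self.marker_labels for a in AXES]


@dataclass
class MarkerConfig:
    """Marker keep-list and relative segment-mass weights (loaded from YAML)."""

    symmetric_keep: list[str]
    relative_segment_mass: dict[str, float]
    full_marker_set: list[str] = field(default_factory=list)

    def normalized_weights(self, labels: list[str]) -> np.ndarray:
        """Weights for ``labels``, renormalized to sum to 1."""
        try:
            w = np.array([self.relative_segment_mass[m] for m in labels], float)
        except KeyError as exc:
            raise KeyError(f"no segment-mass weight for marker {exc.args[0]!r}") from None
        if np.any(w <= 0):
            raise ValueError("segment-mass weights must be positive")
        return w / w.sum()


def default_marker_config() -> MarkerConfig:
    path = Path(__file__).parent / "data" / "plugin_gait.yaml"
    return load_marker_config(path)


def load_marker_config(path: str | Path) -> MarkerConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return MarkerConfig(
        symmetric_keep=list(raw["symmetric_keep"]),
        relative_segment_mass={k: float(v) for k, v in raw["relative_segment_mass"].items()},
        full_marker_set=list(raw.get("full_marker_set", [])),
    )


# ---------------------------------------------------------------------------
# CSV + JSON sidecar


def write_trial_csv(trial: MarkerFrameSeries, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write a trial as wide CSV (missing = empty cell) plus JSON sidecar."""
    path = Path(path)
    t = np.arange(trial.n_frames) / trial.rate_hz
    df = pd.DataFrame(trial.coords, columns=trial.column_labels())
    df.insert(0, "time", t)
    # default float formatting = shortest round-trip repr -> bit-exact reload
    df.to_csv(path, index=False)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    meta = {
        "subject_id": trial.meta.subject_id,
        "group": trial.meta.group,
        "condition": trial.meta.condition,
        "height_m": trial.meta.height_m,
        "front_foot": trial.meta.front_foot,
        "rate_hz": trial.rate_hz,
    }
    sidecar.write_text(json.dumps(meta, indent=2))


def read_trial(path: str | Path, sidecar: str | Path | None = None) -> MarkerFrameSeries:
    """Read a trial from wide CSV (or C3D) with a JSON metadata sidecar.

    CSV columns: ``time`` plus ``<MARKER>_X/_Y/_Z``; empty cells become
    missing (NaN) marker-frames.  C3D coordinates are converted from the
    file's unit (commonly mm) to meters.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    raw = json.loads(sidecar.read_text())
    missing = {k for k in ("subject_id", "group", "condition", "height_m", "rate_hz") if k not in raw}
    if missing:
        raise ValueError(f"sidecar {sidecar} missing required fields: {sorted(missing)}")
    meta = TrialMeta(
        subject_id=str(raw["subject_id"]),
        group=raw["group"],
        condition=raw["condition"],
        height_m=float(raw["height_m"]),
        front_foot=raw.get("front_foot", "right"),
    )
    rate = float(raw["rate_hz"])

    if path.suffix.lower() == ".c3d":
        coords, labels = _read_c3d(path)
        return MarkerFrameSeries(labels, coords, rate, meta)
    if path.suffix.lower() != ".csv":
        raise ValueError(f"unknown trial format {path.suffix!r} (expected .csv or .c3d)")

    df = pd.read_csv(path)
    cols = [c for c in df.columns if c != "time"]
    labels: list[str] = []
    for c in cols:
        if "_" not in c or c.rsplit("_", 1)[1] not in AXES:
            raise ValueError(f"unexpected column {c!r}; expected <MARKER>_X/_Y/_Z")
        m = c.rsplit("_", 1)[0]
        if m not in labels:
            labels.append(m)
    expected = [f"{m}_{a}" for m in labels for a in AXES]
    if cols != expected:
        raise ValueError("marker columns are not contiguous X/Y/Z triplets")
    return MarkerFrameSeries(labels, df[expected].to_numpy(float), rate, meta)


def _read_c3d(path: Path) -> tuple[np.ndarray, list[str]]:
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading C3D files requires the optional 'ezc3d' dependency "
            "(pip install pmsway[c3d]); alternatively export trials as wide CSV"
        ) from exc
    c3d = ezc3d.c3d(str(path))
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames)
    labels = list(c3d["parameters"]["POINT"]["LABELS"]["value"])
    unit = c3d["parameters"]["POINT"].get("UNITS", {}).get("value", ["mm"])[0]
    scale = 1e-3 if str(unit).lower().startswith("mm") else 1.0
    xyz = np.transpose(pts[:3], (2, 1, 0)) * scale  # (frames, markers, 3)
    return xyz.reshape(xyz.shape[0], -1), labels
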