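"""Data model, file I/O, geometry conversion, and preprocessing.

Coordinate conventions
----------------------
Pixel coordinates have their origin at the screen top-left, x rightward,
y downward.  Degree coordinates are visual angles about the screen centre,
computed per-axis with the flat-screen tangent approximation
``deg = atan(offset_mm / viewing_distance_mm)``; x rightward, y downward.
Timestamps are milliseconds since recording start; velocities are deg/s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScreenGeometry",
    "GazeSample",
    "GazeRecording",
    "EventSegment",
    "read_gaze_csv",
    "write_gaze_csv",
    "remove_binocular_dropouts",
    "to_degrees",
    "to_pixels",
    "sample_velocity",
    "sample_velocities",
    "segments_from_labels",
    "labels_from_segments",
    "segments_to_frame",
    "write_events_csv",
    "read_events_csv",
]

UNIT_PIXELS = "pixels"
UNIT_DEGREES = "degrees"

#: classical + behavioural event labels used throughout the package
EVENT_LABELS = ("fixation", "saccade", "smooth_pursuit", "stare", "move", "noise")


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical screen and viewing geometry for pixel<->degree conversion.

    All lengths are millimetres.  The conversion is invertible on the screen
    rectangle because the per-axis tangent map is strictly monotone.
    """

    width_px: int
    height_px: int
    physical_width_mm: float
    physical_height_mm: float
    viewing_distance_mm: float

    def __post_init__(self) -> None:
        for name in (
            "width_px",
            "height_px",
            "physical_width_mm",
            "physical_height_mm",
            "viewing_distance_mm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"ScreenGeometry.{name} must be strictly positive")

    @property
    def mm_per_px_x(self) -> float:
        return self.physical_width_mm / self.width_px

    @property
    def mm_per_px_y(self) -> float:
        return self.physical_height_mm / self.height_px

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenGeometry":
        """Load geometry from a YAML file with keys width_px, height_px,
        physical_width_mm, physical_height_mm, viewing_distance_mm."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        required = {
            "width_px",
            "height_px",
            "physical_width_mm",
            "physical_height_mm",
            "viewing_distance_mm",
        }
        missing = required - set(data)
        if missing:
            raise ValueError(f"geometry file {path} missing keys: {sorted(missing)}")
        return cls(**{k: data[k] for k in required})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "width_px": self.width_px,
                    "height_px": self.height_px,
                    "physical_width_mm": self.physical_width_mm,
                    "physical_height_mm": self.physical_height_mm,
                    "viewing_distance_mm": self.viewing_distance_mm,
                },
                fh,
            )


@dataclass(frozen=True)
class GazeSample:
    """One gaze sample: time (ms), position, and per-eye validity flags."""

    t: float
    x: float
    y: float
    left_valid: bool = True
    right_valid: bool = True


@dataclass
class GazeRecording:
    """A time-ordered gaze recording stored as column arrays.

    ``unit`` flags whether x/y are screen pixels or visual-angle degrees.
    Timestamps must be strictly increasing.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    left_valid: np.ndarray | None = None
    right_valid: np.ndarray | None = None
    geometry: ScreenGeometry | None = None
    unit: str = UNIT_DEGREES
    nominal_rate: float = 40.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.t)
        if len(self.x) != n or len(self.y) != n:
            raise ValueError("t, x, y must have equal length")
        if self.left_valid is None:
            self.left_valid = np.ones(n, dtype=bool)
        if self.right_valid is None:
            self.right_valid = np.ones(n, dtype=bool)
        self.left_valid = np.asarray(self.left_valid, dtype=bool)
        self.right_valid = np.asarray(self.right_valid, dtype=bool)
        if not np.all(np.isfinite(self.t)) or np.any(self.t < 0):
            raise ValueError("timestamps must be finite and non-negative")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            bad = int(np.argmin(np.diff(self.t) > 0))
            raise ValueError(
                f"timestamps must be strictly increasing (violated at sample {bad + 1})"
            )
        if self.unit not in (UNIT_PIXELS, UNIT_DEGREES):
            raise ValueError(f"unknown unit {self.unit!r}")
        if not self.nominal_rate > 0:
            raise ValueError("nominal_rate must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_ms(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def sample(self, i: int) -> GazeSample:
        return GazeSample(
            float(self.t[i]),
            float(self.x[i]),
            float(self.y[i]),
            bool(self.left_valid[i]),
            bool(self.right_valid[i]),
        )

    def copy(self) -> "GazeRecording":
        return GazeRecording(
            self.t.copy(),
            self.x.copy(),
            self.y.copy(),
            self.left_valid.copy(),
            self.right_valid.copy(),
            self.geometry,
            self.unit,
            self.nominal_rate,
        )


@dataclass
class EventSegment:
    """A labelled contiguous span of samples (inclusive indices).

    The centroid is the mean position of the member samples (degrees when
    the recording is in degrees) and duration is ``t[end] - t[start]`` ms.
    """

    label: str
    start_index: int
    end_index: int
    centroid: tuple[float, float]
    duration: float

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("start_index must be <= end_index")
        if self.label not in EVENT_LABELS:
            raise ValueError(f"unknown event label {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index + 1

    @classmethod
    def from_span(
        cls, rec: GazeRecording, label: str, start: int, end: int
    ) -> "EventSegment":
        xs = rec.x[start : end + 1]
        ys = rec.y[start : end + 1]
        return cls(
            label=label,
            start_index=int(start),
            end_index=int(end),
            centroid=(float(np.mean(xs)), float(np.mean(ys))),
            duration=float(rec.t[end] - rec.t[start]),
        )


# ---------------------------------------------------------------------------
# CSV I/O.  Header: t,x,y[,valid_l,valid_r]; t in ms; UTF-8.
# ---------------------------------------------------------------------------


def read_gaze_csv(
    path: str | Path,
    geometry: ScreenGeometry | None = None,
    unit: str = UNIT_DEGREES,
    nominal_rate: float = 40.0,
) -> GazeRecording:
    """Read a gaze CSV (columns ``t,x,y`` and optional ``valid_l,valid_r``).

    Missing validity columns default to valid.  Malformed rows raise a parse
    error naming the offending line; non-increasing timestamps raise a
    validation error.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - passthrough text
        raise ValueError(f"malformed gaze CSV {path}: {exc}") from exc
    for col in ("t", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"gaze CSV {path} missing required column {col!r}")
    for col in ("t", "x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(vals.to_numpy(dtype=float)))[0]
        if bad.size:
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"malformed value in column {col!r} of {path} at line {bad[0] + 2}"
            )
        df[col] = vals
    left = df["valid_l"].astype(bool).to_numpy() if "valid_l" in df else None
    right = df["valid_r"].astype(bool).to_numpy() if "valid_r" in df else None
    return GazeRecording(
        t=df["t"].to_numpy(),
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        left_valid=left,
        right_valid=right,
        geometry=geometry,
        unit=unit,
        nominal_rate=nominal_rate,
    )


def write_gaze_csv(rec: GazeRecording, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "t": rec.t,
            "x": rec.x,
            "y": rec.y,
            "valid_l": rec.left_valid.astype(int),
            "valid_r": rec.right_valid.astype(int),
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def remove_binocular_dropouts(
    rec: GazeRecording,
) -> tuple[GazeRecording, np.ndarray]:
    """Drop samples not detected in either eye (blink/dropout noise).

    Only samples with *both* eyes invalid are removed; one-eye samples are
    retained.  Returns the filtered recording and a boolean mask over the
    original samples, True where a sample was removed.  Ordering of the
    surviving samples is preserved.
    """
    removed = (~rec.left_valid) & (~rec.right_valid)
    keep = ~removed
    out = GazeRecording(
        t=rec.t[keep],
        x=rec.x[keep],
        y=rec.y[keep],
        left_valid=rec.left_valid[keep],
        right_valid=rec.right_valid[keep],
        geometry=rec.geometry,
        unit=rec.unit,
        nominal_rate=rec.nominal_rate,
    )
    return out, removed


# ---------------------------------------------------------------------------
# Geometry conversion
# ---------------------------------------------------------------------------


def _require_geometry(rec: GazeRecording) -> ScreenGeometry:
    if rec.geometry is None:
        raise ValueError("recording has no ScreenGeometry attached")
    return rec.geometry


def to_degrees(rec: GazeRecording) -> GazeRecording:
    """Convert pixel positions to visual angle (degrees) about screen centre."""
    if rec.unit == UNIT_DEGREES:
        warnings.warn("recording already in degrees; to_degrees is a no-op")
        return rec.copy()
    g = _require_geometry(rec)
    cx = g.width_px / 2.0
    cy = g.height_px / 2.0
    x_deg = np.degrees(np.arctan((rec.x - cx) * g.mm_per_px_x / g.viewing_distance_mm))
    y_deg = np.degrees(np.arctan((rec.y - cy) * g.mm_per_px_y / g.viewing_distance_mm))
    out = rec.copy()
    out.x = x_deg
    out.y = y_deg
    out.unit = UNIT_DEGREES
    return out


def to_pixels(rec: GazeRecording) -> GazeRecording:
    """Inverse of :func:`to_degrees`."""
    if rec.unit == UNIT_PIXELS:
        warnings.warn("recording already in pixels; to_pixels is a no-op")
        return rec.copy()
    g = _require_geometry(rec)
    cx = g.width_px / 2.0
    cy = g.height_px / 2.0
    x_px = cx + np.tan(np.radians(rec.x)) * g.viewing_distance_mm / g.mm_per_px_x
    y_px = cy + np.tan(np.radians(rec.y)) * g.viewing_distance_mm / g.mm_per_px_y
    out = rec.copy()
    out.x = x_px
    out.y = y_px
    out.unit = UNIT_PIXELS
    return out


# ---------------------------------------------------------------------------
# Velocity
# ---------------------------------------------------------------------------


def sample_velocities(rec: GazeRecording) -> np.ndarray:
    """Point-to-point angular velocity (deg/s), backward difference.

    The first sample's velocity is defined as 0.
    """
    if rec.unit != UNIT_DEGREES:
        raise ValueError("velocity requires a recording in degrees")
    if len(rec) < 2:
        raise ValueError("velocity needs at least 2 samples")
    dt = np.diff(rec.t) / 1000.0  # s
    disp = np.hypot(np.diff(rec.x), np.diff(rec.y))
    v = np.zeros(len(rec))
    v[1:] = disp / dt
    return v


def sample_velocity(rec: GazeRecording, i: int) -> float:
    """Velocity of sample ``i`` (deg/s) from the backward difference i-1 -> i."""
    if not 1 <= i < len(rec):
        raise IndexError("sample_velocity requires 1 <= i < n")
    if rec.unit != UNIT_DEGREES:
        raise ValueError("velocity requires a recording in degrees")
    dt = (rec.t[i] - rec.t[i - 1]) / 1000.0
    if dt == 0:
        raise ValueError("zero time step")
    return float(np.hypot(rec.x[i] - rec.x[i - 1], rec.y[i] - rec.y[i - 1]) / dt)


# ---------------------------------------------------------------------------
# Label <-> segment conversion
# ---------------------------------------------------------------------------


def segments_from_labels(
    rec: GazeRecording, labels: Sequence[str]
) -> list[EventSegment]:
    """Collapse per-sample labels into maximal-run segments."""
    labels = list(labels)
    if len(labels) != len(rec):
        raise ValueError("labels must cover every sample")
    segments: list[EventSegment] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segments.append(EventSegment.from_span(rec, labels[start], start, i - 1))
            start = i
    return segments


def labels_from_segments(segments: Iterable[EventSegment], n: int) -> np.ndarray:
    """Expand segments back to per-sample labels (object array of str)."""
    out = np.empty(n, dtype=object)
    for seg in segments:
        out[seg.start_index : seg.end_index + 1] = seg.label
    if any(v is None for v in out):
        raise ValueError("segments do not cover all samples")
    return out


def segments_to_frame(segments: Sequence[EventSegment], rec: GazeRecording) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [s.label for s in segments],
            "start_index": [s.start_index for s in segments],
            "end_index": [s.end_index for s in segments],
            "start_ms": [float(rec.t[s.start_index]) for s in segments],
            "end_ms": [float(rec.t[s.end_index]) for s in segments],
            "centroid_x_deg": [s.centroid[0] for s in segments],
            "centroid_y_deg": [s.centroid[1] for s in segments],
            "duration_ms": [s.duration for s in segments],
        }
    )


def write_events_csv(
    segments: Sequence[EventSegment], rec: GazeRecording, path: str | Path
) -> None:
    segments_to_frame(segments, rec).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[EventSegment]:
    df = pd.read_csv(path)
    return [
        EventSegment(
            label=row["label"],
            start_index=int(row["start_index"]),
            end_index=int(row["end_index"]),
            centroid=(float(row["centroid_x_deg"]), float(row["centroid_y_deg"])),
            duration=float(row["duration_ms"]),
        )
        for _, row in df.iterrows()
    ]
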