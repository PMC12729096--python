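"""Gaze-sample streams and delimited-text I/O.

A :class:`GazeStream` holds a time-ordered 30 Hz (by default) recording as
column arrays: timestamps in milliseconds since scenario onset, per-eye
validity flags, the merged gaze position in screen centimeters, per-eye pupil
diameters in millimeters, and the eye-to-screen distance in centimeters.
Samples where both eyes are invalid carry NaN position and pupil values.

Files are UTF-8 delimited text (tab or comma, auto-detected) with one header
row.  The canonical column names are::

    t_ms, left_valid, right_valid, x_cm, y_cm,
    pupil_left_mm, pupil_right_mm, eye_distance_cm

Pixel exports with ``x_px, y_px`` instead of ``x_cm, y_cm`` are converted at
read time when the geometry carries ``resolution_px``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry

__all__ = ["GazeStream", "read_gaze_samples", "write_gaze_samples"]

_COLUMNS = ["t_ms", "left_valid", "right_valid", "x_cm", "y_cm",
            "pupil_left_mm", "pupil_right_mm", "eye_distance_cm"]
_MANDATORY = ["t_ms", "left_valid", "right_valid"]


class GazeFormatError(ValueError):
    """Raised when a gaze file violates the documented dialect."""


class GazeDataError(ValueError):
    """Raised when parsed gaze data violate stream invariants."""


@dataclass
class GazeStream:
    """Time-ordered gaze samples with recording geometry and session labels."""

    t_ms: np.ndarray
    left_valid: np.ndarray
    right_valid: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    pupil_left_mm: np.ndarray
    pupil_right_mm: np.ndarray
    eye_distance_cm: np.ndarray | None = None
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    participant_id: str = ""
    condition_id: str = ""

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.left_valid = np.asarray(self.left_valid, dtype=bool)
        self.right_valid = np.asarray(self.right_valid, dtype=bool)
        for name in ("x_cm", "y_cm", "pupil_left_mm", "pupil_right_mm"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.eye_distance_cm is not None:
            self.eye_distance_cm = np.asarray(self.eye_distance_cm, dtype=float)
        n = self.t_ms.size
        for name in ("left_valid", "right_valid", "x_cm", "y_cm",
                     "pupil_left_mm", "pupil_right_mm"):
            if getattr(self, name).size != n:
                raise GazeDataError(f"column {name} length mismatch")
        if n > 1:
            dt = np.diff(self.t_ms)
            bad = np.nonzero(dt <= 0)[0]
            if bad.size:
                raise GazeDataError(
                    f"timestamps not strictly increasing at row {bad[0] + 1} "
                    f"(t={self.t_ms[bad[0] + 1]:.3f} after {self.t_ms[bad[0]]:.3f})")
            nominal = self.geometry.sample_period_ms
            med = float(np.median(dt))
            if abs(med - nominal) > 0.1 * nominal:
                raise GazeDataError(
                    f"median inter-sample interval {med:.2f} ms deviates >10% "
                    f"from nominal {nominal:.2f} ms")
        # both-eye-invalid samples must not carry position or pupil data
        blind = ~self.left_valid & ~self.right_valid
        for name in ("x_cm", "y_cm", "pupil_left_mm", "pupil_right_mm"):
            arr = getattr(self, name)
            arr[blind] = np.nan
        self.pupil_left_mm[~self.left_valid] = np.nan
        self.pupil_right_mm[~self.right_valid] = np.nan

    # -- derived views ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(self.t_ms.size)

    @property
    def any_valid(self) -> np.ndarray:
        """Samples where at least one eye is tracked (position available)."""
        return self.left_valid | self.right_valid

    @property
    def both_invalid(self) -> np.ndarray:
        return ~self.any_valid

    @property
    def sample_period_ms(self) -> float:
        return self.geometry.sample_period_ms

    @property
    def duration_ms(self) -> float:
        """Recording span counted as n_samples x sample period."""
        return self.n_samples * self.sample_period_ms

    def to_frame(self) -> pd.DataFrame:
        data = {
            "t_ms": self.t_ms,
            "left_valid": self.left_valid.astype(int),
            "right_valid": self.right_valid.astype(int),
            "x_cm": self.x_cm,
            "y_cm": self.y_cm,
            "pupil_left_mm": self.pupil_left_mm,
            "pupil_right_mm": self.pupil_right_mm,
        }
        if self.eye_distance_cm is not None:
            data["eye_distance_cm"] = self.eye_distance_cm
        return pd.DataFrame(data)

    def slice(self, t0_ms: float, t1_ms: float) -> "GazeStream":
        """Sub-stream with t0_ms <= t < t1_ms (labels and geometry kept)."""
        m = (self.t_ms >= t0_ms) & (self.t_ms < t1_ms)
        kw = {name: getattr(self, name)[m]
              for name in ("t_ms", "left_valid", "right_valid", "x_cm", "y_cm",
                           "pupil_left_mm", "pupil_right_mm")}
        kw["eye_distance_cm"] = (None if self.eye_distance_cm is None
                                 else self.eye_distance_cm[m])
        return replace(self, **kw)


def _detect_delimiter(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_gaze_samples(path, geometry: ScreenGeometry,
                      participant_id: str = "", condition_id: str = "") -> GazeStream:
    """Read a delimited gaze-sample file into a :class:`GazeStream`.

    Rows whose timestamp does not parse as a number are dropped; validity
    flags accept 0/1, true/false (any case).  Missing mandatory columns raise
    :class:`GazeFormatError`; non-monotone timestamps raise
    :class:`GazeDataError` naming the first offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_detect_delimiter(path), encoding="utf-8")
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise GazeFormatError(f"missing mandatory columns: {missing}")
    has_cm = "x_cm" in df.columns and "y_cm" in df.columns
    has_px = "x_px" in df.columns and "y_px" in df.columns
    if not has_cm and not has_px:
        raise GazeFormatError("missing position columns (x_cm/y_cm or x_px/y_px)")

    t = pd.to_numeric(df["t_ms"], errors="coerce")
    df = df[t.notna()].copy()
    df["t_ms"] = t[t.notna()].astype(float)

    def as_bool(col):
        s = df[col]
        if s.dtype == object:
            return s.astype(str).str.strip().str.lower().isin(
                {"1", "true", "t", "yes"}).to_numpy()
        return s.fillna(0).astype(float).to_numpy() != 0

    if has_cm:
        x = pd.to_numeric(df["x_cm"], errors="coerce").to_numpy()
        y = pd.to_numeric(df["y_cm"], errors="coerce").to_numpy()
    else:
        x, y = geometry.px_to_cm(
            pd.to_numeric(df["x_px"], errors="coerce").to_numpy(),
            pd.to_numeric(df["y_px"], errors="coerce").to_numpy())

    def numeric(col):
        if col not in df.columns:
            return np.full(len(df), np.nan)
        return pd.to_numeric(df[col], errors="coerce").to_numpy()

    dist = numeric("eye_distance_cm")
    return GazeStream(
        t_ms=df["t_ms"].to_numpy(),
        left_valid=as_bool("left_valid"),
        right_valid=as_bool("right_valid"),
        x_cm=x, y_cm=y,
        pupil_left_mm=numeric("pupil_left_mm"),
        pupil_right_mm=numeric("pupil_right_mm"),
        eye_distance_cm=None if np.all(np.isnan(dist)) else dist,
        geometry=geometry,
        participant_id=participant_id,
        condition_id=condition_id,
    )


def write_gaze_samples(stream: GazeStream, path, delimiter: str = "\t") -> None:
    """Write a stream back to delimited text (lossless round-trip)."""
    stream.to_frame().to_csv(Path(path), sep=delimiter, index=False)
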