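"""Ocular event detection: blinks, track loss, fixations, pupil summaries.

Blinks are maximal runs of samples with *both* eyes untracked whose duration
(run length x sample period) falls inside a closed band, 100-600 ms by
default; longer runs are reported as track-loss segments and shorter runs are
ignored as single-sample dropouts.

Fixations follow the dispersion-threshold (I-DT) scheme: a window of
consecutive position-carrying samples grows while the maximum pairwise
Euclidean distance between member samples stays within the screen-cm
equivalent of a visual-angle bound (1 degree by default); when growth stops,
the window is emitted as a fixation if it lasted at least the minimum
duration (100 ms).  Any untracked sample terminates the current window — no
interpolation across dropouts is attempted, since at 30 Hz a single
interpolated sample would fabricate 33 ms of data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .geometry import ScreenGeometry, visual_angle_to_cm
from .io import GazeStream

__all__ = [
    "DetectionParams", "Blink", "TrackLoss", "Fixation",
    "detect_gaps", "detect_blinks", "detect_fixations",
    "pupil_mean", "blink_stats",
]


@dataclass(frozen=True)
class DetectionParams:
    """Event-detection thresholds.

    ``dispersion_metric`` selects how window dispersion is measured:
    ``"max_pairwise"`` (default; the window fits in a disc of the threshold
    diameter) or ``"range_sum"`` (x-range + y-range, the classic I-DT
    variant).
    """

    blink_min_ms: float = 100.0
    blink_max_ms: float = 600.0
    fixation_dispersion_deg: float = 1.0
    fixation_min_ms: float = 100.0
    dispersion_metric: str = "max_pairwise"

    def __post_init__(self) -> None:
        if not 0 < self.blink_min_ms < self.blink_max_ms:
            raise ValueError("need 0 < blink_min_ms < blink_max_ms")
        if self.fixation_dispersion_deg <= 0 or self.fixation_min_ms <= 0:
            raise ValueError("fixation thresholds must be > 0")
        if self.dispersion_metric not in ("max_pairwise", "range_sum"):
            raise ValueError(f"unknown dispersion_metric {self.dispersion_metric!r}")


@dataclass(frozen=True)
class Blink:
    start_ms: float
    end_ms: float

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class TrackLoss:
    """Both-eye data loss too long to be an eyelid closure."""

    start_ms: float
    end_ms: float

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class Fixation:
    start_ms: float
    end_ms: float
    centroid_x_cm: float
    centroid_y_cm: float
    n_samples: int

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


def detect_gaps(stream: GazeStream, params: DetectionParams | None = None
                ) -> tuple[list[Blink], list[TrackLoss]]:
    """Split both-eye-invalid runs into blinks (in-band) and track loss.

    Run duration = run length x sample period; both band edges inclusive.
    Runs below the lower edge are ignored.
    """
    params = params or DetectionParams()
    invalid = stream.both_invalid
    period = stream.sample_period_ms
    blinks: list[Blink] = []
    losses: list[TrackLoss] = []
    if invalid.size == 0:
        return blinks, losses
    padded = np.concatenate(([False], invalid, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for i0, i1 in zip(edges[::2], edges[1::2]):  # [i0, i1) invalid run
        dur = (i1 - i0) * period
        start = stream.t_ms[i0]
        # tolerate float representation of the band edges at one part in 1e9
        if params.blink_min_ms - 1e-6 <= dur <= params.blink_max_ms + 1e-6:
            blinks.append(Blink(start, start + dur))
        elif dur > params.blink_max_ms:
            losses.append(TrackLoss(start, start + dur))
    return blinks, losses


def detect_blinks(stream: GazeStream, params: DetectionParams | None = None
                  ) -> list[Blink]:
    """Blinks only; see :func:`detect_gaps` for the track-loss remainder."""
    return detect_gaps(stream, params)[0]


@njit(cache=True)
def _idt_core(x, y, valid, period_ms, thr_cm, min_ms, range_sum):  # pragma: no cover
    n = x.size
    min_len = int(np.ceil(min_ms / period_ms - 1e-9))
    out = np.empty((n, 2), dtype=np.int64)
    k = 0
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        if range_sum:
            xmin = xmax = x[i]
            ymin = ymax = y[i]
            while j + 1 < n and valid[j + 1]:
                nxmin = min(xmin, x[j + 1]); nxmax = max(xmax, x[j + 1])
                nymin = min(ymin, y[j + 1]); nymax = max(ymax, y[j + 1])
                if (nxmax - nxmin) + (nymax - nymin) > thr_cm:
                    break
                xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
                j += 1
        else:
            while j + 1 < n and valid[j + 1]:
                ok = True
                for m in range(i, j + 1):
                    dx = x[j + 1] - x[m]
                    dy = y[j + 1] - y[m]
                    if dx * dx + dy * dy > thr_cm * thr_cm:
                        ok = False
                        break
                if not ok:
                    break
                j += 1
        if j - i + 1 >= min_len:
            out[k, 0] = i
            out[k, 1] = j
            k += 1
            i = j + 1
        else:
            i += 1
    return out[:k]


def detect_fixations(stream: GazeStream, params: DetectionParams | None = None,
                     geometry: ScreenGeometry | None = None) -> list[Fixation]:
    """Dispersion-threshold fixation detection on the merged gaze position.

    The angular dispersion bound is converted to screen centimeters at the
    geometry's viewing distance.  Fixation duration is counted as
    n_samples x sample period, matching the blink convention.
    """
    params = params or DetectionParams()
    geometry = geometry or stream.geometry
    thr_cm = visual_angle_to_cm(params.fixation_dispersion_deg,
                                geometry.viewing_distance_cm)
    valid = stream.any_valid & np.isfinite(stream.x_cm) & np.isfinite(stream.y_cm)
    x = np.where(valid, stream.x_cm, 0.0)
    y = np.where(valid, stream.y_cm, 0.0)
    spans = _idt_core(x, y, valid, stream.sample_period_ms, thr_cm,
                      params.fixation_min_ms,
                      params.dispersion_metric == "range_sum")
    period = stream.sample_period_ms
    fixations = []
    for i, j in spans:
        sl = slice(i, j + 1)
        fixations.append(Fixation(
            start_ms=float(stream.t_ms[i]),
            end_ms=float(stream.t_ms[i] + (j - i + 1) * period),
            centroid_x_cm=float(np.mean(stream.x_cm[sl])),
            centroid_y_cm=float(np.mean(stream.y_cm[sl])),
            n_samples=int(j - i + 1),
        ))
    return fixations


def pupil_mean(stream: GazeStream) -> float:
    """Mean pupil diameter (mm) over samples with at least one tracked eye.

    Per sample the available eyes are averaged (one eye suffices).  Returns
    NaN, with a warning, when no sample carries a pupil reading.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_sample = np.nanmean(
            np.column_stack([stream.pupil_left_mm, stream.pupil_right_mm]), axis=1)
    if np.all(np.isnan(per_sample)):
        warnings.warn("no valid pupil samples; mean undefined", stacklevel=2)
        return float("nan")
    return float(np.nanmean(per_sample))


def blink_stats(blinks: list[Blink]) -> tuple[int, float]:
    """(count, mean duration ms); the mean is NaN when there are no blinks."""
    if not blinks:
        return 0, float("nan")
    durations = [b.duration_ms for b in blinks]
    return len(blinks), float(np.mean(durations))
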