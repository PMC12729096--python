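"""Screen geometry and visual-angle conversions.

All on-screen quantities in this package are expressed in centimeters with the
origin at the top-left corner of the display, x increasing rightward and y
increasing downward.  Visual angles are the full angle subtended at the eye by
an extent centered on the line of sight:

    theta = 2 * atan(extent / (2 * distance))
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScreenGeometry",
    "cm_to_visual_angle",
    "visual_angle_to_cm",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display and recording geometry.

    Defaults describe a 61 x 34 cm radar display viewed from 60 cm with a
    30 Hz remote eye tracker.
    """

    display_width_cm: float = 61.0
    display_height_cm: float = 34.0
    viewing_distance_cm: float = 60.0
    sampling_rate_hz: float = 30.0
    resolution_px: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for name in ("display_width_cm", "display_height_cm",
                     "viewing_distance_cm", "sampling_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 30.0 <= self.viewing_distance_cm <= 120.0:
            warnings.warn(
                f"viewing_distance_cm={self.viewing_distance_cm} is outside the "
                "plausible 30-120 cm band for a remote desktop tracker",
                stacklevel=2,
            )
        if self.resolution_px is not None:
            w, h = self.resolution_px
            if w <= 0 or h <= 0:
                raise ValueError("resolution_px entries must be positive")

    @property
    def sample_period_ms(self) -> float:
        """Nominal inter-sample interval in milliseconds."""
        return 1000.0 / self.sampling_rate_hz

    def px_to_cm(self, x_px, y_px):
        """Convert pixel coordinates to screen centimeters (requires resolution_px)."""
        if self.resolution_px is None:
            raise ValueError("px_to_cm requires resolution_px to be set")
        rx, ry = self.resolution_px
        return (np.asarray(x_px, dtype=float) * self.display_width_cm / rx,
                np.asarray(y_px, dtype=float) * self.display_height_cm / ry)


def cm_to_visual_angle(extent_cm, distance_cm):
    """Full visual angle (degrees) subtended by ``extent_cm`` at ``distance_cm``.

    Accepts scalars or arrays; extents must be non-negative and the viewing
    distance strictly positive.
    """
    extent = np.asarray(extent_cm, dtype=float)
    distance = np.asarray(distance_cm, dtype=float)
    if np.any(distance <= 0):
        raise ValueError("distance_cm must be > 0")
    if np.any(extent < 0):
        raise ValueError("extent_cm must be >= 0")
    angle = np.degrees(2.0 * np.arctan2(extent, 2.0 * distance))
    return float(angle) if angle.ndim == 0 else angle


def visual_angle_to_cm(angle_deg, distance_cm):
    """On-screen extent (cm) subtending ``angle_deg`` at ``distance_cm``.

    Inverse of :func:`cm_to_visual_angle`; angles must lie in [0, 180).
    """
    angle = np.asarray(angle_deg, dtype=float)
    distance = np.asarray(distance_cm, dtype=float)
    if np.any(distance <= 0):
        raise ValueError("distance_cm must be > 0")
    if np.any(angle < 0) or np.any(angle >= 180.0):
        raise ValueError("angle_deg must lie in [0, 180)")
    extent = 2.0 * distance * np.tan(np.radians(angle) / 2.0)
    return float(extent) if extent.ndim == 0 else extent
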