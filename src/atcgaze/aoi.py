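"""Static and aircraft-centered (dynamic) areas of interest.

Three static AOIs partition the radar display: the central *active sector*
rectangle, the *flight-plan sheet* pinned to the top-right corner, and the
remaining *out-of-sector* airspace (the set complement, so the three regions
are pairwise disjoint and cover the display).  Rectangles are closed on the
left/top edges and open on the right/bottom, which makes boundary
classification deterministic; where the sheet brushes the sector corner the
sheet wins.

Dynamic AOIs are fixed-size rectangles that translate with each aircraft's
projected screen position, the same size for every aircraft, optionally
extended toward the data-tag box.  Fixations are assigned to the aircraft
whose AOI contains the centroid for the largest fraction of the fixation's
duration, evaluated on the sample grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import Fixation
from .geometry import ScreenGeometry
from .scenario import Scenario, Trajectory

__all__ = [
    "RectAOI", "StaticAOIs", "DynamicAOISpec", "AttentionSeries",
    "build_static_aois", "assign_fixation_static", "dynamic_aoi_at",
    "assign_fixation_dynamic", "cumulative_fixation_time",
    "sliding_window_attention", "sector_entry_time",
]

SECTOR_WIDTH_CM = 27.5
SECTOR_HEIGHT_CM = 20.5
SHEET_WIDTH_CM = 17.0
SHEET_HEIGHT_CM = 7.5


@dataclass(frozen=True)
class RectAOI:
    """Axis-aligned screen rectangle; closed left/top, open right/bottom."""

    name: str
    left_cm: float
    top_cm: float
    width_cm: float
    height_cm: float

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError(f"{self.name}: AOI sides must be > 0")

    @property
    def right_cm(self) -> float:
        return self.left_cm + self.width_cm

    @property
    def bottom_cm(self) -> float:
        return self.top_cm + self.height_cm

    @property
    def center(self) -> tuple[float, float]:
        return (self.left_cm + self.width_cm / 2, self.top_cm + self.height_cm / 2)

    def contains(self, x_cm, y_cm):
        x = np.asarray(x_cm, float)
        y = np.asarray(y_cm, float)
        inside = ((x >= self.left_cm) & (x < self.right_cm)
                  & (y >= self.top_cm) & (y < self.bottom_cm))
        return bool(inside) if inside.ndim == 0 else inside


@dataclass(frozen=True)
class StaticAOIs:
    """The three-region static partition of the display."""

    sector: RectAOI
    sheet: RectAOI
    display_width_cm: float
    display_height_cm: float

    def on_display(self, x_cm, y_cm):
        x = np.asarray(x_cm, float)
        y = np.asarray(y_cm, float)
        inside = ((x >= 0) & (x < self.display_width_cm)
                  & (y >= 0) & (y < self.display_height_cm))
        return bool(inside) if inside.ndim == 0 else inside

    def classify(self, x_cm, y_cm):
        """Label array: sheet > sector > out_of_sector; off_display outside."""
        x = np.atleast_1d(np.asarray(x_cm, float))
        y = np.atleast_1d(np.asarray(y_cm, float))
        labels = np.full(x.shape, "out_of_sector", dtype=object)
        labels[~self.on_display(x, y)] = "off_display"
        m = self.on_display(x, y) & self.sector.contains(x, y)
        labels[m] = "sector"
        m = self.on_display(x, y) & self.sheet.contains(x, y)
        labels[m] = "sheet"
        return labels

    @property
    def labels(self) -> tuple[str, str, str]:
        return ("sector", "out_of_sector", "sheet")


def build_static_aois(geometry: ScreenGeometry) -> StaticAOIs:
    """Centered sector and top-right flight-plan sheet on the display."""
    if (geometry.display_width_cm < SECTOR_WIDTH_CM
            or geometry.display_height_cm < SECTOR_HEIGHT_CM
            or geometry.display_width_cm < SHEET_WIDTH_CM
            or geometry.display_height_cm < SHEET_HEIGHT_CM):
        raise ValueError("display smaller than the static AOI layout")
    sector = RectAOI(
        "sector",
        left_cm=(geometry.display_width_cm - SECTOR_WIDTH_CM) / 2,
        top_cm=(geometry.display_height_cm - SECTOR_HEIGHT_CM) / 2,
        width_cm=SECTOR_WIDTH_CM, height_cm=SECTOR_HEIGHT_CM)
    sheet = RectAOI(
        "sheet",
        left_cm=geometry.display_width_cm - SHEET_WIDTH_CM,
        top_cm=0.0, width_cm=SHEET_WIDTH_CM, height_cm=SHEET_HEIGHT_CM)
    return StaticAOIs(sector=sector, sheet=sheet,
                      display_width_cm=geometry.display_width_cm,
                      display_height_cm=geometry.display_height_cm)


def assign_fixation_static(fix: Fixation, aois: StaticAOIs) -> str:
    """Static AOI label for a fixation's centroid."""
    return str(aois.classify(fix.centroid_x_cm, fix.centroid_y_cm)[0])


@dataclass(frozen=True)
class DynamicAOISpec:
    """Per-aircraft tracking rectangle, identical size for all aircraft."""

    width_cm: float = 3.0
    height_cm: float = 2.0
    tag_offset_cm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError("dynamic AOI sides must be > 0")


def dynamic_aoi_at(trajectory: Trajectory, t_s: float, spec: DynamicAOISpec,
                   scenario: Scenario) -> RectAOI:
    """The aircraft's AOI rectangle at time ``t_s`` (seconds).

    Centered on the projected symbol position and extended (bounding box) to
    cover the same rectangle displaced by the tag offset, so the area is
    constant over time for every aircraft.
    """
    if not 0 <= t_s <= scenario.duration_s:
        raise ValueError(f"t_s={t_s} outside scenario span [0, {scenario.duration_s}]")
    x_cm, y_cm = scenario.viewport.to_screen(*trajectory.position_at(t_s))
    ox, oy = spec.tag_offset_cm
    left = min(x_cm - spec.width_cm / 2, x_cm - spec.width_cm / 2 + ox)
    top = min(y_cm - spec.height_cm / 2, y_cm - spec.height_cm / 2 + oy)
    return RectAOI(trajectory.flight, left, top,
                   spec.width_cm + abs(ox), spec.height_cm + abs(oy))


def _aoi_contains_track(x_cm, y_cm, px, py, spec: DynamicAOISpec):
    """Vectorized containment of gaze point(s) in the moving AOI at matched times."""
    ox, oy = spec.tag_offset_cm
    left = np.minimum(px - spec.width_cm / 2, px - spec.width_cm / 2 + ox)
    top = np.minimum(py - spec.height_cm / 2, py - spec.height_cm / 2 + oy)
    w = spec.width_cm + abs(ox)
    h = spec.height_cm + abs(oy)
    return ((x_cm >= left) & (x_cm < left + w)
            & (y_cm >= top) & (y_cm < top + h))


def assign_fixation_dynamic(fix: Fixation, trajectories: dict[str, Trajectory],
                            spec: DynamicAOISpec, scenario: Scenario,
                            sampling_rate_hz: float = 30.0) -> str | None:
    """Aircraft label owning the fixation, or None.

    The winner is the aircraft whose AOI contains the fixation centroid for
    the greatest fraction of the fixation's duration (sample grid); ties go
    to the AOI center nearest the centroid at the fixation midpoint.
    """
    if not trajectories:
        return None
    t = np.arange(fix.start_ms, fix.end_ms, 1000.0 / sampling_rate_hz) / 1000.0
    if t.size == 0:
        t = np.array([fix.start_ms / 1000.0])
    t = np.clip(t, 0.0, scenario.duration_s)
    fractions = {}
    for name, traj in trajectories.items():
        px, py = scenario.viewport.to_screen(*traj.position_at(t))
        fractions[name] = float(np.mean(_aoi_contains_track(
            fix.centroid_x_cm, fix.centroid_y_cm, px, py, spec)))
    best = max(fractions.values())
    if best <= 0.0:
        return None
    tied = [n for n, f in fractions.items() if f == best]
    if len(tied) == 1:
        return tied[0]
    mid = min(max((fix.start_ms + fix.end_ms) / 2000.0, 0.0), scenario.duration_s)

    def center_dist(name):
        px, py = scenario.viewport.to_screen(*trajectories[name].position_at(mid))
        return float(np.hypot(fix.centroid_x_cm - px, fix.centroid_y_cm - py))

    return min(tied, key=center_dist)


def assign_fixations_dynamic(fixations: list[Fixation],
                             trajectories: dict[str, Trajectory],
                             spec: DynamicAOISpec, scenario: Scenario,
                             sampling_rate_hz: float = 30.0) -> list[str | None]:
    """Batch dynamic assignment; same rule as :func:`assign_fixation_dynamic`.

    Aircraft tracks are projected once on the scenario sample grid, so
    assigning thousands of fixations costs one pass per aircraft.
    """
    if not trajectories or not fixations:
        return [None] * len(fixations)
    period = 1000.0 / sampling_rate_hz
    n = int(round(scenario.duration_s * sampling_rate_hz))
    t_grid = np.arange(n) * period / 1000.0
    names = list(trajectories)
    px = np.empty((len(names), n))
    py = np.empty((len(names), n))
    for i, name in enumerate(names):
        px[i], py[i] = scenario.viewport.to_screen(
            *trajectories[name].position_at(t_grid))
    labels: list[str | None] = []
    for fix in fixations:
        i0 = min(max(int(fix.start_ms / period), 0), n - 1)
        i1 = max(min(int(np.ceil(fix.end_ms / period)), n), i0 + 1)
        best = 0.0
        best_names: list[str] = []
        for i, name in enumerate(names):
            frac = float(np.mean(_aoi_contains_track(
                fix.centroid_x_cm, fix.centroid_y_cm,
                px[i, i0:i1], py[i, i0:i1], spec)))
            if frac > best:
                best, best_names = frac, [name]
            elif frac == best and best > 0:
                best_names.append(name)
        if not best_names:
            labels.append(None)
        elif len(best_names) == 1:
            labels.append(best_names[0])
        else:
            mid = min(max((i0 + i1) // 2, 0), n - 1)
            labels.append(min(
                best_names,
                key=lambda nm: float(np.hypot(
                    fix.centroid_x_cm - px[names.index(nm), mid],
                    fix.centroid_y_cm - py[names.index(nm), mid]))))
    return labels


def cumulative_fixation_time(fixations: list[Fixation], labels: list[str | None],
                             aircraft: str, window_s: tuple[float, float]) -> float:
    """Seconds of fixation time assigned to ``aircraft`` inside the window.

    Fixations are clipped to the window; ``labels`` is the per-fixation
    dynamic assignment (parallel to ``fixations``).
    """
    t0, t1 = window_s
    if t0 >= t1:
        raise ValueError("window must satisfy t0 < t1")
    total = 0.0
    for fix, label in zip(fixations, labels):
        if label != aircraft:
            continue
        overlap = min(fix.end_ms / 1000.0, t1) - max(fix.start_ms / 1000.0, t0)
        if overlap > 0:
            total += overlap
    return total


@dataclass
class AttentionSeries:
    """Trailing sliding-window fixation-time shares per aircraft, percent."""

    window_ms: float
    times_ms: np.ndarray
    shares_pct: dict[str, np.ndarray]

    @property
    def total_pct(self) -> np.ndarray:
        return self.shares_pct["Total"]


def sliding_window_attention(fixations: list[Fixation], labels: list[str | None],
                             aircraft: list[str], record_duration_ms: float,
                             window_ms: float = 10_000.0,
                             sampling_rate_hz: float = 30.0) -> AttentionSeries:
    """Percentage of each trailing window spent fixating each aircraft.

    Grid step is one sample period; the series starts once a full window is
    available.  The "Total" series is the sum over the listed aircraft.
    """
    if record_duration_ms <= window_ms:
        raise ValueError("record shorter than the sliding window; "
                         "use a shorter window")
    period = 1000.0 / sampling_rate_hz
    n = int(round(record_duration_ms / period))
    grid = np.arange(n) * period
    win = int(round(window_ms / period))
    shares: dict[str, np.ndarray] = {}
    total = np.zeros(n - win)
    for ac in aircraft:
        occupied = np.zeros(n, dtype=float)
        for fix, label in zip(fixations, labels):
            if label != ac:
                continue
            i0 = int(np.ceil(fix.start_ms / period - 1e-9))
            i1 = int(np.ceil(fix.end_ms / period - 1e-9))
            occupied[max(i0, 0):min(i1, n)] = 1.0
        csum = np.concatenate(([0.0], np.cumsum(occupied)))
        s = 100.0 * (csum[win:-1] - csum[:-win - 1]) / win
        shares[ac] = s
        total += s
    shares["Total"] = total
    return AttentionSeries(window_ms=window_ms, times_ms=grid[win:] ,
                           shares_pct=shares)


def sector_entry_time(trajectory: Trajectory, scenario: Scenario,
                      sector: RectAOI, grid_s: float = 1.0) -> float:
    """First time the projected symbol enters the sector rectangle (0 if inside at start)."""
    t = np.arange(0.0, scenario.duration_s + grid_s / 2, grid_s)
    x, y = scenario.viewport.to_screen(*trajectory.position_at(t))
    inside = sector.contains(x, y)
    idx = np.flatnonzero(inside)
    if idx.size == 0:
        raise ValueError(f"{trajectory.flight} never enters the sector")
    return float(t[idx[0]])
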