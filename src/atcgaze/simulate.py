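"""Synthetic study generator: scenarios, gaze streams, interventions, scores.

This module stands in for the raw recordings of a 24-participant simulated
en route control study (2 traffic x 3 complexity within-subject design,
16-min sessions at 30 Hz).  Every generated quantity has a known ground
truth so each analysis stage can be tested end to end:

* ``generate_scenario`` builds a 960 s traffic picture with the condition's
  aircraft count.  The 12-aircraft / high-complexity scenario embeds two
  scripted conflicts — an Easy pair (level standard-route POB456 vs climbing
  non-standard HYG532) violating separation 140 s after onset if unresolved,
  and a Difficult trio (standard GPL751 and KET456, climbing non-standard
  REV756, plus the uninvolved look-alike SRT346) first violating at 240 s.
  All other aircraft fly routes that are conflict-free by 2,000 ft vertical
  spacing.
* ``simulate_gaze`` renders an alternating fixation/saccade renewal process
  over {aircraft, out-of-sector, flight-plan sheet} targets with
  condition-dependent weights, Poisson blink gaps (both eyes lost,
  truncated-normal durations inside the 100-600 ms band) and an AR(1) pupil
  trace around a condition baseline.
* ``simulate_interventions`` issues clearances that verifiably resolve (or
  fail to resolve) the scripted conflicts.
* ``simulate_cohort`` bundles the full synthetic study.

Calibration targets are the emulated study conditions: pupil 3.41/3.44 mm
(low/high traffic, between-participant SD 0.32), blink durations 315/295 ms,
an ~83/13/4% sector / out-of-sector / sheet split of fixation time, and
Easy-conflict cumulative fixation totals of 35.67 s (solvers) vs 16.11 s
(non-solvers) with 68.56 vs 81.50 s for the Difficult conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import signal

from .cdr import Intervention, SeparationStandard, check_separation
from .geometry import ScreenGeometry
from .io import GazeStream
from .scenario import ConflictSpec, Scenario, Trajectory, Viewport, KN_TO_NM_PER_S
from .workload import Condition, CONDITIONS, SubjectiveScores

__all__ = [
    "CohortParams", "SessionData", "SyntheticCohort",
    "default_viewport", "schedule_conflict", "schedule_intercept",
    "generate_scenario", "simulate_gaze", "simulate_interventions",
    "simulate_scores", "cohort_scenarios", "iter_cohort_sessions",
    "simulate_cohort", "simulate_metric_table",
]

SECTOR_NM = (110.0, 82.0)  # NM extent mapped onto the 27.5 x 20.5 cm sector


def default_viewport(geometry: ScreenGeometry | None = None) -> Viewport:
    """Linear viewport mapping the sector's NM extent onto the sector rectangle."""
    geometry = geometry or ScreenGeometry()
    from .aoi import SECTOR_HEIGHT_CM, SECTOR_WIDTH_CM
    return Viewport(
        sector_left_cm=(geometry.display_width_cm - SECTOR_WIDTH_CM) / 2,
        sector_top_cm=(geometry.display_height_cm - SECTOR_HEIGHT_CM) / 2,
        sector_width_cm=SECTOR_WIDTH_CM, sector_height_cm=SECTOR_HEIGHT_CM,
        sector_x0_nm=0.0, sector_y0_nm=0.0,
        sector_width_nm=SECTOR_NM[0], sector_height_nm=SECTOR_NM[1])


# ---------------------------------------------------------------------------
# conflict scheduling
# ---------------------------------------------------------------------------

def _velocity(heading_deg: float, gs_kn: float) -> np.ndarray:
    theta = np.radians(heading_deg)
    return gs_kn * KN_TO_NM_PER_S * np.array([np.sin(theta), np.cos(theta)])


class SchedulingError(ValueError):
    """Raised when the requested conflict geometry cannot close."""


def schedule_conflict(target_violation_s: float,
                      flights: tuple[str, str],
                      speeds_kn: tuple[float, float],
                      headings_deg: tuple[float, float],
                      altitudes: tuple[dict, dict],
                      meeting_point_nm: tuple[float, float],
                      standard: SeparationStandard | None = None,
                      grid_s: float = 1.0,
                      duration_s: float = 960.0,
                      route_classes: tuple[str, str] = ("standard", "non-standard"),
                      name: str = "conflict") -> tuple[ConflictSpec, dict[str, Trajectory]]:
    """Place two aircraft so their first loss of separation falls on target.

    Both aircraft are put on a collision course through ``meeting_point_nm``;
    initial positions are back-computed so the lateral distance crosses the
    5 NM minimum half a grid step before ``target_violation_s`` (hence the
    first violating 1 s grid time is the target itself).  Altitude dicts take
    the keys of :meth:`Trajectory.straight` (``alt0_ft``, optional
    ``climb_to_ft``/``climb_rate_ft_min``); vertical separation must already
    be below the minimum when the lateral gap closes, otherwise scheduling
    fails.  The round trip is verified with :func:`check_separation`.
    """
    standard = standard or SeparationStandard()
    va = _velocity(headings_deg[0], speeds_kn[0])
    vb = _velocity(headings_deg[1], speeds_kn[1])
    w = vb - va
    speed = float(np.hypot(*w))
    if speed < 1e-9:
        raise SchedulingError("courses do not close (zero relative velocity)")
    t_cross = target_violation_s - grid_s / 2.0
    if t_cross <= 0:
        raise SchedulingError("target time too early for the grid")
    t_hit = t_cross + standard.lateral_min_nm / speed
    p = np.asarray(meeting_point_nm, dtype=float)
    trajs = {}
    for flight, v, alt, rc in zip(flights, (va, vb), altitudes, route_classes):
        x0, y0 = p - v * t_hit
        trajs[flight] = Trajectory.straight(
            flight, x0, y0,
            course_deg=float(np.degrees(np.arctan2(v[0], v[1]))),
            gs_kn=float(np.hypot(*v) / KN_TO_NM_PER_S),
            alt0_ft=alt["alt0_ft"], duration_s=duration_s,
            climb_to_ft=alt.get("climb_to_ft"),
            climb_rate_ft_min=alt.get("climb_rate_ft_min", 0.0),
            route_class=rc)
    spec = ConflictSpec(name=name, aircraft=tuple(flights),
                        scripted_violation_s=target_violation_s,
                        crossing_angle_deg=abs(headings_deg[1] - headings_deg[0]))
    probe = Scenario(traffic=2, complexity="probe", trajectories=trajs,
                     viewport=default_viewport(), duration_s=duration_s)
    t_found = check_separation(probe, standard=standard, grid_s=grid_s)
    if t_found is None or abs(t_found - target_violation_s) > grid_s:
        raise SchedulingError(
            f"vertical profile never unsafe near the lateral closure "
            f"(checker found {t_found}, wanted {target_violation_s})")
    return spec, trajs


def schedule_intercept(fixed: Trajectory, flight: str, gs_kn: float,
                       heading_deg: float, target_violation_s: float,
                       alt: dict, standard: SeparationStandard | None = None,
                       grid_s: float = 1.0, duration_s: float = 960.0,
                       route_class: str = "standard") -> Trajectory:
    """Place one aircraft on a collision course with an existing trajectory
    so their first loss of separation falls on ``target_violation_s``."""
    standard = standard or SeparationStandard()
    v_new = _velocity(heading_deg, gs_kn)
    t_cross = target_violation_s - grid_s / 2.0
    # fixed aircraft velocity around the crossing (its track is straight)
    eps = 1.0
    fx0, fy0 = fixed.position_at(t_cross - eps)
    fx1, fy1 = fixed.position_at(t_cross + eps)
    v_fix = np.array([(fx1 - fx0), (fy1 - fy0)]) / (2 * eps)
    w = v_new - v_fix
    speed = float(np.hypot(*w))
    if speed < 1e-9:
        raise SchedulingError("intercept course does not close")
    t_hit = t_cross + standard.lateral_min_nm / speed
    p = np.asarray(fixed.position_at(t_hit))
    x0, y0 = p - v_new * t_hit
    return Trajectory.straight(
        flight, x0, y0, heading_deg, gs_kn, alt0_ft=alt["alt0_ft"],
        duration_s=duration_s, climb_to_ft=alt.get("climb_to_ft"),
        climb_rate_ft_min=alt.get("climb_rate_ft_min", 0.0),
        route_class=route_class)


# ---------------------------------------------------------------------------
# packaged scenario
# ---------------------------------------------------------------------------

EASY_AIRCRAFT = ("POB456", "HYG532")
DIFFICULT_AIRCRAFT = ("REV756", "KET456", "GPL751")
LOOKALIKE = "SRT346"

# vertical layout: the Easy cluster sits at 27.2-29 kft, the Difficult
# cluster at 33.2-35.2 kft (+ look-alike at 37 kft); fillers keep >= 2,000 ft
# to every cluster and to each other, so only scripted pairs can conflict.
_FILLER_LEVELS_12HIGH = [21_000, 23_000, 25_000, 31_000, 39_000, 41_000]


def _easy_conflict(duration_s: float) -> tuple[ConflictSpec, dict[str, Trajectory]]:
    spec, trajs = schedule_conflict(
        target_violation_s=140.0,
        flights=EASY_AIRCRAFT,
        speeds_kn=(450.0, 350.0),
        headings_deg=(90.0, 160.0),
        altitudes=({"alt0_ft": 29_000.0},
                   {"alt0_ft": 27_200.0, "climb_to_ft": 28_800.0,
                    "climb_rate_ft_min": 1_200.0}),
        meeting_point_nm=(40.0, 68.0),
        duration_s=duration_s,
        name="easy")
    return spec, trajs


def _difficult_conflict(duration_s: float) -> tuple[ConflictSpec, dict[str, Trajectory]]:
    spec_rk, trajs = schedule_conflict(
        target_violation_s=240.0,
        flights=("KET456", "REV756"),
        speeds_kn=(430.0, 300.0),
        headings_deg=(270.0, 350.0),
        altitudes=({"alt0_ft": 34_000.0},
                   {"alt0_ft": 33_200.0, "climb_to_ft": 34_800.0,
                    "climb_rate_ft_min": 1_200.0}),
        meeting_point_nm=(75.0, 35.0),
        route_classes=("standard", "non-standard"),
        duration_s=duration_s,
        name="difficult")
    trajs["GPL751"] = schedule_intercept(
        trajs["REV756"], "GPL751", gs_kn=355.0, heading_deg=180.0,
        target_violation_s=300.0, alt={"alt0_ft": 35_200.0},
        duration_s=duration_s)
    # look-alike on a similar non-standard track, 2,000+ ft above everything
    rev = trajs["REV756"]
    trajs[LOOKALIKE] = Trajectory.straight(
        LOOKALIKE, float(rev.x_nm[0]) + 12.0, float(rev.y_nm[0]) - 2.0,
        course_deg=350.0, gs_kn=300.0, alt0_ft=37_000.0,
        duration_s=duration_s, route_class="non-standard")
    spec = ConflictSpec(name="difficult", aircraft=DIFFICULT_AIRCRAFT,
                        scripted_violation_s=240.0,
                        crossing_angle_deg=spec_rk.crossing_angle_deg)
    return spec, trajs


def _filler_trajectories(n: int, levels_ft: list[float], rng: np.random.Generator,
                         duration_s: float) -> dict[str, Trajectory]:
    """Level cross-sector routes, mutually safe by 2,000 ft vertical spacing."""
    trajs = {}
    ys = np.linspace(10.0, SECTOR_NM[1] - 10.0, n) + rng.uniform(-3, 3, n)
    for i in range(n):
        eastbound = i % 2 == 0
        gs = float(rng.uniform(390.0, 440.0))
        length = gs * KN_TO_NM_PER_S * duration_s
        x0 = -2.0 if eastbound else SECTOR_NM[0] + 2.0
        # keep the route inside the display margin for the whole session
        x0 = x0 if eastbound else max(x0, length - 60.0)
        trajs[f"FIL{i + 1:03d}"] = Trajectory.straight(
            f"FIL{i + 1:03d}", x0, float(ys[i]),
            course_deg=90.0 if eastbound else 270.0, gs_kn=gs,
            alt0_ft=float(levels_ft[i]), duration_s=duration_s)
    return trajs


def generate_scenario(condition: Condition, seed: int = 0,
                      geometry: ScreenGeometry | None = None,
                      duration_s: float = 960.0) -> Scenario:
    """A 960 s scenario with the condition's aircraft count.

    Only the 12-aircraft / high-complexity scenario carries the two scripted
    conflicts; every other traffic picture is conflict-free by construction.
    """
    rng = np.random.default_rng(seed)
    trajectories: dict[str, Trajectory] = {}
    conflicts: list[ConflictSpec] = []
    if condition.traffic == 12 and condition.complexity == "high":
        easy, easy_trajs = _easy_conflict(duration_s)
        diff, diff_trajs = _difficult_conflict(duration_s)
        trajectories.update(easy_trajs)
        trajectories.update(diff_trajs)
        conflicts = [easy, diff]
        n_fill = condition.traffic - len(trajectories)
        levels = _FILLER_LEVELS_12HIGH
    else:
        n_fill = condition.traffic
        levels = [21_000 + 2_000 * i for i in range(n_fill)]
    trajectories.update(_filler_trajectories(n_fill, levels, rng, duration_s))
    return Scenario(traffic=condition.traffic, complexity=condition.complexity,
                    trajectories=trajectories, conflicts=conflicts,
                    viewport=default_viewport(geometry), duration_s=duration_s)


# ---------------------------------------------------------------------------
# cohort parameters
# ---------------------------------------------------------------------------

def _by_traffic(low: float, high: float) -> dict[int, float]:
    return {6: low, 12: high}


@dataclass
class CohortParams:
    """Generative parameters of the synthetic cohort (defaults = study conditions)."""

    n_participants: int = 24
    session_duration_s: float = 960.0
    sampling_rate_hz: float = 30.0
    seed_offset: int = 0

    # pupil (mm): baseline by traffic, between-participant SD, AR(1) noise
    pupil_base_mm: dict = field(default_factory=lambda: _by_traffic(3.41, 3.44))
    pupil_between_sd_mm: float = 0.32
    pupil_within_sd_mm: float = 0.04
    pupil_ar1: float = 0.97

    # blinks: Poisson rate per minute (decreasing with traffic, extra drop
    # under high complexity), truncated-normal durations inside 100-600 ms
    blink_rate_per_min: dict = field(default_factory=lambda: _by_traffic(14.0, 9.5))
    blink_rate_high_complexity_drop: float = 1.5
    blink_duration_mean_ms: dict = field(default_factory=lambda: _by_traffic(315.0, 295.0))
    blink_duration_sd_ms: float = 60.0

    # fixation renewal process
    fixation_mean_ms: float = 280.0
    fixation_shape: float = 4.0
    gaze_jitter_cm: float = 0.05
    aircraft_jitter_cm: float = 0.25

    # attention policy: share of fixation targets per static region
    sector_weight: dict = field(default_factory=lambda: {
        "low": 0.78, "medium": 0.83, "high": 0.88})
    sheet_weight: dict = field(default_factory=lambda: _by_traffic(0.055, 0.035))
    aircraft_share_within_sector: float = 0.75

    # conflict gaze calibration (cumulative seconds on conflict aircraft up
    # to the scripted violation) and solver policy
    easy_conflict_gaze_s: dict = field(default_factory=lambda: {
        True: 35.67, False: 16.11})
    difficult_conflict_gaze_s: dict = field(default_factory=lambda: {
        True: 68.56, False: 81.50})
    solver_prob: dict = field(default_factory=lambda: {
        "easy": 8 / 24, "difficult": 13 / 24})

    # subjective scales
    isa_base: float = 2.6
    isa_traffic_effect: float = 1.6
    isa_complexity_effect: dict = field(default_factory=lambda: {
        "low": 0.0, "medium": 0.55, "high": 0.65})
    isa_participant_sd: float = 0.5
    isa_noise_sd: float = 0.6
    nasa_component_base: float = 6.0
    nasa_traffic_effect: float = 4.0
    nasa_complexity_effect: dict = field(default_factory=lambda: {
        "low": 0.0, "medium": 1.2, "high": 1.5})
    nasa_participant_sd: float = 1.5
    nasa_noise_sd: float = 1.5

    head_distance_mean_cm: float = 59.0
    head_distance_sd_cm: float = 1.0
    climb_rate_ft_min: float = 1500.0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.blink_rate_per_min.values()):
            raise ValueError("blink rates must be >= 0")
        if not all(100.0 <= m <= 600.0 for m in self.blink_duration_mean_ms.values()):
            raise ValueError("blink duration means must lie inside [100, 600] ms")
        if not all(0.0 <= p <= 1.0 for p in self.solver_prob.values()):
            raise ValueError("solver probabilities must lie in [0, 1]")

    def blink_rate(self, condition: Condition) -> float:
        rate = self.blink_rate_per_min[condition.traffic]
        if condition.complexity == "high":
            rate -= self.blink_rate_high_complexity_drop
        return max(rate, 0.0)

    def region_weights(self, condition: Condition) -> tuple[float, float, float]:
        """(sector, out_of_sector, sheet) fixation-target weights."""
        sector = self.sector_weight[condition.complexity]
        sheet = self.sheet_weight[condition.traffic]
        return sector, max(1.0 - sector - sheet, 0.0), sheet

    @classmethod
    def null(cls, n_participants: int = 24) -> "CohortParams":
        """Zero-effect variant: all condition-dependent parameters equalized."""
        return cls(
            n_participants=n_participants,
            pupil_base_mm=_by_traffic(3.42, 3.42),
            blink_rate_per_min=_by_traffic(11.0, 11.0),
            blink_rate_high_complexity_drop=0.0,
            blink_duration_mean_ms=_by_traffic(305.0, 305.0),
            sector_weight={"low": 0.83, "medium": 0.83, "high": 0.83},
            sheet_weight=_by_traffic(0.045, 0.045),
            isa_traffic_effect=0.0,
            isa_complexity_effect={"low": 0.0, "medium": 0.0, "high": 0.0},
            nasa_traffic_effect=0.0,
            nasa_complexity_effect={"low": 0.0, "medium": 0.0, "high": 0.0},
        )


# ---------------------------------------------------------------------------
# gaze stream synthesis
# ---------------------------------------------------------------------------

def _inject_blinks(left_valid, right_valid, rate_per_min, mean_ms, sd_ms,
                   period_ms, rng) -> int:
    """Overlay both-eye gaps; returns the number of blinks injected."""
    n = left_valid.size
    minutes = n * period_ms / 60_000.0
    count = rng.poisson(rate_per_min * minutes)
    if count == 0:
        return 0
    # truncated-normal durations kept strictly inside the 100-600 ms band
    durations = rng.normal(mean_ms, sd_ms, size=count * 3)
    durations = durations[(durations >= 120.0) & (durations <= 580.0)][:count]
    while durations.size < count:
        extra = rng.normal(mean_ms, sd_ms, size=count)
        durations = np.concatenate([
            durations, extra[(extra >= 120.0) & (extra <= 580.0)]])[:count]
    lengths = np.clip(np.round(durations / period_ms).astype(int), 4, 17)
    starts = np.sort(rng.integers(2, n - 20, size=count))
    placed = 0
    last_end = -10
    for s, ln in zip(starts, lengths):
        if s <= last_end + 2:  # keep valid samples between gaps
            continue
        left_valid[s:s + ln] = False
        right_valid[s:s + ln] = False
        last_end = s + ln
        placed += 1
    return placed


def _fixation_duty(params: CohortParams, condition: Condition) -> float:
    """Expected fraction of session time inside fixations."""
    period = 1000.0 / params.sampling_rate_hz
    fix = params.fixation_mean_ms
    sac = 1.5 * period
    blink_loss = params.blink_rate(condition) / 60.0 * (
        np.mean(list(params.blink_duration_mean_ms.values())) / 1000.0)
    return fix / (fix + sac) * (1.0 - blink_loss)


def _sample_region_points(code, aois, rng):
    """Uniform points for out-of-sector (code 1) and sheet (code 2) targets."""
    n = code.size
    x = np.empty(n)
    y = np.empty(n)
    m_sheet = code == 2
    x[m_sheet] = rng.uniform(aois.sheet.left_cm, aois.sheet.right_cm, m_sheet.sum())
    y[m_sheet] = rng.uniform(aois.sheet.top_cm, aois.sheet.bottom_cm, m_sheet.sum())
    m_out = code == 1
    k = int(m_out.sum())
    ox = np.empty(0)
    oy = np.empty(0)
    while ox.size < k:  # rejection-sample the complement region
        cx = rng.uniform(0, aois.display_width_cm, 2 * k + 8)
        cy = rng.uniform(0, aois.display_height_cm, 2 * k + 8)
        keep = ~aois.sector.contains(cx, cy) & ~aois.sheet.contains(cx, cy)
        ox = np.concatenate([ox, cx[keep]])
        oy = np.concatenate([oy, cy[keep]])
    x[m_out] = ox[:k]
    y[m_out] = oy[:k]
    return x, y


def simulate_gaze(scenario: Scenario, params: CohortParams,
                  rng: np.random.Generator,
                  condition: Condition | None = None,
                  participant_id: str = "P01",
                  pupil_offset_mm: float = 0.0,
                  solver: dict[str, bool] | None = None,
                  geometry: ScreenGeometry | None = None) -> GazeStream:
    """Render one session's 30 Hz gaze stream over a scenario.

    ``solver`` maps conflict names to resolution outcomes and controls the
    dwell boost on conflict aircraft before each scripted violation.
    """
    from .aoi import build_static_aois

    geometry = geometry or ScreenGeometry(sampling_rate_hz=params.sampling_rate_hz)
    condition = condition or Condition(scenario.traffic, scenario.complexity)
    solver = solver or {}
    aois = build_static_aois(geometry)
    period = 1000.0 / params.sampling_rate_hz
    n = int(round(scenario.duration_s * params.sampling_rate_hz))
    t_grid_s = np.arange(n) * period / 1000.0

    # projected aircraft tracks on the sample grid
    names = list(scenario.trajectories)
    pos = np.empty((len(names), 2, n))
    for i, name in enumerate(names):
        px, py = scenario.viewport.to_screen(
            *scenario.trajectories[name].position_at(t_grid_s))
        pos[i, 0] = px
        pos[i, 1] = py
    conflict_idx = {c.name: np.array([names.index(a) for a in c.aircraft])
                    for c in scenario.conflicts}

    # --- renewal process: alternating fixation / saccade events ----------
    mean_len = params.fixation_mean_ms / period
    n_events = int(n / (mean_len + 1.5) * 1.35) + 16
    fix_len = np.clip(np.round(rng.gamma(
        params.fixation_shape, params.fixation_mean_ms / params.fixation_shape,
        n_events) / period).astype(int), 3, 45)
    sac_len = rng.integers(1, 3, n_events)
    lengths = np.empty(2 * n_events, dtype=int)
    lengths[0::2] = fix_len
    lengths[1::2] = sac_len
    ends = np.cumsum(lengths)
    n_events_used = int(np.searchsorted(ends, n)) + 1
    lengths = lengths[:n_events_used]
    starts = np.concatenate(([0], ends[:n_events_used - 1]))
    is_fix = np.arange(n_events_used) % 2 == 0

    fix_starts = starts[is_fix]
    k = fix_starts.size
    t_fix_s = fix_starts * period / 1000.0

    # --- fixation target categories --------------------------------------
    # codes: 0 sector, 1 out-of-sector, 2 sheet, 3 easy conflict, 4 difficult
    w_sector, w_out, w_sheet = params.region_weights(condition)
    duty = _fixation_duty(params, condition)
    p_conf = np.zeros((2, k))
    targets = {"easy": params.easy_conflict_gaze_s,
               "difficult": params.difficult_conflict_gaze_s}
    for row, c in enumerate(scenario.conflicts):
        tot = targets[c.name][bool(solver.get(c.name, False))]
        p_conf[row] = np.where(t_fix_s < c.scripted_violation_s,
                               tot / (c.scripted_violation_s * duty), 0.0)
    p_conf_tot = p_conf.sum(axis=0)
    np.clip(p_conf_tot, 0.0, 0.85, out=p_conf_tot)
    rest = 1.0 - p_conf_tot
    u = rng.uniform(size=k)
    code = np.full(k, 0, dtype=int)
    edges0 = p_conf[0] if scenario.conflicts else np.zeros(k)
    edges1 = p_conf_tot
    edges2 = edges1 + rest * w_out
    edges3 = edges2 + rest * w_sheet
    if scenario.conflicts:
        code[u < edges0] = 3
        code[(u >= edges0) & (u < edges1)] = 4
    code[(u >= edges1) & (u < edges2)] = 1
    code[(u >= edges2) & (u < edges3)] = 2

    # --- target positions -------------------------------------------------
    x_t = np.empty(k)
    y_t = np.empty(k)
    start_idx = np.minimum(fix_starts, n - 1)
    # sector fixations: mostly on a random aircraft, else a random sector point
    m = code == 0
    on_ac = m & (rng.uniform(size=k) < params.aircraft_share_within_sector)
    # conflict aircraft receive attention through the boost probabilities
    # only, so the boost alone calibrates the conflict dwell totals
    in_conflict = {a for c in scenario.conflicts for a in c.aircraft}
    pool = np.array([i for i, nm in enumerate(names) if nm not in in_conflict]
                    or list(range(len(names))))
    ac = pool[rng.integers(0, pool.size, size=k)]
    x_t[on_ac] = pos[ac[on_ac], 0, start_idx[on_ac]]
    y_t[on_ac] = pos[ac[on_ac], 1, start_idx[on_ac]]
    m_pt = m & ~on_ac
    x_t[m_pt] = rng.uniform(aois.sector.left_cm, aois.sector.right_cm, m_pt.sum())
    y_t[m_pt] = rng.uniform(aois.sector.top_cm, aois.sector.bottom_cm, m_pt.sum())
    # conflict-aircraft fixations
    for code_val, cname in ((3, "easy"), (4, "difficult")):
        mc = code == code_val
        if not mc.any():
            continue
        idx = conflict_idx[cname]
        pick = idx[rng.integers(0, idx.size, size=int(mc.sum()))]
        x_t[mc] = pos[pick, 0, start_idx[mc]]
        y_t[mc] = pos[pick, 1, start_idx[mc]]
    ac_like = (code == 0) & on_ac | (code >= 3)
    x_t[ac_like] += rng.normal(0, params.aircraft_jitter_cm, int(ac_like.sum()))
    y_t[ac_like] += rng.normal(0, params.aircraft_jitter_cm, int(ac_like.sum()))
    # peripheral regions
    ox, oy = _sample_region_points(code, aois, rng)
    per = (code == 1) | (code == 2)
    x_t[per] = ox[per]
    y_t[per] = oy[per]
    np.clip(x_t, 0.05, geometry.display_width_cm - 0.05, out=x_t)
    np.clip(y_t, 0.05, geometry.display_height_cm - 0.05, out=y_t)

    # --- expand events to samples ----------------------------------------
    event_x = np.empty(n_events_used)
    event_y = np.empty(n_events_used)
    event_x[is_fix] = x_t
    event_y[is_fix] = y_t
    sac = ~is_fix
    prev_fix = np.arange(n_events_used)[is_fix]
    # saccade events sit between fixation i and i+1: use the midpoint
    nxt = np.concatenate([x_t[1:], x_t[-1:]])
    nyt = np.concatenate([y_t[1:], y_t[-1:]])
    n_sac = int(sac.sum())
    event_x[sac] = ((x_t + nxt) / 2)[:n_sac]
    event_y[sac] = ((y_t + nyt) / 2)[:n_sac]
    x = np.repeat(event_x, lengths)[:n]
    y = np.repeat(event_y, lengths)[:n]
    x = x + rng.normal(0, params.gaze_jitter_cm, n)
    y = y + rng.normal(0, params.gaze_jitter_cm, n)

    # --- validity / blinks -------------------------------------------------
    left_valid = np.ones(n, dtype=bool)
    right_valid = np.ones(n, dtype=bool)
    _inject_blinks(left_valid, right_valid, params.blink_rate(condition),
                   params.blink_duration_mean_ms[condition.traffic],
                   params.blink_duration_sd_ms, period, rng)

    # --- pupil and head distance ------------------------------------------
    base = params.pupil_base_mm[condition.traffic] + pupil_offset_mm
    innov = rng.normal(0.0, params.pupil_within_sd_mm
                       * np.sqrt(1 - params.pupil_ar1 ** 2), n)
    pupil = base + signal.lfilter([1.0], [1.0, -params.pupil_ar1], innov)
    asym = rng.normal(0.0, 0.05)
    pupil_left = pupil - asym / 2
    pupil_right = pupil + asym / 2
    dist = (params.head_distance_mean_cm
            + rng.normal(0, params.head_distance_sd_cm)
            + rng.normal(0, 0.2, n))

    return GazeStream(
        t_ms=np.arange(n) * period,
        left_valid=left_valid, right_valid=right_valid,
        x_cm=x, y_cm=y,
        pupil_left_mm=pupil_left, pupil_right_mm=pupil_right,
        eye_distance_cm=dist, geometry=geometry,
        participant_id=participant_id, condition_id=condition.label)


# ---------------------------------------------------------------------------
# interventions and subjective scores
# ---------------------------------------------------------------------------

def simulate_interventions(scenario: Scenario, solver: dict[str, bool],
                           params: CohortParams,
                           rng: np.random.Generator) -> list[Intervention]:
    """Clearance log for one participant on the conflict-bearing scenario.

    Solver logs resolve the corresponding conflict (clearances issued well
    before closure, verified by construction against the packaged geometry);
    non-solver logs are empty or contain only post-violation actions.
    """
    if not scenario.conflicts:
        return []
    log: list[Intervention] = []
    by_name = {c.name: c for c in scenario.conflicts}
    if "easy" in by_name:
        entry_s = 25.0  # HYG532 crosses the sector boundary shortly after onset
        log.append(Intervention(entry_s + float(np.clip(abs(rng.normal(12, 9)), 1, 60)),
                                "HYG532", "accept"))
        if solver.get("easy", False):
            t0 = float(rng.uniform(60, 95))
            if rng.uniform() < 0.75:
                log.append(Intervention(t0, "HYG532", "altitude", 27_800.0))
            else:
                log.append(Intervention(t0, "POB456", "altitude", 30_000.0))
        elif rng.uniform() < 0.06:  # rare, too-late action that cannot help
            log.append(Intervention(float(rng.uniform(200, 400)),
                                    "POB456", "altitude", 30_000.0))
    if "difficult" in by_name:
        if solver.get("difficult", False):
            log.append(Intervention(float(rng.uniform(110, 155)),
                                    "REV756", "altitude", 32_800.0))
            log.append(Intervention(float(rng.uniform(190, 250)),
                                    "GPL751", "altitude", 36_400.0))
            if rng.uniform() < 0.15:
                log.append(Intervention(float(rng.uniform(320, 420)),
                                        "REV756", "speed", 280.0))
        else:
            u = rng.uniform()
            if u < 0.18:
                log.append(Intervention(float(rng.uniform(260, 350)),
                                        "REV756", "altitude", 32_800.0))
            elif u < 0.45:
                log.append(Intervention(float(rng.uniform(300, 450)),
                                        "GPL751", "altitude", 36_400.0))
    return sorted(log, key=lambda iv: iv.t_s)


def simulate_scores(condition: Condition, params: CohortParams,
                    rng: np.random.Generator,
                    isa_offset: float = 0.0,
                    nasa_offset: float = 0.0) -> SubjectiveScores:
    """ISA and NASA-TLX responses as monotone noisy functions of demand."""
    mu_isa = (params.isa_base
              + params.isa_traffic_effect * (condition.traffic == 12)
              + params.isa_complexity_effect[condition.complexity]
              + isa_offset)
    isa = np.clip(np.round(rng.normal(mu_isa, params.isa_noise_sd, 8)),
                  1, 7).astype(int)
    mu_nasa = (params.nasa_component_base
               + params.nasa_traffic_effect * (condition.traffic == 12)
               + params.nasa_complexity_effect[condition.complexity]
               + nasa_offset)
    nasa = np.clip(np.round(rng.normal(mu_nasa, params.nasa_noise_sd, 6)),
                   1, 20).astype(int)
    return SubjectiveScores(tuple(int(v) for v in isa),
                            tuple(int(v) for v in nasa))


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SessionData:
    """One participant x condition session with its generative ground truth."""

    participant_id: str
    condition: Condition
    stream: GazeStream
    scores: SubjectiveScores
    interventions: list[Intervention]
    solver: dict[str, bool]


@dataclass
class SyntheticCohort:
    params: CohortParams
    seed: int
    scenarios: dict[str, Scenario]
    sessions: list[SessionData]
    solver_truth: dict[str, dict[str, bool]]  # participant -> conflict -> flag


def _participant_draws(params: CohortParams, rng: np.random.Generator) -> dict:
    return {
        "pupil": float(rng.normal(0, params.pupil_between_sd_mm)),
        "isa": float(rng.normal(0, params.isa_participant_sd)),
        "nasa": float(rng.normal(0, params.nasa_participant_sd)),
        "solver": {name: bool(rng.uniform() < p)
                   for name, p in params.solver_prob.items()},
    }


def cohort_scenarios(params: CohortParams, seed: int) -> dict[str, Scenario]:
    """The six per-condition scenarios used by a cohort run (deterministic)."""
    root = np.random.SeedSequence(seed + params.seed_offset)
    scen_seq, _ = root.spawn(2)
    scen_seeds = scen_seq.generate_state(len(CONDITIONS))
    return {c.label: generate_scenario(c, int(s) % (2 ** 31))
            for c, s in zip(CONDITIONS, scen_seeds)}


def iter_cohort_sessions(params: CohortParams, seed: int,
                         scenarios: dict[str, Scenario] | None = None
                         ) -> Iterator[SessionData]:
    """Lazily yield all participant x condition sessions (memory-friendly)."""
    root = np.random.SeedSequence(seed + params.seed_offset)
    _, cohort_seq = root.spawn(2)
    if scenarios is None:
        scenarios = cohort_scenarios(params, seed)
    part_seqs = cohort_seq.spawn(params.n_participants)
    for p, pseq in enumerate(part_seqs):
        pid = f"P{p + 1:02d}"
        rng = np.random.default_rng(pseq)
        draws = _participant_draws(params, rng)
        for condition in CONDITIONS:
            scenario = scenarios[condition.label]
            stream = simulate_gaze(scenario, params, rng, condition=condition,
                                   participant_id=pid,
                                   pupil_offset_mm=draws["pupil"],
                                   solver=draws["solver"])
            interventions = simulate_interventions(scenario, draws["solver"],
                                                   params, rng)
            scores = simulate_scores(condition, params, rng,
                                     isa_offset=draws["isa"],
                                     nasa_offset=draws["nasa"])
            yield SessionData(pid, condition, stream, scores, interventions,
                              dict(draws["solver"]))


def simulate_cohort(params: CohortParams | None = None, seed: int = 0
                    ) -> SyntheticCohort:
    """Materialize the full synthetic study (24 x 6 sessions by default)."""
    params = params or CohortParams()
    scenarios = cohort_scenarios(params, seed)
    sessions = list(iter_cohort_sessions(params, seed, scenarios))
    truth = {s.participant_id: s.solver for s in sessions}
    return SyntheticCohort(params=params, seed=seed, scenarios=scenarios,
                           sessions=sessions, solver_truth=truth)


def simulate_metric_table(params: CohortParams | None = None, seed: int = 0):
    """Session-level workload metrics drawn directly from the generative model.

    Bypasses gaze-stream rendering: each participant x condition row is drawn
    from the same distributions the full pipeline targets (pupil baseline +
    participant offset, Poisson blink counts, region time shares, subjective
    scales).  Intended for statistical calibration studies (type-I error,
    power) where hundreds of replicate cohorts are needed.
    """
    import pandas as pd

    params = params or CohortParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed + params.seed_offset))
    rows = []
    for p in range(params.n_participants):
        pid = f"P{p + 1:02d}"
        off_pupil = rng.normal(0, params.pupil_between_sd_mm)
        off_isa = rng.normal(0, params.isa_participant_sd)
        off_nasa = rng.normal(0, params.nasa_participant_sd)
        blink_mult = float(np.exp(rng.normal(0, 0.2)))
        for condition in CONDITIONS:
            minutes = params.session_duration_s / 60.0
            w_sector, w_out, w_sheet = params.region_weights(condition)
            share = rng.dirichlet(np.array([w_sector, w_out, w_sheet]) * 160)
            fix_total = params.session_duration_s * rng.normal(0.82, 0.02)
            isa = simulate_scores(condition, params, rng, off_isa, off_nasa)
            rows.append({
                "participant": pid,
                "traffic": condition.traffic,
                "complexity": condition.complexity,
                "pupil_mean_mm": params.pupil_base_mm[condition.traffic]
                + off_pupil + rng.normal(0, 0.01),
                "blink_count": rng.poisson(
                    params.blink_rate(condition) * minutes * blink_mult),
                "blink_mean_ms": rng.normal(
                    params.blink_duration_mean_ms[condition.traffic], 12.0),
                "fix_time_sector_s": fix_total * share[0],
                "fix_time_out_of_sector_s": fix_total * share[1],
                "fix_time_sheet_s": fix_total * share[2],
                "isa_mean": float(np.mean(isa.isa_ratings)),
                "nasa_sum": int(np.sum(isa.nasa_components)),
            })
    return pd.DataFrame(rows)
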