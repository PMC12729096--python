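"""Aircraft trajectories, scripted conflicts, and world-to-screen projection.

World coordinates are nautical miles (x east, y north), altitudes in feet,
ground speeds in knots.  A :class:`Viewport` maps the controlled sector's NM
extent linearly onto the central sector rectangle of the radar display, so
screen positions inherit the cm convention (origin top-left, y down) used by
the gaze modules.

A :class:`Trajectory` is a piecewise-linear waypoint sequence; positions and
altitudes between waypoints are linearly interpolated and held constant after
the last waypoint.  Clearances (altitude, speed) are applied by rebuilding
the waypoint list from the clearance time onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Trajectory", "Viewport", "ConflictSpec", "Scenario"]

KN_TO_NM_PER_S = 1.0 / 3600.0


@dataclass
class Trajectory:
    """Piecewise-linear aircraft motion: waypoints (t_s, x_nm, y_nm, alt_ft, gs_kn)."""

    flight: str
    times_s: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    alt_ft: np.ndarray
    gs_kn: np.ndarray
    route_class: str = "standard"
    vertical_rate_ft_min: float = 0.0

    def __post_init__(self) -> None:
        for name in ("times_s", "x_nm", "y_nm", "alt_ft", "gs_kn"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError(f"{self.flight}: waypoint times must increase")

    @classmethod
    def straight(cls, flight: str, x0_nm: float, y0_nm: float,
                 course_deg: float, gs_kn: float, alt0_ft: float,
                 duration_s: float = 960.0, climb_to_ft: float | None = None,
                 climb_rate_ft_min: float = 0.0,
                 route_class: str = "standard") -> "Trajectory":
        """Constant-course trajectory, optionally climbing to a level-off.

        ``course_deg`` is measured clockwise from north (aviation convention).
        """
        theta = np.radians(course_deg)
        ux, uy = np.sin(theta), np.cos(theta)
        v = gs_kn * KN_TO_NM_PER_S
        times = [0.0]
        alts = [alt0_ft]
        if climb_to_ft is not None and climb_rate_ft_min != 0.0:
            t_level = abs(climb_to_ft - alt0_ft) / abs(climb_rate_ft_min) * 60.0
            if 0 < t_level < duration_s:
                times.append(t_level)
                alts.append(climb_to_ft)
            final_alt = climb_to_ft
        else:
            final_alt = alt0_ft
        times.append(duration_s)
        alts.append(final_alt)
        t = np.asarray(times)
        return cls(
            flight=flight,
            times_s=t,
            x_nm=x0_nm + ux * v * t,
            y_nm=y0_nm + uy * v * t,
            alt_ft=np.asarray(alts),
            gs_kn=np.full(t.size, gs_kn),
            route_class=route_class,
            vertical_rate_ft_min=(climb_rate_ft_min if climb_to_ft is not None else 0.0),
        )

    def position_at(self, t_s):
        """(x_nm, y_nm) at time(s) t_s; held constant outside the waypoint span."""
        t = np.asarray(t_s, dtype=float)
        return (np.interp(t, self.times_s, self.x_nm),
                np.interp(t, self.times_s, self.y_nm))

    def altitude_at(self, t_s):
        return np.interp(np.asarray(t_s, dtype=float), self.times_s, self.alt_ft)

    def state_at(self, t_s):
        """(x_nm, y_nm, alt_ft) at t_s."""
        x, y = self.position_at(t_s)
        return x, y, self.altitude_at(t_s)

    @property
    def t_end(self) -> float:
        return float(self.times_s[-1])

    # -- clearances -------------------------------------------------------
    def with_altitude_clearance(self, t_s: float, cleared_ft: float,
                                rate_ft_min: float = 1500.0) -> "Trajectory":
        """Level off toward ``cleared_ft`` at ``rate_ft_min`` starting at ``t_s``."""
        if rate_ft_min <= 0:
            raise ValueError("rate_ft_min must be > 0")
        x0, y0 = self.position_at(t_s)
        alt0 = float(self.altitude_at(t_s))
        t_reach = t_s + abs(cleared_ft - alt0) / rate_ft_min * 60.0
        # keep the ground track, replace the altitude profile from t_s on
        keep = self.times_s < t_s
        times = list(self.times_s[keep]) + [t_s]
        alts = list(self.alt_ft[keep]) + [alt0]
        xs = list(self.x_nm[keep]) + [x0]
        ys = list(self.y_nm[keep]) + [y0]
        gss = list(self.gs_kn[keep]) + [float(np.interp(t_s, self.times_s, self.gs_kn))]
        end = max(self.t_end, t_reach + 1.0)
        for tt in sorted({t_reach, end}):
            if tt <= t_s:
                continue
            x, y = self.position_at(tt)
            times.append(tt)
            xs.append(x)
            ys.append(y)
            alts.append(cleared_ft if tt >= t_reach
                        else alt0 + np.sign(cleared_ft - alt0) * rate_ft_min / 60.0 * (tt - t_s))
            gss.append(gss[-1])
        return replace(self, times_s=np.asarray(times), x_nm=np.asarray(xs),
                       y_nm=np.asarray(ys), alt_ft=np.asarray(alts),
                       gs_kn=np.asarray(gss))

    def with_speed_clearance(self, t_s: float, cleared_kn: float) -> "Trajectory":
        """Scale the along-track ground speed from ``t_s`` onward."""
        if cleared_kn <= 0:
            raise ValueError("cleared_kn must be > 0")
        x0, y0 = self.position_at(t_s)
        alt0 = float(self.altitude_at(t_s))
        gs_old = float(np.interp(t_s, self.times_s, self.gs_kn))
        factor = cleared_kn / gs_old if gs_old > 0 else 1.0
        keep = self.times_s < t_s
        times = list(self.times_s[keep]) + [t_s]
        xs = list(self.x_nm[keep]) + [x0]
        ys = list(self.y_nm[keep]) + [y0]
        alts = list(self.alt_ft[keep]) + [alt0]
        gss = list(self.gs_kn[keep]) + [cleared_kn]
        for tt in self.times_s[self.times_s > t_s]:
            x, y = self.position_at(tt)
            times.append(tt)
            xs.append(x0 + (x - x0) * factor)
            ys.append(y0 + (y - y0) * factor)
            alts.append(float(self.altitude_at(tt)))
            gss.append(cleared_kn)
        return replace(self, times_s=np.asarray(times), x_nm=np.asarray(xs),
                       y_nm=np.asarray(ys), alt_ft=np.asarray(alts),
                       gs_kn=np.asarray(gss))


@dataclass(frozen=True)
class Viewport:
    """Linear NM -> screen-cm projection.

    The sector's NM bounding box maps onto the central sector rectangle;
    world y (north) increases upward, screen y increases downward.
    """

    sector_left_cm: float
    sector_top_cm: float
    sector_width_cm: float
    sector_height_cm: float
    sector_x0_nm: float
    sector_y0_nm: float
    sector_width_nm: float
    sector_height_nm: float

    @property
    def scale_x(self) -> float:
        return self.sector_width_cm / self.sector_width_nm

    @property
    def scale_y(self) -> float:
        return self.sector_height_cm / self.sector_height_nm

    def to_screen(self, x_nm, y_nm):
        x = self.sector_left_cm + (np.asarray(x_nm, float) - self.sector_x0_nm) * self.scale_x
        y = self.sector_top_cm + (self.sector_y0_nm + self.sector_height_nm
                                  - np.asarray(y_nm, float)) * self.scale_y
        return x, y

    def to_world(self, x_cm, y_cm):
        x = self.sector_x0_nm + (np.asarray(x_cm, float) - self.sector_left_cm) / self.scale_x
        y = (self.sector_y0_nm + self.sector_height_nm
             - (np.asarray(y_cm, float) - self.sector_top_cm) / self.scale_y)
        return x, y


@dataclass(frozen=True)
class ConflictSpec:
    """A scripted loss-of-separation event among the named aircraft."""

    name: str
    aircraft: tuple[str, ...]
    scripted_violation_s: float
    crossing_angle_deg: float = 90.0

    def __post_init__(self) -> None:
        if len(self.aircraft) not in (2, 3):
            raise ValueError("conflicts involve 2 or 3 aircraft")
        if self.scripted_violation_s <= 0:
            raise ValueError("scripted_violation_s must be > 0")

    def pairs(self):
        ac = self.aircraft
        return [(ac[i], ac[j]) for i in range(len(ac)) for j in range(i + 1, len(ac))]


@dataclass
class Scenario:
    """A 16-min traffic picture: trajectories, scripted conflicts, projection."""

    traffic: int
    complexity: str
    trajectories: dict[str, Trajectory]
    conflicts: list[ConflictSpec] = field(default_factory=list)
    viewport: Viewport | None = None
    duration_s: float = 960.0

    @property
    def condition_id(self) -> str:
        return f"{self.traffic}-{self.complexity}"

    def screen_positions(self, t_s):
        """dict flight -> (x_cm, y_cm) arrays at times t_s."""
        if self.viewport is None:
            raise ValueError("scenario has no viewport")
        out = {}
        for name, traj in self.trajectories.items():
            out[name] = self.viewport.to_screen(*traj.position_at(t_s))
        return out
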