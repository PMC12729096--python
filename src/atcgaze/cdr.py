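"""Conflict detection & resolution: separation checking, conflict outcome
records, and the solver / non-solver statistics.

En route safety requires at least 1,000 ft vertical *or* 5 NM lateral
separation between any aircraft pair; a loss of separation occurs when both
margins are infringed simultaneously (strict inequalities, since safety is
defined as "at least" the minima).  A scripted conflict counts as *solved*
when, after applying the controller's clearances to the trajectories, no
loss of separation occurs at any 1 s grid time during the scenario.

The group statistics mirror standard practice for small behavioral samples:
Mann-Whitney U for solver vs. non-solver contrasts and a forward-stepwise
(score-test entry, Wald removal) binomial logistic regression with McFadden
pseudo-R2 and VIF collinearity diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .aoi import DynamicAOISpec, assign_fixations_dynamic, \
    cumulative_fixation_time, sector_entry_time
from .events import Fixation
from .scenario import ConflictSpec, Scenario, Trajectory

__all__ = [
    "SeparationStandard", "Intervention", "ConflictRecord", "LogisticResult",
    "separation", "apply_interventions", "check_separation", "classify_solver",
    "conflict_variables", "mann_whitney", "vif", "forward_stepwise_logistic",
]


@dataclass(frozen=True)
class SeparationStandard:
    lateral_min_nm: float = 5.0
    vertical_min_ft: float = 1000.0

    def __post_init__(self) -> None:
        if self.lateral_min_nm <= 0 or self.vertical_min_ft <= 0:
            raise ValueError("separation minima must be > 0")


@dataclass(frozen=True)
class Intervention:
    """A controller clearance: altitude (ft), speed (kn), or an accept action."""

    t_s: float
    flight: str
    kind: str  # altitude | speed | accept
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("altitude", "speed", "accept"):
            raise ValueError(f"unknown intervention kind {self.kind!r}")
        if self.kind in ("altitude", "speed") and (self.value is None or self.value <= 0):
            raise ValueError(f"{self.kind} clearance needs a positive value")


def separation(a_state, b_state) -> tuple[float, float]:
    """(lateral NM, vertical ft) between two aircraft states (x_nm, y_nm, alt_ft)."""
    ax, ay, aalt = a_state
    bx, by, balt = b_state
    return float(np.hypot(ax - bx, ay - by)), float(abs(aalt - balt))


def apply_interventions(trajectories: dict[str, Trajectory],
                        interventions: list[Intervention],
                        climb_rate_ft_min: float = 1500.0) -> dict[str, Trajectory]:
    """Return trajectories with all clearances applied in time order.

    Altitude clearances level the aircraft toward the cleared level at the
    configured climb/descent rate; speed clearances scale the along-track
    ground speed.  Two clearances of the same kind at the same instant on one
    flight are contradictory and rejected.
    """
    seen: set[tuple[str, str, float]] = set()
    for iv in interventions:
        key = (iv.flight, iv.kind, iv.t_s)
        if key in seen:
            raise ValueError(f"contradictory {iv.kind} clearances on {iv.flight} "
                             f"at t={iv.t_s}")
        seen.add(key)
    out = dict(trajectories)
    for iv in sorted(interventions, key=lambda i: i.t_s):
        if iv.flight not in out:
            raise ValueError(f"intervention names unknown flight {iv.flight!r}")
        if iv.kind == "altitude":
            out[iv.flight] = out[iv.flight].with_altitude_clearance(
                iv.t_s, iv.value, rate_ft_min=climb_rate_ft_min)
        elif iv.kind == "speed":
            out[iv.flight] = out[iv.flight].with_speed_clearance(iv.t_s, iv.value)
    return out


def check_separation(scenario: Scenario,
                     interventions: list[Intervention] | None = None,
                     standard: SeparationStandard | None = None,
                     grid_s: float = 1.0,
                     pairs: list[tuple[str, str]] | None = None,
                     climb_rate_ft_min: float = 1500.0) -> float | None:
    """Earliest grid time with a simultaneous lateral+vertical infringement.

    Clearances are applied to the trajectories before checking.  ``pairs``
    restricts the scan (e.g. to one scripted conflict); by default every
    aircraft pair is checked.  Returns None when separation holds throughout.
    """
    standard = standard or SeparationStandard()
    trajs = apply_interventions(scenario.trajectories, interventions or [],
                                climb_rate_ft_min=climb_rate_ft_min)
    t = np.arange(0.0, scenario.duration_s + grid_s / 2, grid_s)
    names = list(trajs)
    xs, ys, alts = {}, {}, {}
    for name in names:
        xs[name], ys[name] = trajs[name].position_at(t)
        alts[name] = trajs[name].altitude_at(t)
    if pairs is None:
        pairs = [(names[i], names[j]) for i in range(len(names))
                 for j in range(i + 1, len(names))]
    first = None
    for a, b in pairs:
        lat = np.hypot(xs[a] - xs[b], ys[a] - ys[b])
        vert = np.abs(alts[a] - alts[b])
        hit = np.flatnonzero((lat < standard.lateral_min_nm)
                             & (vert < standard.vertical_min_ft))
        if hit.size:
            tv = float(t[hit[0]])
            if first is None or tv < first:
                first = tv
    return first


def classify_solver(scenario: Scenario,
                    interventions: list[Intervention] | None = None,
                    standard: SeparationStandard | None = None,
                    pairs: list[tuple[str, str]] | None = None,
                    grid_s: float = 1.0) -> bool:
    """True when no loss of separation occurs with the clearances applied."""
    return check_separation(scenario, interventions, standard,
                            grid_s=grid_s, pairs=pairs) is None


@dataclass
class ConflictRecord:
    """Per-participant outcome and tallies for one scripted conflict."""

    conflict: str
    solved: bool
    fixation_time_s: dict[str, float]
    altitude_interventions: dict[str, int]
    speed_interventions: dict[str, int]
    time_to_accept_s: float | None = None

    @property
    def total_fixation_time_s(self) -> float:
        return float(sum(self.fixation_time_s.values()))

    @property
    def total_interventions(self) -> int:
        return int(sum(self.altitude_interventions.values())
                   + sum(self.speed_interventions.values()))

    def to_row(self) -> dict:
        row = {"conflict": self.conflict, "solved": self.solved,
               "total_time_s": self.total_fixation_time_s,
               "total_interventions": self.total_interventions,
               "time_to_accept_s": self.time_to_accept_s}
        for ac, v in self.fixation_time_s.items():
            row[f"time_{ac}_s"] = v
        for ac, v in self.altitude_interventions.items():
            row[f"altitude_{ac}"] = v
        for ac, v in self.speed_interventions.items():
            row[f"speed_{ac}"] = v
        return row


def conflict_variables(fixations: list[Fixation],
                       scenario: Scenario,
                       interventions: list[Intervention],
                       conflict: ConflictSpec,
                       spec: DynamicAOISpec | None = None,
                       standard: SeparationStandard | None = None,
                       entry_clipped: tuple[str, ...] = (),
                       sector=None) -> ConflictRecord:
    """Tabulate the conflict-window gaze and intervention variables.

    Cumulative fixation time per conflict aircraft runs from scenario onset
    (or from sector entry for flights named in ``entry_clipped``, which
    requires ``sector``) to the scripted violation time.  Intervention counts
    are split by kind and flight; an intervention naming a flight absent from
    the scenario is a validation error.
    """
    spec = spec or DynamicAOISpec()
    for iv in interventions:
        if iv.flight not in scenario.trajectories:
            raise ValueError(f"intervention log names unknown flight {iv.flight!r}")
    conflict_trajs = {ac: scenario.trajectories[ac] for ac in conflict.aircraft}
    labels = assign_fixations_dynamic(fixations, conflict_trajs, spec, scenario)
    t_end = conflict.scripted_violation_s
    fix_time = {}
    for ac in conflict.aircraft:
        t0 = 0.0
        if ac in entry_clipped:
            if sector is None:
                raise ValueError("entry_clipped requires the sector rectangle")
            t0 = sector_entry_time(scenario.trajectories[ac], scenario, sector)
        fix_time[ac] = cumulative_fixation_time(fixations, labels, ac, (t0, t_end))
    alt_counts = {ac: 0 for ac in conflict.aircraft}
    spd_counts = {ac: 0 for ac in conflict.aircraft}
    accept_t = None
    for iv in interventions:
        if iv.flight not in conflict.aircraft:
            continue
        if iv.kind == "altitude":
            alt_counts[iv.flight] += 1
        elif iv.kind == "speed":
            spd_counts[iv.flight] += 1
        elif accept_t is None or iv.t_s < accept_t:
            accept_t = iv.t_s
    solved = classify_solver(scenario, interventions, standard,
                             pairs=conflict.pairs())
    return ConflictRecord(conflict=conflict.name, solved=solved,
                          fixation_time_s=fix_time,
                          altitude_interventions=alt_counts,
                          speed_interventions=spd_counts,
                          time_to_accept_s=accept_t)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (exact for small untied samples, else
    tie-corrected normal approximation)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def vif(predictors: pd.DataFrame | np.ndarray) -> pd.Series:
    """Variance inflation factor per predictor (1 for a single predictor).

    Each predictor is regressed (with intercept) on the others;
    VIF = 1/(1-R2).  Perfect collinearity yields inf with a warning.
    """
    X = pd.DataFrame(predictors)
    if len(X) < 2:
        raise ValueError("need at least 2 observations")
    out = {}
    for col in X.columns:
        if X.shape[1] == 1:
            out[col] = 1.0
            continue
        others = sm.add_constant(X.drop(columns=[col]).to_numpy())
        fit = sm.OLS(X[col].to_numpy(), others).fit()
        r2 = min(fit.rsquared, 1.0)
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"predictor {col!r} perfectly collinear; VIF infinite",
                          stacklevel=2)
            out[col] = float("inf")
        else:
            out[col] = float(1.0 / (1.0 - r2))
    return pd.Series(out)


@dataclass
class LogisticResult:
    """Forward-stepwise logistic fit summary."""

    predictors: list[str]
    coefficients: dict[str, float]
    intercept: float
    steps: list[dict] = field(default_factory=list)  # name, score_chi2, p, df
    mcfadden_r2: float = 0.0
    vif: dict[str, float] = field(default_factory=dict)
    separation_warning: bool = False


def _fit_logit(y, X) -> tuple:
    """Logit fit that survives (quasi-)complete separation.

    Falls back from Newton to BFGS and finally to a weak ridge penalty;
    returns (fit, separation_flag)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            try:
                fit = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=500)
            except Exception:
                fit = sm.Logit(y, X).fit_regularized(
                    disp=0, alpha=1e-4, L1_wt=0.0, maxiter=500)
    flagged = (not fit.mle_retvals.get("converged", True)
               if hasattr(fit, "mle_retvals") else True)
    # huge slopes or a near-saturated likelihood indicate (quasi-)separation
    flagged = flagged or bool(np.any(np.abs(np.asarray(fit.params)) > 15))
    p = np.clip(np.asarray(fit.predict(X)), 1e-12, 1 - 1e-12)
    flagged = flagged or bool(np.all((p > 0.999) == (np.asarray(y) > 0.5)))
    return fit, flagged


def _score_test(y, X_current, candidate):
    """Rao score (Lagrange-multiplier) test for adding one predictor."""
    n = y.size
    Xc = np.column_stack([np.ones(n)] + X_current)
    fit, _ = _fit_logit(y, Xc)
    p = fit.predict(Xc)
    Xa = np.column_stack([Xc, candidate])
    u = Xa.T @ (y - p)
    w = p * (1 - p)
    info = (Xa * w[:, None]).T @ Xa
    try:
        chi2 = float(u @ np.linalg.solve(info, u))
    except np.linalg.LinAlgError:
        return 0.0, 1.0
    if not np.isfinite(chi2):
        return 0.0, 1.0
    chi2 = max(chi2, 0.0)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def forward_stepwise_logistic(predictors: pd.DataFrame, outcome,
                              entry_p: float = 0.05, removal_p: float = 0.10,
                              max_steps: int = 25) -> LogisticResult:
    """SPSS-style forward-stepwise (Wald) binomial logistic regression.

    At each step the candidate with the smallest score-test p <= ``entry_p``
    enters; after every entry, any included predictor whose Wald p >=
    ``removal_p`` is removed.  Reports per-entry score chi-square, McFadden
    R2 = 1 - lnL/lnL0 for the final model, and VIF over the selected set.
    Quasi-complete separation is flagged rather than raised.
    """
    X = pd.DataFrame(predictors).astype(float)
    y = np.asarray(outcome, float)
    if X.shape[1] < 1:
        raise ValueError("need at least one predictor")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")

    included: list[str] = []
    steps: list[dict] = []
    sep_warn = False
    for _ in range(max_steps):
        remaining = [c for c in X.columns if c not in included]
        if not remaining:
            break
        best = None
        for cand in remaining:
            chi2, p = _score_test(y, [X[c].to_numpy() for c in included],
                                  X[cand].to_numpy())
            if best is None or p < best[2]:
                best = (cand, chi2, p)
        if best is None or best[2] > entry_p:
            break
        included.append(best[0])
        steps.append({"name": best[0], "score_chi2": best[1], "p": best[2], "df": 1})
        # backward Wald removal pass
        while included:
            Xm = sm.add_constant(X[included].to_numpy())
            fit, flagged = _fit_logit(y, Xm)
            sep_warn = sep_warn or flagged
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                wald_p = np.nan_to_num(np.asarray(fit.pvalues)[1:], nan=0.0)
            worst = int(np.argmax(wald_p))
            if wald_p[worst] >= removal_p and len(included) > 1:
                removed = included.pop(worst)
                steps.append({"name": removed, "score_chi2": float("nan"),
                              "p": float(wald_p[worst]), "df": 1,
                              "removed": True})
            else:
                break

    # final fit (intercept-only when nothing entered)
    Xm = sm.add_constant(X[included].to_numpy()) if included \
        else np.ones((y.size, 1))
    fit, flagged = _fit_logit(y, Xm)
    sep_warn = sep_warn or flagged
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null = sm.Logit(y, np.ones((y.size, 1))).fit(disp=0)
    r2 = float(1.0 - fit.llf / null.llf) if null.llf != 0 else 0.0
    coeffs = {name: float(b) for name, b in zip(included, np.asarray(fit.params)[1:])}
    vifs = vif(X[included]).to_dict() if included else {}
    return LogisticResult(predictors=included, coefficients=coeffs,
                          intercept=float(fit.params[0]), steps=steps,
                          mcfadden_r2=max(r2, 0.0), vif=vifs,
                          separation_warning=sep_warn)
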