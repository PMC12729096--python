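"""End-to-end orchestration: simulate -> detect -> AOI -> statistics.

`analyze_cohort` runs the full analysis over a (lazily generated) synthetic
cohort and returns tidy tables; `workload_statistics` and `cdr_statistics`
compute the condition-level and solver/non-solver inferential results.  The
CLI wraps these with file IO; library users call them directly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .aoi import DynamicAOISpec, build_static_aois
from .cdr import (SeparationStandard, conflict_variables, forward_stepwise_logistic,
                  mann_whitney)
from .events import DetectionParams, detect_blinks, detect_fixations
from .geometry import ScreenGeometry
from .simulate import CohortParams, cohort_scenarios, iter_cohort_sessions
from .workload import (rm_anova_2x3, session_metrics,
                       spearman_condition_matrix)

__all__ = [
    "PipelineConfig", "analyze_cohort", "workload_statistics",
    "cdr_statistics", "run_pipeline",
]

WORKLOAD_METRICS = ["pupil_mean_mm", "blink_count", "blink_mean_ms",
                    "fix_time_sector_s", "fix_time_out_of_sector_s",
                    "fix_time_sheet_s", "isa_mean", "nasa_sum"]


@dataclass
class PipelineConfig:
    """Validated run configuration (YAML-loadable)."""

    seed: int = 0
    out_dir: str = "results"
    n_participants: int = 24
    geometry: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    dynamic_aoi: dict = field(default_factory=dict)
    separation: dict = field(default_factory=dict)
    stepwise_entry_p: float = 0.05
    stepwise_removal_p: float = 0.10

    def build(self) -> tuple[ScreenGeometry, DetectionParams, DynamicAOISpec,
                             SeparationStandard]:
        """Instantiate (and thereby validate) the stage parameter objects."""
        return (ScreenGeometry(**self.geometry),
                DetectionParams(**self.detection),
                DynamicAOISpec(**self.dynamic_aoi),
                SeparationStandard(**self.separation))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.build()
        return cfg

    @property
    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def analyze_cohort(params: CohortParams | None = None, seed: int = 0,
                   detection: DetectionParams | None = None,
                   geometry: ScreenGeometry | None = None,
                   dynamic_aoi: DynamicAOISpec | None = None,
                   standard: SeparationStandard | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run detection, AOI accounting and conflict tabulation over a cohort.

    Returns ``(metrics, conflicts)``: one row per participant x condition in
    ``metrics``; one row per participant x scripted conflict in ``conflicts``
    (from the conflict-bearing scenario only).  Sessions are generated
    lazily so a full 24 x 6 cohort never resides in memory at once.
    """
    params = params or CohortParams()
    detection = detection or DetectionParams()
    geometry = geometry or ScreenGeometry(sampling_rate_hz=params.sampling_rate_hz)
    dynamic_aoi = dynamic_aoi or DynamicAOISpec()
    standard = standard or SeparationStandard()
    aois = build_static_aois(geometry)
    metric_rows = []
    conflict_rows = []
    scenarios = cohort_scenarios(params, seed)
    for sess in iter_cohort_sessions(params, seed, scenarios):
        blinks = detect_blinks(sess.stream, detection)
        fixations = detect_fixations(sess.stream, detection, geometry)
        sm = session_metrics(sess.stream, blinks, fixations, aois,
                             sess.scores, sess.condition)
        metric_rows.append(sm.to_row())
        # conflict tabulation only for the conflict-bearing scenario
        if sess.condition.traffic == 12 and sess.condition.complexity == "high":
            scen = scenarios[sess.condition.label]
            for conflict in scen.conflicts:
                clipped = ("HYG532",) if conflict.name == "easy" else ()
                rec = conflict_variables(
                    fixations, scen, sess.interventions, conflict,
                    spec=dynamic_aoi, standard=standard,
                    entry_clipped=clipped, sector=aois.sector)
                row = rec.to_row()
                row["participant"] = sess.participant_id
                row["solver_truth"] = sess.solver[conflict.name]
                conflict_rows.append(row)
    return pd.DataFrame(metric_rows), pd.DataFrame(conflict_rows)


def workload_statistics(metrics: pd.DataFrame) -> dict:
    """RM-ANOVAs per workload metric plus the condition-mean Spearman matrix."""
    out: dict = {"anova": {}, "spearman": {}}
    for metric in WORKLOAD_METRICS:
        if metric not in metrics.columns:
            continue
        table = metrics.rename(columns={metric: "value"})[
            ["participant", "traffic", "complexity", "value"]]
        if table["value"].isna().any():
            # e.g. blink mean duration for zero-blink sessions: listwise drop
            keep = table.groupby("participant")["value"].transform(
                lambda s: s.notna().all())
            table = table[keep]
        try:
            res = rm_anova_2x3(table)
        except ValueError:
            continue
        out["anova"][metric] = {
            eff: {"F": r.F, "df1": r.df1, "df2": r.df2, "p": r.p,
                  "eta_p_sq": r.eta_p_sq, "hf_epsilon": r.hf_epsilon}
            for eff, r in res.items()}
    cond_means = metrics.groupby(["traffic", "complexity"])[
        [m for m in WORKLOAD_METRICS if m in metrics.columns]].mean()
    rho, pval, _ = spearman_condition_matrix(cond_means)
    out["spearman"] = {"rho": rho.to_dict(), "p": pval.to_dict()}
    return out


def cdr_statistics(conflicts: pd.DataFrame, conflict_name: str,
                   entry_p: float = 0.05, removal_p: float = 0.10) -> dict:
    """Solver vs non-solver contrasts and stepwise logistic inference."""
    sub = conflicts[conflicts["conflict"] == conflict_name].copy()
    if sub.empty:
        raise ValueError(f"no records for conflict {conflict_name!r}")
    solved = sub[sub["solved"]]
    unsolved = sub[~sub["solved"]]
    variables = [c for c in sub.columns
                 if c.startswith(("time_", "altitude_", "speed_"))
                 or c in ("total_time_s", "total_interventions")]
    variables = [v for v in variables if v != "time_to_accept_s"
                 and sub[v].notna().all()]
    tests = {}
    for v in variables:
        if solved.empty or unsolved.empty or sub[v].nunique() < 2:
            continue
        U, p = mann_whitney(solved[v], unsolved[v])
        tests[v] = {"U": U, "p": p,
                    "mean_solved": float(solved[v].mean()),
                    "mean_unsolved": float(unsolved[v].mean())}
    significant = [v for v, t in tests.items() if t["p"] < 0.05]
    result = {"n_solved": int(len(solved)), "n_unsolved": int(len(unsolved)),
              "mann_whitney": tests, "stepwise": None}
    if significant and len(solved) and len(unsolved):
        fit = forward_stepwise_logistic(sub[significant],
                                        sub["solved"].astype(float),
                                        entry_p=entry_p, removal_p=removal_p)
        result["stepwise"] = {
            "predictors": fit.predictors,
            "coefficients": fit.coefficients,
            "steps": fit.steps,
            "mcfadden_r2": fit.mcfadden_r2,
            "vif": fit.vif,
            "separation_warning": fit.separation_warning,
        }
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate a cohort, analyze it, and write the report bundle.

    Deterministic for a given config: every output names the config hash and
    reruns are byte-identical.  Returns the paths written.
    """
    geometry, detection, dyn_aoi, standard = config.build()
    params = CohortParams(n_participants=config.n_participants,
                          sampling_rate_hz=geometry.sampling_rate_hz)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics, conflicts = analyze_cohort(params, config.seed, detection,
                                        geometry, dyn_aoi, standard)
    tag = config.digest
    paths = {}
    paths["metrics"] = out / f"metrics_{tag}.csv"
    metrics.to_csv(paths["metrics"], index=False)
    paths["conflicts"] = out / f"conflicts_{tag}.csv"
    conflicts.to_csv(paths["conflicts"], index=False)
    stats = {"workload": workload_statistics(metrics)}
    if not conflicts.empty:
        stats["cdr"] = {name: cdr_statistics(conflicts, name,
                                             config.stepwise_entry_p,
                                             config.stepwise_removal_p)
                        for name in conflicts["conflict"].unique()}
    paths["statistics"] = out / f"statistics_{tag}.json"
    paths["statistics"].write_text(json.dumps(stats, indent=2, default=float))
    log = {"config": asdict(config), "config_hash": tag,
           "n_sessions": int(len(metrics))}
    paths["run_log"] = out / f"run_{tag}.json"
    paths["run_log"].write_text(json.dumps(log, indent=2))
    return {k: str(v) for k, v in paths.items()}
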