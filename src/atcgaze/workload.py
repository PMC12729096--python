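"""Session-level mental-workload indices and their condition statistics.

Each participant x condition session yields a :class:`SessionMetrics` bundle:
mean pupil diameter, blink count and mean blink duration, fixation time and
count per static AOI, the mean of the eight in-task ISA ratings (1-7), the
raw NASA-TLX sum of six components (6-120), and mean head distance.

Condition effects are tested with 2 (traffic: 6 vs 12 aircraft) x
3 (complexity: low/medium/high) repeated-measures ANOVAs.  Sphericity is
assessed per effect with Mauchly's test on the orthonormal contrast scores;
when violated (p < .05) the Huynh-Feldt epsilon rescales the degrees of
freedom.  Partial eta squared is reported per effect.  Significant effects
are followed by Bonferroni-adjusted paired comparisons, and Spearman rank
correlations relate the six condition means of the ocular indices to the
subjective workload scales.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aoi import StaticAOIs
from .events import Blink, Fixation, blink_stats, pupil_mean
from .io import GazeStream

__all__ = [
    "Condition", "CONDITIONS", "SubjectiveScores", "SessionMetrics",
    "AnovaResult", "isa_mean", "nasa_tlx_sum", "session_metrics",
    "rm_anova_2x3", "bonferroni_pairwise", "spearman_condition_matrix",
]

COMPLEXITY_LEVELS = ("low", "medium", "high")
TRAFFIC_LEVELS = (6, 12)


@dataclass(frozen=True)
class Condition:
    """One cell of the 2 (traffic) x 3 (complexity) within-subject design."""

    traffic: int
    complexity: str

    def __post_init__(self) -> None:
        if self.traffic not in TRAFFIC_LEVELS:
            raise ValueError(f"traffic must be one of {TRAFFIC_LEVELS}")
        if self.complexity not in COMPLEXITY_LEVELS:
            raise ValueError(f"complexity must be one of {COMPLEXITY_LEVELS}")

    @property
    def label(self) -> str:
        return f"{self.traffic}-{self.complexity}"


CONDITIONS: tuple[Condition, ...] = tuple(
    Condition(t, c) for t in TRAFFIC_LEVELS for c in COMPLEXITY_LEVELS)


@dataclass(frozen=True)
class SubjectiveScores:
    """Eight ISA ratings (1-7) and six NASA-TLX components (1-20)."""

    isa_ratings: tuple[int, ...]
    nasa_components: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.isa_ratings) != 8:
            raise ValueError("exactly 8 ISA ratings required (one per 2 min)")
        if any(not 1 <= r <= 7 for r in self.isa_ratings):
            raise ValueError("ISA ratings must lie in [1, 7]")
        if len(self.nasa_components) != 6:
            raise ValueError("exactly 6 NASA-TLX components required")
        if any(not 1 <= c <= 20 for c in self.nasa_components):
            raise ValueError("NASA-TLX components must lie in [1, 20]")


def isa_mean(ratings) -> float:
    """Mean of the eight per-scenario ISA ratings."""
    ratings = tuple(ratings)
    if len(ratings) != 8 or any(not 1 <= r <= 7 for r in ratings):
        raise ValueError("need exactly 8 ratings in [1, 7]")
    return float(np.mean(ratings))


def nasa_tlx_sum(components) -> int:
    """Raw NASA-TLX sum over the six components (range 6-120)."""
    components = tuple(components)
    if len(components) != 6 or any(not 1 <= c <= 20 for c in components):
        raise ValueError("need exactly 6 components in [1, 20]")
    return int(np.sum(components))


@dataclass
class SessionMetrics:
    """All workload indices for one participant x condition session."""

    participant_id: str
    condition: Condition
    pupil_mean_mm: float
    blink_count: int
    blink_mean_ms: float
    fixation_time_s: dict[str, float]
    fixation_count: dict[str, int]
    isa_mean: float
    nasa_sum: int
    head_distance_mean_cm: float = float("nan")

    def to_row(self) -> dict:
        row = {
            "participant": self.participant_id,
            "traffic": self.condition.traffic,
            "complexity": self.condition.complexity,
            "pupil_mean_mm": self.pupil_mean_mm,
            "blink_count": self.blink_count,
            "blink_mean_ms": self.blink_mean_ms,
            "isa_mean": self.isa_mean,
            "nasa_sum": self.nasa_sum,
            "head_distance_mean_cm": self.head_distance_mean_cm,
        }
        for label in ("sector", "out_of_sector", "sheet"):
            row[f"fix_time_{label}_s"] = self.fixation_time_s.get(label, 0.0)
            row[f"fix_count_{label}"] = self.fixation_count.get(label, 0)
        return row


def session_metrics(stream: GazeStream, blinks: list[Blink],
                    fixations: list[Fixation], aois: StaticAOIs,
                    scores: SubjectiveScores, condition: Condition) -> SessionMetrics:
    """Assemble the per-session workload indices over the full record."""
    count, mean_ms = blink_stats(blinks)
    fix_time = {label: 0.0 for label in aois.labels}
    fix_count = {label: 0 for label in aois.labels}
    if fixations:
        labels = aois.classify(
            np.array([f.centroid_x_cm for f in fixations]),
            np.array([f.centroid_y_cm for f in fixations]))
        durations = np.array([f.duration_ms for f in fixations]) / 1000.0
        for label in aois.labels:
            m = labels == label
            fix_time[label] = float(durations[m].sum())
            fix_count[label] = int(m.sum())
    head = float("nan")
    if stream.eye_distance_cm is not None:
        head = float(np.nanmean(stream.eye_distance_cm))
    return SessionMetrics(
        participant_id=stream.participant_id,
        condition=condition,
        pupil_mean_mm=pupil_mean(stream),
        blink_count=count,
        blink_mean_ms=mean_ms,
        fixation_time_s=fix_time,
        fixation_count=fix_count,
        isa_mean=isa_mean(scores.isa_ratings),
        nasa_sum=nasa_tlx_sum(scores.nasa_components),
        head_distance_mean_cm=head,
    )


@dataclass
class AnovaResult:
    """One within-subject effect from the 2 x 3 repeated-measures ANOVA."""

    effect: str
    F: float
    df1: float
    df2: float
    p: float
    eta_p_sq: float
    hf_epsilon: float | None = None
    mauchly_p: float | None = None


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast rows (via QR of centered identity)."""
    q, _ = np.linalg.qr(np.eye(k) - 1.0 / k)
    return q.T[:k - 1]


def _sphericity(Y: np.ndarray) -> tuple[float, float, float]:
    """(mauchly_p, gg_epsilon, hf_epsilon) from an n x k score matrix."""
    n, k = Y.shape
    C = _orthonormal_contrasts(k)
    S = np.cov(Y.T, ddof=1)
    M = C @ S @ C.T
    d = k - 1
    tr = np.trace(M)
    eps_gg = tr ** 2 / (d * np.sum(M ** 2)) if np.sum(M ** 2) > 0 else 1.0
    denom = d * (n - 1 - d * eps_gg)
    eps_hf = min(1.0, (n * d * eps_gg - 2) / denom) if denom > 0 else 1.0
    # Mauchly's W with the standard chi-square approximation
    eig = np.linalg.eigvalsh(M)
    if np.any(eig <= 1e-12):
        return 0.0, eps_gg, eps_hf
    W = np.prod(eig) / (tr / d) ** d
    f = 1 - (2 * d ** 2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * np.log(W)
    df = d * (d + 1) // 2 - 1
    return float(stats.chi2.sf(chi2, df)), float(eps_gg), float(eps_hf)


def _effect(name, ss_eff, df1, ss_err, df2, scores=None,
            mauchly_alpha=0.05) -> AnovaResult:
    if ss_eff <= 0 or ss_err < 0:
        return AnovaResult(name, 0.0, df1, df2, 1.0, 0.0)
    F = (ss_eff / df1) / (ss_err / df2) if ss_err > 0 else float("inf")
    eps = None
    mauchly_p = None
    adj1, adj2 = df1, df2
    if scores is not None and scores.shape[1] > 2:
        mauchly_p, _, eps_hf = _sphericity(scores)
        if mauchly_p < mauchly_alpha:
            eps = eps_hf
            adj1, adj2 = df1 * eps_hf, df2 * eps_hf
    p = float(stats.f.sf(F, adj1, adj2)) if np.isfinite(F) else 0.0
    eta = float(ss_eff / (ss_eff + ss_err))
    return AnovaResult(name, float(F), adj1, adj2, p, eta,
                       hf_epsilon=eps, mauchly_p=mauchly_p)


def rm_anova_2x3(table: pd.DataFrame, dv: str = "value",
                 subject: str = "participant", traffic: str = "traffic",
                 complexity: str = "complexity") -> dict[str, AnovaResult]:
    """Two-way within-subject ANOVA on a complete balanced 2 x 3 table.

    ``table`` is long-format with one row per participant x condition.
    Missing or duplicated cells raise (no imputation is attempted).
    Returns results keyed ``traffic``, ``complexity``, ``interaction``.
    """
    df = table[[subject, traffic, complexity, dv]].dropna()
    piv = df.pivot_table(index=subject, columns=[traffic, complexity],
                        values=dv, aggfunc="count")
    expected = [(t, c) for t in TRAFFIC_LEVELS for c in COMPLEXITY_LEVELS]
    if piv.shape[1] != 6 or not piv.notna().all().all() or (piv != 1).any().any():
        raise ValueError("need a complete balanced table: one observation per "
                         "participant in each of the 6 cells")
    if piv.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    wide = df.pivot_table(index=subject, columns=[traffic, complexity], values=dv)
    y = np.stack([wide[(t, c)].to_numpy() for t, c in expected], axis=1)
    n = y.shape[0]
    y = y.reshape(n, 2, 3)

    grand = y.mean()
    mean_a = y.mean(axis=(0, 2))        # traffic
    mean_b = y.mean(axis=(0, 1))        # complexity
    mean_ab = y.mean(axis=0)
    mean_s = y.mean(axis=(1, 2))
    mean_as = y.mean(axis=2)
    mean_bs = y.mean(axis=1)

    ss_a = 3 * n * np.sum((mean_a - grand) ** 2)
    ss_b = 2 * n * np.sum((mean_b - grand) ** 2)
    ss_ab = n * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    ss_s = 6 * np.sum((mean_s - grand) ** 2)
    ss_as = 3 * np.sum((mean_as - mean_a[None, :] - mean_s[:, None] + grand) ** 2)
    ss_bs = 2 * np.sum((mean_bs - mean_b[None, :] - mean_s[:, None] + grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_abs = ss_tot - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs

    b_scores = y.mean(axis=1)           # n x 3, collapsed over traffic
    ab_scores = y[:, 0, :] - y[:, 1, :]  # n x 3 traffic difference
    return {
        "traffic": _effect("traffic", ss_a, 1, ss_as, n - 1),
        "complexity": _effect("complexity", ss_b, 2, ss_bs, 2 * (n - 1),
                              scores=b_scores),
        "interaction": _effect("interaction", ss_ab, 2, ss_abs, 2 * (n - 1),
                               scores=ab_scores),
    }


def bonferroni_pairwise(table: pd.DataFrame, factor: str, dv: str = "value",
                        subject: str = "participant") -> pd.DataFrame:
    """Bonferroni-adjusted paired t comparisons between the factor's levels.

    The other design factor is collapsed by per-participant means before
    pairing.  Adjusted p = raw p x number of comparisons, capped at 1; a
    comparison of identical level profiles reports p = 1.
    """
    collapsed = table.groupby([subject, factor])[dv].mean().reset_index()
    levels = list(pd.unique(collapsed[factor]))
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        wa = collapsed[collapsed[factor] == a].set_index(subject)[dv]
        wb = collapsed[collapsed[factor] == b].set_index(subject)[dv]
        common = wa.index.intersection(wb.index)
        diff = wa.loc[common] - wb.loc[common]
        if np.allclose(diff, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(wa.loc[common], wb.loc[common])
        rows.append({"level_a": a, "level_b": b, "t": float(t),
                     "p_raw": float(p), "p_bonf": float(min(1.0, p * m)),
                     "mean_diff": float(diff.mean())})
    return pd.DataFrame(rows)


def spearman_condition_matrix(condition_means: pd.DataFrame,
                              alpha: float = 0.05
                              ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Spearman rho between all variable pairs over the condition means.

    ``condition_means`` has one row per condition (six in the full design)
    and one column per variable.  Returns (rho, p) matrices and a dict of
    Fisher-z confidence intervals; constant variables yield NaN with a
    warning.
    """
    X = condition_means
    if len(X) < 3:
        raise ValueError("need at least 3 paired observations")
    cols = list(X.columns)
    rho = pd.DataFrame(np.nan, index=cols, columns=cols)
    pval = pd.DataFrame(np.nan, index=cols, columns=cols)
    cis = {}
    n = len(X)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    for a in cols:
        for b in cols:
            if X[a].nunique() < 2 or X[b].nunique() < 2:
                if a != b:
                    warnings.warn(f"constant variable in pair ({a}, {b}); "
                                  "rho undefined", stacklevel=2)
                continue
            r, p = stats.spearmanr(X[a], X[b])
            rho.loc[a, b] = r
            pval.loc[a, b] = p
            if a != b and n > 3 and abs(r) < 1:
                z = np.arctanh(r)
                se = 1.06 / np.sqrt(n - 3)  # Fieller-style SE for Spearman
                cis[(a, b)] = (float(np.tanh(z - zcrit * se)),
                               float(np.tanh(z + zcrit * se)))
    return rho, pval, cis
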