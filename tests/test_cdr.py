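"""Separation checking, conflict tabulation, and solver statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from atcgaze.cdr import (Intervention, SeparationStandard, check_separation,
                         classify_solver, conflict_variables,
                         forward_stepwise_logistic, mann_whitney, separation,
                         vif)
from atcgaze.events import Fixation
from atcgaze.scenario import Scenario, Trajectory
from atcgaze.simulate import default_viewport, generate_scenario
from atcgaze.workload import Condition


class TestSeparation:
    def test_identical_states(self):
        assert separation((0, 0, 30_000), (0, 0, 30_000)) == (0.0, 0.0)

    def test_pythagorean_triangle(self):
        lat, vert = separation((0, 0, 30_000), (3, 4, 30_000))
        assert lat == pytest.approx(5.0) and vert == 0.0

    def test_colocated_vertical(self):
        assert separation((10, 10, 30_000), (10, 10, 31_500)) == (0.0, 1500.0)


def head_on_scenario(gap_nm, v_kn, alt_a=30_000, alt_b=30_000,
                     duration=960.0):
    a = Trajectory.straight("AAA111", 0.0, 40.0, 90.0, v_kn, alt_a,
                            duration_s=duration)
    b = Trajectory.straight("BBB222", gap_nm, 40.0, 270.0, v_kn, alt_b,
                            duration_s=duration)
    return Scenario(traffic=2, complexity="low",
                    trajectories={"AAA111": a, "BBB222": b},
                    viewport=default_viewport(), duration_s=duration)


class TestCheckSeparation:
    def test_head_on_closed_form(self):
        # gap 60 NM closed at 2v = 800 kn: below 5 NM after (55/800) h
        scen = head_on_scenario(60.0, 400.0)
        t_closed_form = (60.0 - 5.0) / (2 * 400.0) * 3600.0
        t = check_separation(scen)
        assert t == pytest.approx(np.ceil(t_closed_form), abs=1.0)

    def test_vertical_separation_prevents_violation(self):
        scen = head_on_scenario(60.0, 400.0, alt_b=31_000)  # exactly 1000 ft
        assert check_separation(scen) is None

    def test_monotone_in_thresholds(self):
        scen = head_on_scenario(60.0, 400.0)
        t_base = check_separation(scen, standard=SeparationStandard())
        t_wide = check_separation(
            scen, standard=SeparationStandard(lateral_min_nm=8.0))
        assert t_wide <= t_base

    def test_packaged_easy_pair_and_clearance(self):
        scen = generate_scenario(Condition(12, "high"), seed=0)
        easy = next(c for c in scen.conflicts if c.name == "easy")
        assert check_separation(scen, pairs=easy.pairs()) == 140.0
        fix = [Intervention(80.0, "HYG532", "altitude", 27_800.0)]
        assert check_separation(scen, fix, pairs=easy.pairs()) is None
        assert classify_solver(scen, fix, pairs=easy.pairs())

    def test_post_hoc_clearance_cannot_change_outcome(self):
        scen = generate_scenario(Condition(12, "high"), seed=0)
        easy = next(c for c in scen.conflicts if c.name == "easy")
        late = [Intervention(400.0, "HYG532", "altitude", 27_800.0)]
        assert check_separation(scen, late, pairs=easy.pairs()) == 140.0

    def test_contradictory_clearances_rejected(self):
        scen = head_on_scenario(60.0, 400.0)
        both = [Intervention(10.0, "AAA111", "altitude", 31_000.0),
                Intervention(10.0, "AAA111", "altitude", 29_000.0)]
        with pytest.raises(ValueError, match="contradictory"):
            check_separation(scen, both)

    def test_conflict_free_geometry_is_solved(self):
        scen = head_on_scenario(60.0, 400.0, alt_b=35_000)
        assert classify_solver(scen)


class TestSpeedClearance:
    def test_speed_change_scales_track(self):
        traj = Trajectory.straight("AAA111", 0.0, 0.0, 90.0, 400.0, 30_000)
        slowed = traj.with_speed_clearance(100.0, 200.0)
        x0, _ = traj.position_at(100.0)
        x1, _ = slowed.position_at(200.0)
        # 100 s at 200 kn instead of 400 kn
        assert x1 - x0 == pytest.approx(200.0 / 3600.0 * 100.0, rel=1e-6)


def fix_at(x, y, start_ms, dur_ms):
    return Fixation(start_ms, start_ms + dur_ms, x, y,
                    max(int(dur_ms / 33.33), 1))


@pytest.fixture(scope="module")
def scen():
    return generate_scenario(Condition(12, "high"), seed=0)


class TestConflictVariables:

    def test_empty_log_zero_counts(self, scen):
        easy = scen.conflicts[0]
        rec = conflict_variables([], scen, [], easy)
        assert rec.total_interventions == 0
        assert rec.total_fixation_time_s == 0.0
        assert not rec.solved  # unresolved scripted conflict

    def test_single_altitude_clearance_counted(self, scen):
        easy = scen.conflicts[0]
        log = [Intervention(80.0, "HYG532", "altitude", 27_800.0)]
        rec = conflict_variables([], scen, log, easy)
        assert rec.altitude_interventions["HYG532"] == 1
        assert rec.total_interventions == 1
        assert rec.solved

    def test_fixation_time_tallied_on_tracked_aircraft(self, scen):
        easy = scen.conflicts[0]
        traj = scen.trajectories["POB456"]
        fixes = []
        for t0 in (40.0, 60.0, 80.0):
            x, y = scen.viewport.to_screen(*traj.position_at(t0))
            fixes.append(fix_at(x, y, t0 * 1000, 2_000.0))
        rec = conflict_variables(fixes, scen, [], easy)
        assert rec.fixation_time_s["POB456"] == pytest.approx(6.0, abs=0.2)

    def test_unknown_flight_rejected(self, scen):
        easy = scen.conflicts[0]
        with pytest.raises(ValueError, match="unknown flight"):
            conflict_variables([], scen, [Intervention(10.0, "ZZZ999",
                                                       "altitude", 30_000.0)],
                               easy)


def exhaustive_mw_p(a, b):
    """Two-sided permutation p-value for the Mann-Whitney U statistic."""
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_stat(x, y):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

    observed = u_stat(a, b)
    n_extreme = 0
    total = 0
    mid = len(a) * len(b) / 2
    for idx in itertools.combinations(range(len(pooled)), n_a):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        if abs(u - mid) >= abs(observed - mid) - 1e-9:
            n_extreme += 1
        total += 1
    return n_extreme / total


class TestMannWhitney:
    def test_complete_separation_extreme_u(self):
        a = list(range(100, 108))          # n = 8, all larger
        b = list(range(16))                # n = 16
        U, p = mann_whitney(a, b)
        assert U in (0.0, 128.0)
        assert p < 0.001

    def test_identical_groups(self):
        _, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed,na,nb", [(0, 4, 5), (1, 6, 6), (2, 8, 7),
                                            (3, 3, 8), (4, 5, 5)])
    def test_matches_exhaustive_permutation(self, seed, na, nb):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.8, 1, na)
        b = rng.normal(0, 1, nb)
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(exhaustive_mw_p(a, b), abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestVif:
    def test_single_predictor_is_one(self):
        assert vif(pd.DataFrame({"x": np.random.default_rng(0).normal(size=30)})
                   )["x"] == 1.0

    def test_orthogonal_pair_near_one(self):
        n = 2000
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        assert vif(X).max() < 1.05

    def test_correlation_09_closed_form(self):
        rng = np.random.default_rng(2)
        n = 100_000
        z = rng.normal(size=n)
        a = z
        b = 0.9 * z + np.sqrt(1 - 0.81) * rng.normal(size=n)
        got = vif(pd.DataFrame({"a": a, "b": b}))["a"]
        assert got == pytest.approx(1 / (1 - 0.81), rel=0.03)

    def test_collinear_flagged_infinite(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.warns(UserWarning, match="collinear"):
            assert np.isinf(vif(X)).all()


class TestStepwiseLogistic:
    def test_null_case_selects_nothing(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        y = rng.integers(0, 2, 200)
        res = forward_stepwise_logistic(X, y)
        assert res.mcfadden_r2 < 0.05
        assert len(res.predictors) <= 1

    def test_strong_predictor_selected_consistently(self):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 150
            signal_x = rng.normal(size=n)
            X = pd.DataFrame(rng.normal(size=(n, 6)),
                             columns=[f"noise{i}" for i in range(6)])
            X["signal"] = signal_x
            logit = 2.0 * signal_x
            y = rng.uniform(size=n) < 1 / (1 + np.exp(-logit))
            res = forward_stepwise_logistic(X, y.astype(float))
            hits += "signal" in res.predictors
        assert hits >= int(0.95 * n_seeds)

    def test_null_model_r2_zero(self):
        # a predictor that never enters leaves the intercept-only model
        y = np.array([0, 1] * 20, float)
        X = pd.DataFrame({"x": np.zeros(40) + np.arange(40) * 0})
        res = forward_stepwise_logistic(X + 1.0, y)
        assert res.predictors == [] and res.mcfadden_r2 == 0.0

    def test_separation_flagged_not_raised(self):
        y = np.array([0] * 10 + [1] * 10, float)
        X = pd.DataFrame({"perfect": np.concatenate([np.zeros(10), np.ones(10)])})
        res = forward_stepwise_logistic(X, y)
        assert res.separation_warning
        assert res.predictors == ["perfect"]

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            forward_stepwise_logistic(pd.DataFrame({"x": [1.0, 2.0]}),
                                      [1.0, 1.0])
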