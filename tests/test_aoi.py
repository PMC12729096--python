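"""Static partition, dynamic aircraft AOIs, and attention accounting."""

import numpy as np
import pytest

from atcgaze.aoi import (DynamicAOISpec, assign_fixation_dynamic,
                         assign_fixation_static, assign_fixations_dynamic,
                         build_static_aois, cumulative_fixation_time,
                         dynamic_aoi_at, sector_entry_time,
                         sliding_window_attention)
from atcgaze.events import Fixation
from atcgaze.geometry import ScreenGeometry, cm_to_visual_angle
from atcgaze.scenario import Scenario, Trajectory
from atcgaze.simulate import default_viewport


def fix_at(x, y, start_ms=0.0, dur_ms=300.0):
    return Fixation(start_ms=start_ms, end_ms=start_ms + dur_ms,
                    centroid_x_cm=x, centroid_y_cm=y,
                    n_samples=max(int(dur_ms / 33.33), 1))


@pytest.fixture
def aois(geometry):
    return build_static_aois(geometry)


class TestStaticAOIs:
    def test_sector_centered(self, aois):
        assert aois.sector.left_cm == pytest.approx((61.0 - 27.5) / 2)
        assert aois.sector.left_cm == pytest.approx(16.75)
        assert aois.sector.top_cm == pytest.approx(6.75)

    def test_sector_angular_size(self, aois, geometry):
        assert round(cm_to_visual_angle(aois.sector.width_cm,
                                        geometry.viewing_distance_cm), 2) == 25.81
        assert round(cm_to_visual_angle(aois.sector.height_cm,
                                        geometry.viewing_distance_cm), 2) == 19.39

    def test_sheet_flush_top_right(self, aois):
        assert aois.sheet.right_cm == pytest.approx(61.0)
        assert aois.sheet.top_cm == 0.0

    def test_classification_and_precedence(self, aois):
        assert assign_fixation_static(fix_at(30.5, 17.0), aois) == "sector"
        assert assign_fixation_static(fix_at(50.0, 3.0), aois) == "sheet"
        assert assign_fixation_static(fix_at(0.1, 0.1), aois) == "out_of_sector"
        assert assign_fixation_static(fix_at(-1.0, 5.0), aois) == "off_display"
        # sliver where sheet and sector rectangles overlap: sheet wins
        assert aois.sector.contains(44.1, 7.0) and aois.sheet.contains(44.1, 7.0)
        assert assign_fixation_static(fix_at(44.1, 7.0), aois) == "sheet"

    def test_boundary_closed_left_top_open_right_bottom(self, aois):
        s = aois.sector
        assert assign_fixation_static(fix_at(s.left_cm, s.top_cm + 1), aois) == "sector"
        assert assign_fixation_static(fix_at(s.right_cm, s.top_cm + 1), aois) \
            == "out_of_sector"

    def test_partition_covers_display(self, aois):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 61, 2000)
        y = rng.uniform(0, 34, 2000)
        labels = aois.classify(x, y)
        assert set(labels) <= {"sector", "out_of_sector", "sheet"}

    def test_too_small_display_rejected(self):
        with pytest.raises(ValueError):
            build_static_aois(ScreenGeometry(display_width_cm=20.0,
                                             display_height_cm=10.0))


def linear_scenario():
    """One aircraft crossing the sector eastbound, one stationary."""
    mover = Trajectory("MOV001", times_s=[0.0, 960.0], x_nm=[10.0, 90.0],
                       y_nm=[41.0, 41.0], alt_ft=[30_000, 30_000],
                       gs_kn=[300, 300])
    still = Trajectory("STI001", times_s=[0.0, 960.0], x_nm=[100.0, 100.0],
                       y_nm=[70.0, 70.0], alt_ft=[20_000, 20_000],
                       gs_kn=[0, 0])
    return Scenario(traffic=2, complexity="low",
                    trajectories={"MOV001": mover, "STI001": still},
                    viewport=default_viewport())


class TestDynamicAOIs:
    def test_stationary_aircraft_constant_rect(self):
        scen = linear_scenario()
        spec = DynamicAOISpec()
        r0 = dynamic_aoi_at(scen.trajectories["STI001"], 0.0, spec, scen)
        r1 = dynamic_aoi_at(scen.trajectories["STI001"], 500.0, spec, scen)
        assert (r0.left_cm, r0.top_cm) == (r1.left_cm, r1.top_cm)

    def test_linear_motion_interpolates_and_area_constant(self):
        scen = linear_scenario()
        spec = DynamicAOISpec(tag_offset_cm=(0.8, -0.6))
        rects = [dynamic_aoi_at(scen.trajectories["MOV001"], t, spec, scen)
                 for t in (0.0, 480.0, 960.0)]
        mid = (rects[0].left_cm + rects[2].left_cm) / 2
        assert rects[1].left_cm == pytest.approx(mid, abs=1e-9)
        areas = {round(r.width_cm * r.height_cm, 9) for r in rects}
        assert len(areas) == 1

    def test_tracking_matches_hand_rectangles_on_linear_path(self):
        # hand-computed: viewport maps 0.25 cm per NM, x_cm = 16.75 + 0.25 x_nm
        scen = linear_scenario()
        spec = DynamicAOISpec(width_cm=3.0, height_cm=2.0)
        for t in (0.0, 240.0, 960.0):
            x_nm = 10.0 + 80.0 * t / 960.0
            expect_cx = 16.75 + 0.25 * x_nm
            r = dynamic_aoi_at(scen.trajectories["MOV001"], t, spec, scen)
            assert abs((r.left_cm + r.width_cm / 2) - expect_cx) < 0.1

    def test_out_of_range_time(self):
        scen = linear_scenario()
        with pytest.raises(ValueError):
            dynamic_aoi_at(scen.trajectories["MOV001"], 1000.0,
                           DynamicAOISpec(), scen)

    def test_assignment_glued_far_and_majority(self):
        scen = linear_scenario()
        spec = DynamicAOISpec()
        vp = scen.viewport
        sx, sy = vp.to_screen(100.0, 70.0)
        assert assign_fixation_dynamic(fix_at(sx, sy, 0, 400),
                                       scen.trajectories, spec, scen) == "STI001"
        assert assign_fixation_dynamic(fix_at(2.0, 2.0, 0, 400),
                                       scen.trajectories, spec, scen) is None

    def test_majority_overlap_wins(self):
        # fixation tracks the mover for 70% of its span, then it drifts off
        scen = linear_scenario()
        spec = DynamicAOISpec(width_cm=3.0, height_cm=2.0)
        traj = scen.trajectories["MOV001"]
        vp = scen.viewport
        # position the centroid where the mover is at 70% of the fixation
        t0, dur = 100.0, 20.0
        x_nm, y_nm = traj.position_at(t0 + 0.2 * dur)
        cx, cy = vp.to_screen(x_nm, y_nm)
        fix = fix_at(cx, cy, t0 * 1000, dur * 1000)
        assert assign_fixation_dynamic(fix, scen.trajectories, spec, scen) \
            == "MOV001"

    def test_batch_matches_single(self):
        scen = linear_scenario()
        spec = DynamicAOISpec()
        rng = np.random.default_rng(3)
        fixes = [fix_at(rng.uniform(0, 61), rng.uniform(0, 34),
                        rng.uniform(0, 900) * 1000, 300.0) for _ in range(60)]
        single = [assign_fixation_dynamic(f, scen.trajectories, spec, scen)
                  for f in fixes]
        batch = assign_fixations_dynamic(fixes, scen.trajectories, spec, scen)
        assert batch == single


class TestCumulativeTime:
    def test_zero_without_assignments(self):
        assert cumulative_fixation_time([], [], "AAA111", (0, 100)) == 0.0

    def test_clipping_half_window(self):
        fix = fix_at(10, 10, start_ms=9_000, dur_ms=2_000)
        t = cumulative_fixation_time([fix], ["AAA111"], "AAA111", (0, 10))
        assert t == pytest.approx(1.0)

    def test_reconstructs_published_total(self):
        # fixture constructed to sum to the 18.29 s solver mean on the climber
        durations_ms = [4000, 3290, 5000, 6000]
        fixes = [fix_at(10, 10, start_ms=5_000 + 8_000 * i, dur_ms=d)
                 for i, d in enumerate(durations_ms)]
        labels = ["HYG532"] * 4
        total = cumulative_fixation_time(fixes, labels, "HYG532", (0, 140))
        assert total == pytest.approx(18.29)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            cumulative_fixation_time([], [], "A", (10, 10))


class TestSlidingWindow:
    def test_full_window_is_100_percent(self):
        fixes = [fix_at(10, 10, start_ms=0, dur_ms=30_000)]
        series = sliding_window_attention(fixes, ["A"], ["A"], 30_000.0)
        assert series.shares_pct["A"][0] == pytest.approx(100.0)

    def test_empty_window_is_zero(self):
        series = sliding_window_attention([], [], ["A"], 30_000.0)
        assert np.all(series.shares_pct["A"] == 0.0)

    def test_half_occupancy(self):
        fixes = [fix_at(10, 10, start_ms=0, dur_ms=5_000)]
        series = sliding_window_attention(fixes, ["A"], ["A"], 20_000.0)
        # at t = 10 s the trailing 10 s window holds 5 s of assigned time
        idx = np.argmin(np.abs(series.times_ms - 10_000.0))
        assert series.shares_pct["A"][idx] == pytest.approx(50.0, abs=1.0)

    def test_total_is_sum_when_disjoint(self):
        fixes = [fix_at(10, 10, 0, 4_000), fix_at(20, 20, 5_000, 4_000)]
        series = sliding_window_attention(fixes, ["A", "B"], ["A", "B"], 30_000.0)
        np.testing.assert_allclose(
            series.total_pct,
            series.shares_pct["A"] + series.shares_pct["B"])
        assert series.total_pct.max() <= 100.0 + 1e-9

    def test_record_shorter_than_window(self):
        with pytest.raises(ValueError, match="shorter"):
            sliding_window_attention([], [], ["A"], 5_000.0, window_ms=10_000.0)


class TestSectorEntry:
    def test_late_entrant_clipped_at_boundary(self, aois):
        scen = linear_scenario()
        # aircraft starting north of the sector, flying due south
        entrant = Trajectory("ENT001", times_s=[0.0, 960.0],
                             x_nm=[55.0, 55.0], y_nm=[95.0, 10.0],
                             alt_ft=[30_000, 30_000], gs_kn=[320, 320])
        scen.trajectories["ENT001"] = entrant
        t_entry = sector_entry_time(entrant, scen, aois.sector)
        # crosses y = 82 NM at t = 960 * 13/85
        assert t_entry == pytest.approx(960 * 13 / 85, abs=1.5)

    def test_never_entering_raises(self, aois):
        scen = linear_scenario()
        outsider = Trajectory("OUT001", times_s=[0.0, 960.0],
                              x_nm=[-40.0, -40.0], y_nm=[-20.0, -20.0],
                              alt_ft=[30_000, 30_000], gs_kn=[0, 0])
        with pytest.raises(ValueError, match="never enters"):
            sector_entry_time(outsider, scen, aois.sector)
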