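"""Blink-gap and dispersion-threshold fixation detection."""

import numpy as np
import pytest

from atcgaze.events import (DetectionParams, blink_stats, detect_blinks,
                            detect_fixations, detect_gaps, pupil_mean)
from atcgaze.geometry import visual_angle_to_cm

from conftest import PERIOD_MS, make_stream, random_walk_stream


def stream_with_gap(n_invalid: int, n_pad: int = 20):
    n = n_pad * 2 + n_invalid
    valid = np.ones(n, dtype=bool)
    valid[n_pad:n_pad + n_invalid] = False
    return make_stream(np.full(n, 10.0), np.full(n, 10.0), valid=valid)


class TestBlinks:
    def test_nine_sample_gap_is_one_300ms_blink(self):
        blinks = detect_blinks(stream_with_gap(9))
        assert len(blinks) == 1
        assert blinks[0].duration_ms == pytest.approx(9 * PERIOD_MS)
        assert blinks[0].duration_ms == pytest.approx(300.0, abs=0.1)

    def test_two_sample_gap_below_band(self):
        assert detect_blinks(stream_with_gap(2)) == []

    def test_nineteen_sample_gap_is_track_loss(self):
        blinks, losses = detect_gaps(stream_with_gap(19))
        assert blinks == []
        assert len(losses) == 1
        assert losses[0].duration_ms == pytest.approx(19 * PERIOD_MS)

    @pytest.mark.parametrize("n_invalid, expected", [
        (3, 1),    # 100 ms: lower edge inclusive
        (18, 1),   # 600 ms: upper edge inclusive
        (2, 0), (19, 0),
    ])
    def test_band_edges_inclusive(self, n_invalid, expected):
        assert len(detect_blinks(stream_with_gap(n_invalid))) == expected

    def test_one_eye_loss_is_not_a_blink(self):
        n = 40
        lv = np.ones(n, bool)
        lv[15:24] = False  # left eye only: not a simultaneous loss
        stream = make_stream(np.full(n, 10.0), np.full(n, 10.0),
                             left_valid=lv, right_valid=np.ones(n, bool))
        assert detect_blinks(stream) == []

    def test_padding_invariance(self):
        # an out-of-band invalid run appended/prepended never becomes a blink
        n = 100
        valid = np.ones(n, bool)
        valid[:25] = False   # 833 ms leading loss
        valid[40:49] = False  # genuine 300 ms blink
        valid[-30:] = False  # 1 s trailing loss
        stream = make_stream(np.full(n, 10.0), np.full(n, 10.0), valid=valid)
        blinks, losses = detect_gaps(stream)
        assert len(blinks) == 1 and len(losses) == 2
        assert blinks[0].start_ms == pytest.approx(40 * PERIOD_MS)

    def test_injected_gap_recovery_exact(self):
        # forty in-band gaps at known sites are recovered one for one
        rng = np.random.default_rng(42)
        n = 20_000
        valid = np.ones(n, bool)
        starts = np.arange(40) * 480 + 50
        true_durations = []
        for s in starts:
            ln = int(rng.integers(3, 19))  # 100-600 ms inclusive
            valid[s:s + ln] = False
            true_durations.append(ln * PERIOD_MS)
        stream = make_stream(np.full(n, 10.0), np.full(n, 10.0), valid=valid)
        blinks = detect_blinks(stream)
        assert len(blinks) == 40
        for b, d in zip(blinks, true_durations):
            assert abs(b.duration_ms - d) <= PERIOD_MS

    def test_empty_stream(self):
        stream = make_stream(np.empty(0), np.empty(0),
                             valid=np.empty(0, dtype=bool))
        assert detect_blinks(stream) == []


class TestBlinkStats:
    def test_empty(self):
        count, mean = blink_stats([])
        assert count == 0 and np.isnan(mean)

    def test_mean(self):
        b1 = detect_blinks(stream_with_gap(6))[0]   # 200 ms
        b2 = detect_blinks(stream_with_gap(12))[0]  # 400 ms
        count, mean = blink_stats([b1, b2])
        assert count == 2 and mean == pytest.approx(300.0)


def brute_force_idt(stream, params=None):
    """Independent oracle: greedy maximal windows, dispersion recomputed
    from scratch with a full pairwise-distance matrix at every step."""
    params = params or DetectionParams()
    thr = visual_angle_to_cm(params.fixation_dispersion_deg,
                             stream.geometry.viewing_distance_cm)
    min_len = int(np.ceil(params.fixation_min_ms / PERIOD_MS - 1e-9))
    valid = (stream.any_valid & np.isfinite(stream.x_cm)
             & np.isfinite(stream.y_cm))
    pts = np.column_stack([stream.x_cm, stream.y_cm])
    n = stream.n_samples

    def dispersion_ok(i, j):
        window = pts[i:j + 1]
        d2 = np.sum((window[:, None] - window[None, :]) ** 2, axis=-1)
        return np.sqrt(d2.max()) <= thr

    out = []
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and valid[j + 1] and dispersion_ok(i, j + 1):
            j += 1
        if j - i + 1 >= min_len:
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


class TestFixations:
    def test_constant_then_jump(self):
        x = np.concatenate([np.full(12, 20.0), np.full(8, 20.0 + 6.0)])
        stream = make_stream(x, np.full(20, 15.0))
        fix = detect_fixations(stream)
        assert len(fix) == 2  # the 8-sample tail is itself >= 100 ms
        assert fix[0].n_samples == 12
        assert fix[0].duration_ms == pytest.approx(12 * PERIOD_MS)
        assert fix[0].duration_ms == pytest.approx(400.0, abs=0.1)
        assert fix[0].centroid_x_cm == pytest.approx(20.0)

    def test_alternating_far_points_yield_nothing(self):
        # 3 degrees apart every sample: dispersion always exceeded
        jump = visual_angle_to_cm(3.0, 60.0)
        x = np.where(np.arange(40) % 2 == 0, 10.0, 10.0 + jump)
        stream = make_stream(x, np.full(40, 15.0))
        assert detect_fixations(stream) == []

    def test_invalid_sample_splits_window(self):
        valid = np.ones(24, bool)
        valid[11] = False
        stream = make_stream(np.full(24, 20.0), np.full(24, 15.0), valid=valid)
        fix = detect_fixations(stream)
        assert len(fix) == 2
        assert fix[0].n_samples == 11 and fix[1].n_samples == 12

    def test_no_valid_samples(self):
        stream = make_stream(np.full(10, 5.0), np.full(10, 5.0),
                             valid=np.zeros(10, bool))
        assert detect_fixations(stream) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        stream = random_walk_stream(np.random.default_rng(seed), n=500)
        got = [(f.start_ms, f.n_samples) for f in detect_fixations(stream)]
        want = [(i * PERIOD_MS, j - i + 1) for i, j in brute_force_idt(stream)]
        assert got == pytest.approx(want)

    @pytest.mark.parametrize("seed", range(5))
    def test_range_sum_variant_matches_its_oracle(self, seed):
        params = DetectionParams(dispersion_metric="range_sum")
        stream = random_walk_stream(np.random.default_rng(100 + seed), n=300)
        thr = visual_angle_to_cm(1.0, 60.0)
        valid = stream.any_valid

        def ok(i, j):
            xs = stream.x_cm[i:j + 1]
            ys = stream.y_cm[i:j + 1]
            return (xs.max() - xs.min()) + (ys.max() - ys.min()) <= thr

        want = []
        i, n = 0, stream.n_samples
        while i < n:
            if not valid[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and valid[j + 1] and ok(i, j + 1):
                j += 1
            if j - i + 1 >= 3:
                want.append((i, j - i + 1))
                i = j + 1
            else:
                i += 1
        got = [(int(round(f.start_ms / PERIOD_MS)), f.n_samples)
               for f in detect_fixations(stream, params)]
        assert got == want

    def test_fixations_disjoint_from_blinks_and_bounded(self):
        rng = np.random.default_rng(7)
        stream = random_walk_stream(rng, n=2000, p_invalid=0.0)
        # carve some gaps
        for s in (100, 700, 1500):
            stream.left_valid[s:s + 8] = False
            stream.right_valid[s:s + 8] = False
        stream.x_cm[~stream.any_valid] = np.nan
        fixations = detect_fixations(stream)
        blinks = detect_blinks(stream)
        for f in fixations:
            for b in blinks:
                assert (f.end_ms <= b.start_ms + 1e-6
                        or f.start_ms >= b.end_ms - 1e-6)
        total = sum(f.duration_ms for f in fixations)
        assert total <= stream.duration_ms


class TestPupil:
    def test_constant(self):
        stream = make_stream(np.full(30, 10.0), np.full(30, 10.0), pupil=3.44)
        assert pupil_mean(stream) == pytest.approx(3.44)

    def test_two_eye_mean(self):
        stream = make_stream(np.full(30, 10.0), np.full(30, 10.0))
        stream.pupil_left_mm[:] = 3.0
        stream.pupil_right_mm[:] = 4.0
        assert pupil_mean(stream) == pytest.approx(3.5)

    def test_single_eye_suffices(self):
        n = 30
        rv = np.zeros(n, bool)
        stream = make_stream(np.full(n, 10.0), np.full(n, 10.0),
                             left_valid=np.ones(n, bool), right_valid=rv)
        stream.pupil_left_mm[:] = 3.2
        assert pupil_mean(stream) == pytest.approx(3.2)

    def test_no_valid_pupil_is_nan_with_warning(self):
        stream = make_stream(np.full(10, 5.0), np.full(10, 5.0),
                             valid=np.zeros(10, bool))
        with pytest.warns(UserWarning):
            assert np.isnan(pupil_mean(stream))


class TestDetectionParams:
    def test_invalid_band(self):
        with pytest.raises(ValueError):
            DetectionParams(blink_min_ms=600, blink_max_ms=100)

    def test_unknown_metric(self):
        with pytest.raises(ValueError):
            DetectionParams(dispersion_metric="bogus")
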