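"""Beat-series compilation, artifact filtering, and uniform resampling."""

import numpy as np
import pytest

from hrvdyn.preprocess import (
    BeatSeries,
    compile_segments,
    contiguous_runs,
    filter_outliers,
    interpolate_uniform,
    mask_interval,
    person_mean,
)


class TestCompileSegments:
    def test_gap_preserves_task_clock(self):
        seg = [0.8] * 37  # 29.6 s of beats
        beats = compile_segments([seg, None, seg])
        np.testing.assert_allclose(beats.gap_intervals, [(29.6, 59.6)])
        # beats resume on the original clock after the inserted 30 s
        assert beats.beat_times[37] == pytest.approx(59.6 + 0.8)
        assert beats.task_length == pytest.approx(29.6 + 30 + 29.6)

    def test_all_segments_present_no_gaps(self):
        beats = compile_segments([[0.8] * 37, [0.75] * 40])
        assert beats.gap_intervals == []
        assert beats.n_beats == 77

    def test_ms_input_equals_seconds_input(self):
        ms = compile_segments([[800, 790, 810, 805]], unit="ms")
        s = compile_segments([[0.800, 0.790, 0.810, 0.805]], unit="s")
        np.testing.assert_allclose(ms.beat_times, s.beat_times)
        np.testing.assert_allclose(ms.ibis, s.ibis)

    @pytest.mark.parametrize("bad", [[0.8, float("nan")], [0.8, -0.2]])
    def test_invalid_records_rejected(self, bad):
        with pytest.raises(ValueError):
            compile_segments([bad])

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError):
            compile_segments([[0.8]], unit="min")


class TestFilterOutliers:
    def test_hard_range_removal_keeps_clock(self):
        beats = compile_segments([[0.8, 0.79, 3.0, 0.81]])
        out, report = filter_outliers(beats)
        assert report.n_hard_range == 1
        # surviving beats keep their original (cumulative) times
        np.testing.assert_allclose(out.ibis, [0.8, 0.79, 0.81])
        np.testing.assert_allclose(out.beat_times, [0.8, 1.59, 4.59 + 0.81])

    def test_smooth_series_untouched_and_idempotent(self):
        rng = np.random.default_rng(0)
        ibis = 0.8 + 0.02 * rng.standard_normal(200)
        beats = compile_segments([ibis])
        once, r1 = filter_outliers(beats)
        assert r1.n_removed == 0
        twice, r2 = filter_outliers(once)
        assert r2.n_removed == 0

    def test_adaptive_rule_catches_in_range_artifact(self):
        # a 1.5 s beat is inside the hard range but ~2x the running median
        ibis = [0.8] * 20 + [1.5] + [0.8] * 20
        beats = compile_segments([ibis])
        _, report = filter_outliers(beats)
        assert report.n_adaptive == 1 and report.n_hard_range == 0

    def test_clock_preservation_leaves_grid_unchanged_far_from_artifact(self):
        rng = np.random.default_rng(1)
        clean = list(0.8 + 0.01 * rng.standard_normal(250))
        with_artifact = clean.copy()
        with_artifact[100] = 3.0  # artifact replacing one beat's value
        g_clean = interpolate_uniform(
            filter_outliers(compile_segments([clean]))[0], fs=1
        )
        g_art = interpolate_uniform(
            filter_outliers(compile_segments([with_artifact]))[0], fs=1
        )
        n = min(g_clean.n, g_art.n)
        # far from the artifact the accumulated clock is identical, so the
        # late-series times differ and values agree only where beats align;
        # check the opening stretch before the artifact
        np.testing.assert_allclose(
            g_clean.values[:70], g_art.values[:70], atol=1e-9
        )


class TestInterpolateUniform:
    @pytest.mark.parametrize("fs", [1, 4])
    def test_constant_series_reproduced(self, fs):
        beats = compile_segments([[0.5] * 120])
        s = interpolate_uniform(beats, fs=fs)
        assert np.allclose(s.values[~s.missing], 0.5)

    def test_linear_trend_reproduced(self):
        # ibi at each beat time follows the line 0.70 + 0.002 t over ~100 s
        ibis = []
        t = 0.0
        while t < 100:
            ibi = (0.70 + 0.002 * t) / (1 - 0.002)  # so ibi = line(t + ibi)
            ibis.append(ibi)
            t += ibi
        beats = compile_segments([ibis])
        s = interpolate_uniform(beats, fs=1)
        grid = s.times()[~s.missing]
        expected = 0.70 + 0.002 * grid
        err = np.abs(s.values[~s.missing] - expected)[2:-2]
        assert err.max() < 1e-6  # cubic spline is exact on a line

    def test_gap_never_interpolated_across(self):
        seg = [0.8] * 37
        beats = compile_segments([seg, None, seg])
        s = interpolate_uniform(beats, fs=1)
        g0, g1 = beats.gap_intervals[0]
        in_gap = (s.times() >= g0) & (s.times() < g1)
        assert s.missing[in_gap].all()
        assert not s.missing[~in_gap].all()

    def test_1hz_equals_4hz_subsampled_on_gap_free_data(self):
        rng = np.random.default_rng(2)
        ibis = 0.8 + 0.03 * np.sin(np.arange(300) / 7) + 0.005 * rng.standard_normal(300)
        beats = compile_segments([ibis])
        s1 = interpolate_uniform(beats, fs=1)
        s4 = interpolate_uniform(beats, fs=4)
        sub = s4.values[:: 4][: s1.n]
        ok = ~s1.missing & ~s4.missing[::4][: s1.n]
        np.testing.assert_allclose(s1.values[ok], sub[ok], atol=1e-9)

    def test_silent_span_becomes_gap(self):
        # 10 s without beats mid-series exceeds the 3 s silence threshold
        t1 = np.cumsum([0.8] * 50)
        t2 = t1[-1] + 10 + np.cumsum([0.8] * 50)
        beats = BeatSeries(
            np.concatenate([t1, t2]), np.array([0.8] * 100), task_length=100.0
        )
        s = interpolate_uniform(beats, fs=1)
        silent = (s.times() > t1[-1] + 0.5) & (s.times() < t1[-1] + 9.5)
        assert s.missing[silent].all()

    def test_no_interpolable_run_raises(self):
        beats = compile_segments([[0.8, 0.8]])
        with pytest.raises(ValueError):
            interpolate_uniform(beats, fs=1)


class TestClockConservation:
    def test_beats_plus_gaps_cover_task(self):
        seg = [0.8] * 37
        beats = compile_segments([seg, None, seg, None])
        total_gap = sum(g1 - g0 for g0, g1 in beats.gap_intervals)
        # last beat + the trailing 30-s gap reaches the task end
        assert beats.beat_times[-1] + 30 == pytest.approx(beats.task_length)
        assert total_gap == pytest.approx(60.0)
        runs = contiguous_runs(beats)
        covered = sum(r1 - r0 for r0, r1 in runs) + total_gap
        assert covered == pytest.approx(beats.task_length)


class TestPersonMean:
    def test_constant_and_mixture(self):
        s = interpolate_uniform(compile_segments([[0.76] * 100]), fs=1)
        assert person_mean(s) == pytest.approx(0.76, abs=1e-9)
        from hrvdyn.preprocess import UniformSeries

        u = UniformSeries(
            np.array([0.6] * 5 + [1.0] * 5), np.zeros(10, bool), fs=1
        )
        assert person_mean(u) == pytest.approx(0.8)

    def test_all_missing_raises(self):
        from hrvdyn.preprocess import UniformSeries

        u = UniformSeries(np.full(5, np.nan), np.ones(5, bool), fs=1)
        with pytest.raises(ValueError):
            person_mean(u)

    def test_cohort_means_match_generator_distribution(self, latent_cohort):
        means = np.array([s.phys.mean() for s in latent_cohort.subjects])
        p = latent_cohort.params
        # person means scatter around the generating distribution
        assert abs(means.mean() - p.phys_mean) < 3 * p.phys_sd / np.sqrt(
            len(means)
        ) + 0.02


class TestMaskInterval:
    def test_mask_records_gap_and_removes_beats(self):
        beats = compile_segments([[0.8] * 300])
        masked = mask_interval(beats, 120.0, 150.0)
        assert (120.0, 150.0) in masked.gap_intervals
        in_gap = (masked.beat_times >= 120) & (masked.beat_times < 150)
        assert not in_gap.any()
        assert masked.task_length == beats.task_length
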