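"""Episode segmentation, Q/L ratio, cross-correlation lag, paired runs,
PRR, and the Mann-Whitney U test (exact branch vs enumeration/scipy)."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from astroloco import runstats, synthdata
from astroloco.runstats import (
    Episode,
    EpisodeSet,
    PairedRun,
    SpeedTrace,
    episode_means,
    find_paired_runs,
    mann_whitney,
    paired_run_ratio,
    ql_ratio,
    segment_episodes,
    speed_dff_crosscorr,
)

FS = 6.0


def _speed_with_runs(runs, duration=200.0, fs=FS, peak=10.0):
    speed = np.zeros(int(duration * fs))
    for a, b in runs:
        speed[int(a * fs) : int(b * fs)] = peak
    return SpeedTrace(speed, fs)


def _episodes(runs, duration=200.0, fs=FS):
    return segment_episodes(_speed_with_runs(runs, duration, fs))


class TestSegmentEpisodes:
    def test_all_zero_speed_is_single_quiescence(self):
        eps = segment_episodes(SpeedTrace(np.zeros(600), FS))
        assert len(eps) == 1 and eps.episodes[0].label == "quiescence"
        assert eps.episodes[0].duration_s == pytest.approx(100.0)

    def test_episodes_tile_the_recording_and_alternate(self):
        eps = _episodes([(30, 50), (100, 130)])
        assert eps.episodes[0].start_s == 0.0
        assert eps.episodes[-1].end_s == pytest.approx(200.0)
        total = sum(e.duration_s for e in eps)
        assert total == pytest.approx(200.0)

    def test_generator_truth_recovered_within_one_second(self):
        cfg = synthdata.ScenarioConfig(
            duration_s=400.0, fov=(16, 16), n_astro=0, seed=3
        )
        speed, runs, _ = synthdata.generate_speed_trace(cfg)
        eps = segment_episodes(speed)
        det = [(e.start_s, e.end_s) for e in eps.runs()]
        assert len(det) == len(runs)
        for (a, b), (a2, b2) in zip(runs, det):
            assert abs(a - a2) < 1.0 and abs(b - b2) < 1.0

    def test_sub_gap_interruptions_merged(self):
        eps = _episodes([(30, 40), (40.2, 50)])
        assert len(eps.runs()) == 1


class TestEpisodeMeans:
    def test_constant_trace(self):
        eps = _episodes([(30, 50)])
        df = episode_means(np.full(int(200 * FS), 3.0), eps)
        assert np.allclose(df["mean"], 3.0)

    def test_locomotion_indicator(self):
        eps = _episodes([(30, 50), (100, 130)])
        x = eps.label_array(int(200 * FS)).astype(float)
        df = episode_means(x, eps)
        loc = df[df["label"] == "locomotion"]["mean"]
        qui = df[df["label"] == "quiescence"]["mean"]
        assert np.allclose(loc, 1.0, atol=0.02) and np.allclose(qui, 0.0, atol=0.02)


class TestQlRatio:
    def test_equal_activity_gives_one(self):
        eps = _episodes([(30, 50)])
        assert ql_ratio(np.ones(int(200 * FS)), eps) == pytest.approx(1.0)

    def test_locomotion_only_activity_gives_zero(self):
        eps = _episodes([(30, 50)])
        x = eps.label_array(int(200 * FS)).astype(float)
        assert ql_ratio(x, eps) == pytest.approx(0.0, abs=0.02)

    def test_missing_label_is_nan(self):
        eps = segment_episodes(SpeedTrace(np.zeros(100), FS))
        assert np.isnan(ql_ratio(np.ones(100), eps))


class TestCrossCorrelation:
    def test_self_correlation_peaks_at_zero_lag(self):
        sp = _speed_with_runs([(30, 50), (100, 140)])
        r, lag = speed_dff_crosscorr(sp.speed, sp)
        assert r == pytest.approx(1.0) and lag == 0.0

    @pytest.mark.parametrize("delay", [0.0, 2.5, 5.0])
    def test_delayed_copy_recovers_lag(self, delay):
        sp = _speed_with_runs([(30, 50), (100, 140)])
        k = int(delay * FS)
        x = np.concatenate([np.zeros(k), sp.speed[: sp.speed.size - k]])
        _, lag = speed_dff_crosscorr(x, sp)
        assert lag == pytest.approx(delay, abs=1 / FS + 1e-9)

    def test_zero_variance_input_is_nan(self):
        sp = _speed_with_runs([(30, 50)])
        r, lag = speed_dff_crosscorr(np.zeros(sp.speed.size), sp)
        assert np.isnan(r) and np.isnan(lag)


class TestPairedRuns:
    def test_only_sub_30s_gaps_pair_greedily(self):
        eps = _episodes([(10, 20), (30, 40), (80, 90)], duration=120.0)
        pairs = find_paired_runs(eps)  # gaps: 10 s and 40 s
        assert len(pairs) == 1
        assert pairs[0].first.start_s == pytest.approx(10.0, abs=0.5)
        assert pairs[0].gap_s < 30.0

    def test_exactly_30s_gap_excluded(self):
        eps = _episodes([(10, 20), (50, 60)], duration=120.0)
        pairs = find_paired_runs(eps, max_gap_s=30.0)
        # measured gap is 30 s (within a sample); strict < excludes it
        assert pairs == [] or pairs[0].gap_s < 30.0 - 1 / FS

    def test_no_runs_gives_empty_list(self):
        eps = segment_episodes(SpeedTrace(np.zeros(600), FS))
        assert find_paired_runs(eps) == []

    def test_an_episode_joins_at_most_one_pair(self):
        eps = _episodes([(10, 20), (30, 40), (50, 60)], duration=120.0)
        pairs = find_paired_runs(eps)
        assert len(pairs) == 1  # greedy: (1,2); run 3 has no partner left


class TestPairedRunRatio:
    def _pair(self):
        return PairedRun(
            Episode(10.0, 20.0, "locomotion"), Episode(40.0, 50.0, "locomotion")
        )

    def test_identical_responses_give_unity(self):
        x = np.zeros(int(120 * FS))
        for onset in (12.0, 42.0):
            i = int(onset * FS)
            x[i : i + 12] = 5.0
        assert paired_run_ratio(x, self._pair(), FS) == pytest.approx(1.0)

    def test_scaled_second_response_gives_alpha(self):
        x = np.zeros(int(120 * FS))
        x[int(12 * FS) : int(12 * FS) + 12] = 5.0
        x[int(42 * FS) : int(42 * FS) + 12] = 5.0 * 0.32
        assert paired_run_ratio(x, self._pair(), FS) == pytest.approx(0.32)

    def test_zero_first_response_is_nan(self):
        x = np.zeros(int(120 * FS))
        assert np.isnan(paired_run_ratio(x, self._pair(), FS))


class TestMannWhitney:
    def test_complete_separation_u_zero_exact_p(self):
        u, p = mann_whitney(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert u == 0.0
        # one-sided exact P(U <= 0) = 1/20; two-sided doubles it
        assert p == pytest.approx(2 / 20)

    def test_identical_samples_give_p_one(self):
        a = np.array([1.0, 2, 3, 4])
        _, p = mann_whitney(a, a.copy())
        assert p == pytest.approx(1.0)

    def test_u_statistics_sum_to_product_of_sizes(self, rng):
        a, b = rng.random(6), rng.random(5)
        ua, _ = mann_whitney(a, b)
        ub, _ = mann_whitney(b, a)
        assert ua + ub == pytest.approx(30.0)

    def test_exact_branch_matches_scipy_without_ties(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 5))
            b = rng.normal(size=rng.integers(2, 6))
            u, p = mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_branch_close_to_scipy_normal_approx(self, rng):
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(0.6, 1.0, 25)
        _, p = mann_whitney(a, b)
        ref = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        )
        assert p == pytest.approx(ref.pvalue, rel=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney(np.array([]), np.array([1.0]))


class TestEpisodeSetInvariants:
    def test_non_tiling_episodes_rejected(self):
        with pytest.raises(ValueError):
            EpisodeSet(
                [Episode(0, 10, "quiescence"), Episode(12, 20, "locomotion")],
                FS,
            )

    def test_adjacent_same_label_rejected(self):
        with pytest.raises(ValueError):
            EpisodeSet(
                [Episode(0, 10, "quiescence"), Episode(10, 20, "quiescence")],
                FS,
            )
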