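"""Activity-unit factorization: HALS monotonicity and recovery, Li
footprint clipping, Ward merging, and unit classification."""

import numpy as np
import pytest

from astroloco import neuro, runstats
from astroloco.benchmarks import exhaustive_li_threshold
from astroloco.neuro import (
    ActivityUnit,
    Component,
    clip_footprint_li,
    hals_nmf,
    merge_units,
    patch_decompose,
    refine_global,
    unit_classification,
)


def _toy_movie(rng, t=90, h=24, w=24, n_units=2, noise=0.05):
    fps, traces = [], []
    for k in range(n_units):
        fp = np.zeros((h, w))
        y = 4 + 10 * k
        fp[y : y + 4, 4:16] = 1.0
        tr = np.zeros(t)
        tr[15 + 25 * k : 25 + 25 * k] = 3.0 + k
        fps.append(fp)
        traces.append(tr)
    frames = np.einsum("kt,khw->thw", np.stack(traces), np.stack(fps))
    frames += noise * rng.random((t, h, w))
    return frames, fps, traces


class TestHals:
    def test_objective_monotone_and_factors_nonnegative(self, rng):
        y = rng.random((50, 40))
        a0, c0 = rng.random((50, 4)), rng.random((4, 40))
        a, c, hist = hals_nmf(y, a0, c0, n_iter=30)
        assert all(x >= y2 - 1e-9 for x, y2 in zip(hist, hist[1:]))
        assert a.min() >= 0 and c.min() >= 0

    def test_exact_rank_data_reconstructed(self, rng):
        a_true = np.abs(rng.random((60, 3)))
        c_true = np.abs(rng.random((3, 50)))
        y = a_true @ c_true
        a, c, hist = hals_nmf(
            y, rng.random((60, 3)), rng.random((3, 50)), n_iter=500, tol=0.0
        )
        assert hist[-1] < 1e-6 * np.linalg.norm(y) ** 2


class TestPatchDecompose:
    def test_single_footprint_recovered(self, rng):
        frames, fps, traces = _toy_movie(rng, n_units=1)
        comps = patch_decompose(frames, patch=24, k_per_patch=1, seed=0)
        real = [c for c in comps if not c.is_background]
        assert real
        best = max(
            float(np.corrcoef(c.footprint.ravel(), fps[0].ravel())[0, 1])
            for c in real
        )
        assert best > 0.9

    def test_all_factors_nonnegative(self, rng):
        frames, _, _ = _toy_movie(rng)
        for c in patch_decompose(frames, patch=24, k_per_patch=3, seed=0):
            assert c.footprint.min() >= 0 and c.trace.min() >= 0

    def test_all_zero_movie_yields_no_components(self):
        assert patch_decompose(np.zeros((10, 16, 16))) == []


class TestRefineGlobal:
    def test_objective_not_worse_than_initialization(self, rng):
        frames, _, _ = _toy_movie(rng)
        comps = patch_decompose(frames, patch=16, k_per_patch=2, seed=0)
        y = frames.reshape(frames.shape[0], -1).T
        a0 = np.stack([c.footprint.ravel() for c in comps], axis=1)
        c0 = np.stack([c.trace for c in comps])
        obj0 = float(np.linalg.norm(y - a0 @ c0) ** 2)
        refined = refine_global(frames, comps, n_iter=30)
        a1 = np.stack([c.footprint.ravel() for c in refined], axis=1)
        # refined components are renormalized; rebuild the product
        c1 = np.stack([c.trace for c in refined])
        obj1 = float(np.linalg.norm(y - a1 @ c1) ** 2)
        assert obj1 <= obj0 + 1e-6 * obj0

    def test_empty_initialization_rejected(self):
        with pytest.raises(ValueError):
            refine_global(np.zeros((5, 8, 8)), [])


class TestLiClipping:
    def test_bimodal_footprint_keeps_bright_mode(self, rng):
        fp = np.zeros((40, 40))
        weak = rng.uniform(0.005, 0.02, 1000)
        fp.ravel()[:1000] = weak
        fp.ravel()[1200:1300] = 1.0
        out = clip_footprint_li(fp)
        assert (out > 0).sum() == 100
        thr_oracle = exhaustive_li_threshold(fp[fp > 0])
        assert ((out > 0) == (fp >= thr_oracle)).all()

    def test_constant_footprint_unchanged_with_warning(self):
        fp = np.zeros((8, 8))
        fp[2:4, 2:4] = 0.7
        with pytest.warns(UserWarning):
            out = clip_footprint_li(fp)
        assert np.array_equal(out, fp)

    def test_idempotent(self, rng):
        fp = np.zeros((30, 30))
        fp.ravel()[:400] = rng.uniform(0.001, 0.05, 400)
        fp.ravel()[500:560] = rng.uniform(0.8, 1.0, 60)
        once = clip_footprint_li(fp)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            twice = clip_footprint_li(once)
        assert np.array_equal(once, twice)


class TestMergeUnits:
    def _comp(self, fp, tr):
        return Component(fp, tr)

    def test_identical_traces_merge_into_one_unit(self, rng):
        tr = rng.random(40)
        fps = [np.zeros((8, 8)) for _ in range(3)]
        for i, fp in enumerate(fps):
            fp[i, :] = 1.0
        comps = [self._comp(fp, tr + 1e-3 * i) for i, fp in enumerate(fps)]
        other = self._comp(np.ones((8, 8)), rng.random(40))
        units = merge_units(comps + [other], n_final=2)
        sizes = sorted(len(u.members) for u in units)
        assert sizes == [1, 3]

    def test_three_orthogonal_groups_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        base = [np.zeros(60) for _ in range(3)]
        for i, b in enumerate(base):
            b[20 * i : 20 * i + 15] = 1.0
        comps, labels = [], []
        for i, b in enumerate(base):
            for j in range(3):
                fp = np.zeros((6, 6))
                fp[i, j] = 1.0
                comps.append(self._comp(fp, b + 0.01 * rng.random(60)))
                labels.append(i)
        units = merge_units(comps, n_final=3)
        pred = np.zeros(len(comps), dtype=int)
        for k, u in enumerate(units):
            for m in u.members:
                pred[m] = k
        assert adjusted_rand_score(labels, pred) == 1.0

    def test_n_final_equal_to_component_count_means_no_merge(self, rng):
        comps = [
            self._comp(np.ones((4, 4)), rng.random(20)) for _ in range(4)
        ]
        units = merge_units(comps, n_final=4)
        assert all(len(u.members) == 1 for u in units)

    def test_fewer_components_than_units_warns(self, rng):
        comps = [self._comp(np.ones((4, 4)), rng.random(20))]
        with pytest.warns(UserWarning):
            units = merge_units(comps, n_final=3)
        assert len(units) == 1


class TestUnitClassification:
    def _episodes(self, n=120, fs=6.0):
        speed = np.zeros(n)
        speed[40:80] = 10.0
        return runstats.segment_episodes(runstats.SpeedTrace(speed, fs))

    def test_speed_locked_trace_is_locomotion_active(self):
        eps = self._episodes()
        tr = np.zeros(120)
        tr[40:80] = 1.0
        unit = ActivityUnit(np.ones((4, 4)), tr)
        assert unit_classification([unit], eps) == ["locomotion-active"]

    def test_anticorrelated_trace_is_quiescent_active(self):
        eps = self._episodes()
        tr = np.ones(120)
        tr[40:80] = 0.0
        unit = ActivityUnit(np.ones((4, 4)), tr)
        assert unit_classification([unit], eps) == ["quiescent-active"]

    def test_generator_assignment_recovered(self, neuro_recording):
        rec = neuro_recording
        fs = rec.green.fs
        eps = runstats.segment_episodes(
            runstats.SpeedTrace(rec.speed.speed, rec.speed.fs)
        )
        units = [
            ActivityUnit(fp, tr)
            for fp, tr in zip(rec.scene.neuro_footprints, rec.truth.neuro_traces)
        ]
        labels = unit_classification(units, eps)
        expected = [
            "locomotion-active" if l == "locomotion" else "quiescent-active"
            for l in rec.truth.neuro_labels
        ]
        n_match = sum(a == b for a, b in zip(labels, expected))
        assert n_match >= 0.9 * len(labels)
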