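"""Generator invariants: episode construction, scene geometry, kinetic
ground truth readable off the clean traces, and the camera noise model."""

import numpy as np
import pytest

from astroloco import synthdata
from astroloco.synthdata import ScenarioConfig


def _cfg(**kw):
    base = dict(
        duration_s=120.0,
        fov=(48, 48),
        n_astro=1,
        astro_domain_radius_px=18,
        astro_soma_radius_px=5,
        seed=0,
    )
    base.update(kw)
    return ScenarioConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"duration_s": 0.0},
            {"fs_raw": -1.0},
            {"depletion_alpha": 0.0},
            {"depletion_alpha": 1.5},
            {"osc_freq_hz": 0.05},
            {"n_astro": -1},
            {"paired_gap_s": 30.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            _cfg(**kw)

    def test_json_roundtrip(self):
        cfg = _cfg(seed=5, depletion_alpha=0.5)
        assert ScenarioConfig.from_json(cfg.to_json()) == cfg


class TestSpeedTrace:
    def test_sample_count_and_nonnegativity(self):
        cfg = _cfg(duration_s=600.0)
        speed, runs, _ = synthdata.generate_speed_trace(cfg)
        assert speed.speed.size == 18000  # 600 s x 30 Hz
        assert speed.speed.min() >= 0

    def test_deterministic_for_fixed_seed(self):
        cfg = _cfg(seed=3)
        s1, r1, p1 = synthdata.generate_speed_trace(cfg)
        s2, r2, p2 = synthdata.generate_speed_trace(cfg)
        assert np.array_equal(s1.speed, s2.speed)
        assert r1 == r2 and p1 == p2

    def test_unpaired_runs_separated_by_more_than_30s(self):
        cfg = _cfg(duration_s=600.0, paired_run_prob=0.0, seed=1)
        _, runs, pairs = synthdata.generate_speed_trace(cfg)
        assert pairs == []
        gaps = [b[0] - a[1] for a, b in zip(runs, runs[1:])]
        assert all(g > 30.0 for g in gaps)

    def test_paired_runs_have_sub_30s_gap(self):
        cfg = _cfg(duration_s=600.0, paired_run_prob=1.0, seed=2)
        _, runs, pairs = synthdata.generate_speed_trace(cfg)
        assert pairs
        for i, j in pairs:
            assert runs[j][0] - runs[i][1] < 30.0

    def test_speed_zero_outside_runs(self):
        cfg = _cfg(duration_s=300.0, seed=4)
        speed, runs, _ = synthdata.generate_speed_trace(cfg)
        mask = np.zeros(speed.speed.size, dtype=bool)
        for a, b in runs:
            mask[int(a * 30) : int(b * 30) + 1] = True
        assert np.all(speed.speed[~mask] == 0)


class TestScene:
    def test_soma_inside_disjoint_domains(self):
        cfg = _cfg(fov=(96, 96), n_astro=2)
        scene = synthdata.generate_scene(cfg)
        assert scene.astro_ids == [1, 2]
        for cid in scene.astro_ids:
            soma, dom = scene.soma_mask(cid), scene.domain_mask(cid)
            assert soma.any() and (soma & ~dom).sum() == 0
            assert soma.sum() < dom.sum()
        overlap = (scene.astro_domain_labels > 0).sum()
        assert overlap == sum(
            scene.domain_mask(c).sum() for c in scene.astro_ids
        )

    def test_footprints_nonnegative_peak_one(self):
        cfg = ScenarioConfig.neuro_default(
            fov=(48, 48), n_neuro_units=3, neuro_len_px=10, seed=0
        )
        scene = synthdata.generate_scene(cfg)
        assert len(scene.neuro_footprints) == 3
        for fp in scene.neuro_footprints:
            assert fp.min() >= 0 and fp.max() == pytest.approx(1.0)

    def test_placement_error_when_fov_too_small(self):
        with pytest.raises(synthdata.PlacementError):
            synthdata.generate_scene(_cfg(fov=(40, 40), n_astro=9))

    def test_deterministic(self):
        a = synthdata.generate_scene(_cfg(seed=9))
        b = synthdata.generate_scene(_cfg(seed=9))
        assert np.array_equal(a.astro_domain_labels, b.astro_domain_labels)


class TestFluorescence:
    def _clean(self, **kw):
        cfg = _cfg(mean_quiet_s=25.0, paired_run_prob=0.0,
                   quiescent_event_rate_hz=0.0, **kw)
        speed, runs, pairs = synthdata.generate_speed_trace(cfg)
        scene = synthdata.generate_scene(cfg)
        g, r, truth = synthdata.simulate_fluorescence(cfg, scene, speed, runs, pairs)
        return cfg, scene, g, r, truth

    def test_soma_onset_follows_processes_by_configured_delay(self):
        cfg, scene, g, _, truth = self._clean(soma_delay_s=4.7, osc_depth=0.0)
        cid = scene.astro_ids[0]
        soma = truth.astro_soma_traces[cid]
        proc = truth.astro_proc_traces[cid]
        t_s = np.flatnonzero(soma >= 0.15 * soma.max())[0]
        t_p = np.flatnonzero(proc >= 0.15 * proc.max())[0]
        assert (t_s - t_p) / cfg.fs_raw == pytest.approx(4.7, abs=1 / cfg.fs_raw)

    def test_soma_peak_is_amplified_process_peak(self):
        _, scene, _, _, truth = self._clean(soma_amplification=3.0, osc_depth=0.0)
        cid = scene.astro_ids[0]
        ratio = truth.astro_soma_traces[cid].max() / truth.astro_proc_traces[cid].max()
        assert ratio == pytest.approx(3.0, rel=0.02)

    def test_no_depletion_when_alpha_is_one(self):
        cfg = _cfg(duration_s=150.0, paired_run_prob=1.0, depletion_alpha=1.0,
                   mean_quiet_s=30.0, seed=6)
        speed, runs, pairs = synthdata.generate_speed_trace(cfg)
        scene = synthdata.generate_scene(cfg)
        _, _, truth = synthdata.simulate_fluorescence(cfg, scene, speed, runs, pairs)
        amps = truth.run_amplitudes[scene.astro_ids[0]]
        # per-cell jitter only: all run amplitudes within the jitter band
        assert np.all(np.abs(np.asarray(amps) - 1.0) <= 0.05 + 1e-9)

    def test_depletion_scales_second_run_of_pair(self):
        cfg = _cfg(duration_s=150.0, paired_run_prob=1.0, depletion_alpha=0.4,
                   mean_quiet_s=30.0, seed=6)
        speed, runs, pairs = synthdata.generate_speed_trace(cfg)
        scene = synthdata.generate_scene(cfg)
        _, _, truth = synthdata.simulate_fluorescence(cfg, scene, speed, runs, pairs)
        amps = truth.run_amplitudes[scene.astro_ids[0]]
        i, j = truth.paired_intervals[0]
        assert amps[j] / amps[i] == pytest.approx(0.4, rel=0.12)

    def test_red_channel_is_static(self):
        _, _, _, red, _ = self._clean()
        assert np.ptp(red.frames, axis=0).max() == 0


class TestCamera:
    def test_noiseless_zero_shift_limit_is_identity(self):
        cfg = synthdata.ScenarioConfig(
            duration_s=2.0, fov=(32, 32), n_astro=0, photon_gain=0.0,
            read_noise_sd=0.0, max_shift_px=0, seed=0,
        )
        speed, runs, pairs = synthdata.generate_speed_trace(cfg)
        scene = synthdata.generate_scene(cfg)
        g, _, _ = synthdata.simulate_fluorescence(cfg, scene, speed, runs, pairs)
        noisy, shifts = synthdata.apply_camera(g, cfg)
        assert np.allclose(noisy.frames, g.frames)
        assert np.all(shifts == 0)

    def test_zero_max_shift_gives_zero_ground_truth_shifts(self):
        cfg = synthdata.ScenarioConfig(
            duration_s=2.0, fov=(16, 16), n_astro=0, max_shift_px=0, seed=0
        )
        assert np.all(synthdata.generate_shifts(cfg, 60) == 0)

    def test_poisson_variance_matches_mean(self):
        # flat frame, mean 100, gain 1: sample variance within 5% of 100
        cfg = synthdata.ScenarioConfig(
            duration_s=2.0, fov=(340, 340), n_astro=0, photon_gain=1.0,
            read_noise_sd=0.0, max_shift_px=0, seed=1,
        )
        from astroloco.preprocess import Movie

        flat = Movie(np.full((1, 340, 340), 100.0, dtype=np.float32), 30.0)
        noisy, _ = synthdata.apply_camera(flat, cfg)
        var = noisy.frames.astype(float).var()
        assert var == pytest.approx(100.0, rel=0.05)

    def test_counts_are_integer_valued(self, astro_recording):
        assert astro_recording.green.frames.dtype == np.uint16

    def test_same_seed_reproduces_recording(self):
        cfg = synthdata.ScenarioConfig(
            duration_s=5.0, fov=(32, 32), n_astro=1,
            astro_domain_radius_px=12, astro_soma_radius_px=4, seed=11,
        )
        a = synthdata.simulate_recording(cfg)
        b = synthdata.simulate_recording(cfg)
        assert np.array_equal(a.green.frames, b.green.frames)
        assert np.array_equal(a.truth.shifts, b.truth.shifts)
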