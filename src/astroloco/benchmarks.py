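"""Ground-truth validation experiments.

Each function generates synthetic recordings with
:mod:`astroloco.synthdata`, runs the corresponding analysis stage, and
measures recovery of the injected ground truth.  They are used both by the
test suite and by ``scripts/acceptance.py``; all randomness derives from the
``seed`` argument.

Problem sizes (field of view, duration, numbers of movies/cells/seeds) are
chosen so the whole battery runs in minutes on a single core while keeping
every recovery target statistically meaningful; the kinetic and noise
parameters are the generator defaults.
"""

from __future__ import annotations



import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_li

from . import activity, astro, neuro, preprocess, runstats, synthdata
from .pipeline import PipelineConfig, _dff_from_movie

__all__ = [
    "shift_recovery",
    "denoise_gain",
    "baseline_dff_recovery",
    "active_area_rules",
    "latency_and_oscillation",
    "lag_recovery",
    "prr_recovery",
    "directional_contrasts",
    "factorization_quality",
    "li_threshold_agreement",
    "mann_whitney_agreement",
    "feret_agreement",
]


def _seed_of(seed: int, tag: int, k: int = 0) -> int:
    """Derive a child seed below 2**31."""
    return int(
        np.random.SeedSequence([seed, tag, k]).generate_state(1)[0] % (2**31)
    )


# --------------------------------------------------------------------------
# shared small-scene analysis path


def _small_astro_cfg(seed: int, **kw) -> synthdata.ScenarioConfig:
    base = dict(
        duration_s=260.0,
        fov=(40, 40),
        n_astro=1,
        astro_domain_radius_px=15,
        astro_soma_radius_px=4,
        paired_run_prob=0.0,
        seed=seed,
    )
    base.update(kw)
    return synthdata.ScenarioConfig(**base)


def _small_neuro_cfg(seed: int, **kw) -> synthdata.ScenarioConfig:
    base = dict(
        duration_s=260.0,
        fov=(40, 40),
        n_neuro_units=4,
        neuro_len_px=10,
        paired_run_prob=0.0,
        seed=seed,
    )
    base.update(kw)
    return synthdata.ScenarioConfig.neuro_default(**base)


def _process(
    rec: synthdata.SimulatedRecording,
    use_clean: bool = False,
    denoise: bool = False,
) -> tuple[activity.DffMovie, np.ndarray, runstats.SpeedTrace, runstats.EpisodeSet]:
    """Bin, motion-correct and convert a recording to dF/F; resample the
    speed trace to the binned clock and segment episodes."""
    cfg = PipelineConfig()
    green = rec.clean_green if use_clean else rec.green
    g = preprocess.temporal_bin(green, cfg.bin_batch)
    if use_clean:
        shifts = preprocess.ShiftSeries(np.zeros((g.n_frames, 2)))
    else:
        r = preprocess.temporal_bin(rec.red, cfg.bin_batch)
        r_dn = preprocess.denoise_reference(r, cfg.ref_components, cfg.ref_sigma_px)
        shifts = preprocess.estimate_shifts(r_dn)
        g = preprocess.apply_shifts(g, shifts)
    if denoise:
        g = preprocess.patch_svd_denoise(
            g, cfg.patch_px, cfg.patch_overlap, cfg.patch_rank, cfg.patch_sigma
        )
    margin = int(np.abs(shifts.shifts).max())
    d = _dff_from_movie(g, cfg, crop_margin=margin)
    mean_dff = activity.frame_mean_dff(d)
    idx = np.clip(
        (np.arange(g.n_frames) * rec.speed.fs / g.fs).astype(int),
        0,
        rec.speed.speed.size - 1,
    )
    sp = runstats.SpeedTrace(rec.speed.speed[idx], g.fs)
    eps = runstats.segment_episodes(sp)
    return d, mean_dff, sp, eps


# --------------------------------------------------------------------------
# 1. rigid shift recovery


def shift_recovery(seed: int, n_movies: int = 10) -> dict:
    """Fraction of synthetic movies whose injected integer drift (<= 5 px)
    is recovered exactly by the red-channel registration chain."""
    n_exact = 0
    total_err = 0.0
    for k in range(n_movies):
        cfg = _small_astro_cfg(
            _seed_of(seed, 1, k), duration_s=25.0, fov=(48, 48),
            astro_domain_radius_px=18, astro_soma_radius_px=5, max_shift_px=5,
        )
        rec = synthdata.simulate_recording(cfg)
        rb = preprocess.temporal_bin(rec.red, 5)
        est = preprocess.estimate_shifts(
            preprocess.denoise_reference(rb, 50, 1.0)
        )
        gt = rec.truth.shifts[::5][: rb.n_frames]
        err = np.abs(est.shifts - gt)
        n_exact += int((err == 0).all())
        total_err += float(err.max())
    return {
        "n_movies": n_movies,
        "fraction_exact": n_exact / n_movies,
        "max_abs_error_px": total_err if n_movies == 0 else float(total_err),
    }


# --------------------------------------------------------------------------
# 2. patch-SVD denoising gain


def denoise_gain(seed: int) -> dict:
    """MSE reduction of the Anscombe/patch-SVD chain vs the raw movie,
    both compared to the noise-free truth (drift disabled to isolate the
    denoiser)."""
    cfg = _small_astro_cfg(
        _seed_of(seed, 2), duration_s=100.0, fov=(64, 64),
        astro_domain_radius_px=24, astro_soma_radius_px=6, max_shift_px=0,
    )
    rec = synthdata.simulate_recording(cfg)
    clean = preprocess.temporal_bin(rec.clean_green, 5)
    noisy = preprocess.temporal_bin(rec.green, 5)
    den = preprocess.patch_svd_denoise(noisy, patch=32, rank=8)
    mse_raw = float(np.mean((noisy.frames - clean.frames) ** 2))
    mse_den = float(np.mean((den.frames - clean.frames) ** 2))
    return {
        "mse_raw": mse_raw,
        "mse_denoised": mse_den,
        "mse_reduction_pct": 100.0 * (1.0 - mse_den / mse_raw),
    }


# --------------------------------------------------------------------------
# 3. baseline / dF/F recovery on constructed traces


def baseline_dff_recovery(seed: int, n_pixels: int = 64) -> dict:
    """Envelope + mode-corrected baseline on traces with a known slow
    baseline and sparse transients; errors of F0 and of transient peak dF/F."""
    rng = np.random.default_rng(_seed_of(seed, 3))
    fs, dur = 6.0, 600.0
    t = np.arange(int(dur * fs)) / fs
    f0_true = np.empty((t.size, n_pixels))
    f = np.empty_like(f0_true)
    peak_true = 80.0  # transient peak dF/F, percent
    peak_frames = []
    for p in range(n_pixels):
        # bright baseline keeps shot noise ~2% of F0; transients shorter
        # than the envelope window so the running minimum sees the floor
        base = 2000.0 * (
            1.0 + 0.08 * np.sin(2 * np.pi * t / 300.0 + rng.uniform(0, 2 * np.pi))
        )
        onsets = rng.uniform(40, dur - 40, 4)
        dff = np.zeros_like(t)
        for on in onsets:
            dff += synthdata._dexp_kernel(t - on, 1.0, 3.0)
        dff *= peak_true / 100.0 / max(dff.max(), 1e-9)
        trace = base * (1.0 + dff)
        noisy = rng.poisson(trace).astype(float)
        f0_true[:, p] = base
        f[:, p] = noisy
        peak_frames.append(int(np.argmax(dff)))
    f0 = activity.baseline_envelope(f, fs, sigma_t=15.0)
    f0 = activity.mode_bias_correct(f, f0)
    f0_err = float(np.mean(np.abs(f0 - f0_true) / f0_true)) * 100.0
    d = activity.compute_dff(
        f[:, :, None], f0[:, :, None], fs,
        stained=np.ones((n_pixels, 1), dtype=bool),
    )
    dff_pct = d.dff[:, :, 0]
    peak_errs = [
        abs(dff_pct[fr, p] - peak_true) / peak_true * 100.0
        for p, fr in enumerate(peak_frames)
    ]
    return {
        "f0_mean_error_pct": f0_err,
        "dff_peak_mean_error_pct": float(np.mean(peak_errs)),
    }


# --------------------------------------------------------------------------
# 4. active-segment threshold rules (bit-exact constructions)


def active_area_rules(seed: int = 0) -> dict:
    """The three printed rules on constructed inputs: cluster size must be
    strictly greater than 16 px, chains must span >= 3 frames, and
    dF/F = 15.0 % is retained (>= threshold)."""
    h = w = 12
    stained = np.ones((h, w), dtype=bool)

    def seg_count(dff):
        d = activity.DffMovie(dff.astype(np.float32), 6.0, stained)
        return activity.detect_active_segments(d).n_segments

    # 16-px cluster (4x4): not > 16 -> rejected; 17 px -> retained
    dff16 = np.zeros((5, h, w))
    dff16[:, 2:6, 2:6] = 20.0
    dff17 = dff16.copy()
    dff17[:, 6, 2] = 20.0

    # 30-px cluster alive for only 2 frames -> rejected
    dff2f = np.zeros((5, h, w))
    dff2f[1:3, 2:8, 2:7] = 20.0

    # exactly 15.0 % everywhere, 5 frames -> retained (>= 15)
    dff15 = np.zeros((5, h, w))
    dff15[:, 2:8, 2:8] = 15.0

    return {
        "cluster_16px_rejected": int(seg_count(dff16) == 0),
        "cluster_17px_retained": int(seg_count(dff17) == 1),
        "chain_2frames_rejected": int(seg_count(dff2f) == 0),
        "dff_15pct_retained": int(seg_count(dff15) == 1),
    }


# --------------------------------------------------------------------------
# 5 & 6. latency recovery and somatic oscillation direction


def latency_and_oscillation(
    seed: int,
    delays: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0),
    movies_per_delay: int = 10,
) -> dict:
    """Inject centripetal soma delays, recover the 15%-of-peak latency on
    the noiseless and the noisy pipeline, and compare soma vs process
    wavelet band power on every noisy cell."""
    err_clean: list[float] = []
    err_noisy: list[float] = []
    osc_wins = 0
    n_cells = 0
    for di, delay in enumerate(delays):
        for k in range(movies_per_delay):
            cfg = _small_astro_cfg(
                _seed_of(seed, 5, di * 100 + k),
                duration_s=90.0, fov=(48, 48),
                astro_domain_radius_px=18, astro_soma_radius_px=5,
                mean_quiet_s=25.0, soma_delay_s=delay,
            )
            rec = synthdata.simulate_recording(cfg)
            cid = rec.scene.astro_ids[0]
            soma_m = rec.scene.soma_mask(cid)
            proc_m = rec.scene.processes_mask(cid)
            for use_clean in (True, False):
                d, _, _, _ = _process(rec, use_clean=use_clean)
                soma, proc = astro.compartment_traces(d, soma_m, proc_m)
                sn = astro.normalize_to_peak(soma)
                pn = astro.normalize_to_peak(proc)
                lat = astro.onset_latency(sn, pn, d.fs)
                (err_clean if use_clean else err_noisy).append(
                    abs(lat - delay)
                )
                if not use_clean:
                    n_cells += 1
                    osc_wins += int(
                        astro.wavelet_band_power(sn, d.fs)
                        > astro.wavelet_band_power(pn, d.fs)
                    )
    return {
        "n_cells": n_cells,
        "latency_max_error_clean_s": float(np.max(err_clean)),
        "latency_max_error_noisy_s": float(np.max(err_noisy)),
        "soma_power_wins_fraction": osc_wins / n_cells,
    }


# --------------------------------------------------------------------------
# 7. cross-correlation lag recovery


def lag_recovery(
    seed: int, lags_s: tuple[float, ...] = (0.0, 2.5, 5.0), fs: float = 6.0
) -> dict:
    """Delay a generated speed trace by known lags and recover them."""
    cfg = _small_astro_cfg(_seed_of(seed, 7), duration_s=300.0)
    speed_raw, _, _ = synthdata.generate_speed_trace(cfg)
    step = int(round(speed_raw.fs / fs))
    sp = runstats.SpeedTrace(speed_raw.speed[::step], fs)
    errs = {}
    for lag in lags_s:
        k = int(round(lag * fs))
        x = np.concatenate([np.zeros(k), sp.speed[: sp.speed.size - k]])
        _, lag_est = runstats.speed_dff_crosscorr(x, sp, max_lag_s=12.0)
        errs[lag] = abs(lag_est - lag)
    return {
        "max_lag_error_s": float(max(errs.values())),
        "lag_errors_s": {str(k): float(v) for k, v in errs.items()},
    }


# --------------------------------------------------------------------------
# 8. paired-run ratio recovery


def prr_recovery(
    seed: int,
    alphas: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0),
    n_seeds: int = 20,
) -> dict:
    """Median recovered PRR per injected depletion factor alpha."""
    medians = {}
    for ai, alpha in enumerate(alphas):
        vals: list[float] = []
        for k in range(n_seeds):
            cfg = _small_astro_cfg(
                _seed_of(seed, 8, ai * 1000 + k),
                duration_s=85.0, mean_run_s=7.0, mean_quiet_s=10.0,
                paired_run_prob=1.0, depletion_alpha=alpha,
            )
            rec = synthdata.simulate_recording(cfg)
            _, mean_dff, sp, eps = _process(rec)
            pairs = runstats.find_paired_runs(eps)
            vals.extend(
                runstats.paired_run_ratio(mean_dff, p, sp.fs) for p in pairs
            )
        medians[alpha] = float(np.nanmedian(vals))
    return {
        "median_prr": {str(a): m for a, m in medians.items()},
        "max_abs_deviation": float(
            max(abs(m - a) for a, m in medians.items())
        ),
        "median_prr_alpha1": medians[alphas[-1]],
    }


# --------------------------------------------------------------------------
# 9. astro vs neuro directional contrasts


def directional_contrasts(seed: int, n_seeds: int = 20) -> dict:
    """Q/L ratios and cross-correlation lags of default astro vs neuro
    scenes, compared with the package's Mann-Whitney test."""
    aq, nq, al, nl = [], [], [], []
    for k in range(n_seeds):
        rec_a = synthdata.simulate_recording(
            _small_astro_cfg(_seed_of(seed, 9, k))
        )
        _, mdff_a, sp_a, eps_a = _process(rec_a)
        aq.append(runstats.ql_ratio(mdff_a, eps_a))
        al.append(runstats.speed_dff_crosscorr(mdff_a, sp_a, 15.0)[1])
        rec_n = synthdata.simulate_recording(
            _small_neuro_cfg(_seed_of(seed, 10, k))
        )
        _, mdff_n, sp_n, eps_n = _process(rec_n)
        nq.append(runstats.ql_ratio(mdff_n, eps_n))
        nl.append(runstats.speed_dff_crosscorr(mdff_n, sp_n, 15.0)[1])
    _, p_ql = runstats.mann_whitney(np.asarray(aq), np.asarray(nq))
    _, p_lag = runstats.mann_whitney(np.asarray(al), np.asarray(nl))
    return {
        "astro_ql_median": float(np.median(aq)),
        "neuro_ql_median": float(np.median(nq)),
        "p_ql": float(p_ql),
        "astro_lag_median_s": float(np.median(al)),
        "neuro_abs_lag_median_s": float(np.median(np.abs(nl))),
        "p_lag": float(p_lag),
        "astro_lag_all_positive": int(all(l > 0 for l in al)),
        "neuro_lag_all_small": int(all(abs(l) < 0.5 for l in nl)),
    }


# --------------------------------------------------------------------------
# 10. factorization quality


def factorization_quality(seed: int, n_movies: int = 2) -> dict:
    """End-to-end activity-unit segmentation on 6-unit neuronal movies:
    footprint Jaccard and trace correlation against ground truth (matched
    by the Hungarian assignment on Jaccard)."""
    js, cs = [], []
    for k in range(n_movies):
        cfg = _small_neuro_cfg(
            _seed_of(seed, 11, k), duration_s=200.0, fov=(64, 64),
            n_neuro_units=6, neuro_len_px=12,
        )
        rec = synthdata.simulate_recording(cfg)
        d, _, _, _ = _process(rec)
        units = neuro.segment_units(
            d.dff, patch=100, k_per_patch=12, n_final=6, seed=cfg.seed
        )
        bins = rec.truth.neuro_traces[0].size // 5 * 5
        tt = [
            tr[:bins].reshape(-1, 5).mean(1)[: units[0].trace.size]
            for tr in rec.truth.neuro_traces
        ]
        # compare within the analysed region (borders touched by drift are
        # cropped from the stained mask and invisible to the method),
        # against the effective (optically blurred) footprints the movie
        # actually contains, with the pipeline's own support rule (Li clip)
        # applied to truth and estimate alike
        true_sup = [
            (neuro.clip_footprint_li(fp.copy()) > 0) & d.stained
            for fp in rec.truth.neuro_effective_footprints
        ]
        jmat = np.zeros((len(units), len(true_sup)))
        cmat = np.zeros_like(jmat)
        for i, u in enumerate(units):
            su = u.footprint > 0
            for j, st in enumerate(true_sup):
                jmat[i, j] = (su & st).sum() / max((su | st).sum(), 1)
                if u.trace.std() > 0 and np.std(tt[j]) > 0:
                    cmat[i, j] = np.corrcoef(u.trace, tt[j])[0, 1]
        ri, cj = linear_sum_assignment(-jmat)
        # average over all truth units: an unrecovered unit counts as zero
        n_true = len(true_sup)
        js.append(float(jmat[ri, cj].sum() / n_true))
        cs.append(float(cmat[ri, cj].sum() / n_true))
    return {
        "mean_footprint_jaccard": float(np.mean(js)),
        "mean_trace_correlation": float(np.mean(cs)),
    }


def li_cross_entropy(vals: np.ndarray, t: float) -> float:
    """Li's minimum-cross-entropy objective for threshold ``t``."""
    v = np.asarray(vals, dtype=float)
    lo, hi = v[v < t], v[v >= t]
    if lo.size == 0 or hi.size == 0 or lo.mean() <= 0:
        return float("inf")
    return float(-(lo.sum() * np.log(lo.mean()) + hi.sum() * np.log(hi.mean())))


def exhaustive_li_threshold(vals: np.ndarray) -> float:
    """Global minimizer of Li's cross-entropy over thresholds between
    consecutive sorted unique values (brute force)."""
    uniq = np.unique(np.asarray(vals, dtype=float))
    cands = 0.5 * (uniq[:-1] + uniq[1:])
    ces = [li_cross_entropy(vals, t) for t in cands]
    return float(cands[int(np.argmin(ces))])


def li_threshold_agreement(seed: int, n_hist: int = 100) -> dict:
    """Agreement (identical clipped pixel sets) between the iterative Li
    threshold and the exhaustive cross-entropy search on random bimodal
    footprint-like histograms."""
    rng = np.random.default_rng(_seed_of(seed, 12))
    agree = 0
    for _ in range(n_hist):
        n_lo = int(rng.integers(100, 2000))
        n_hi = int(rng.integers(max(30, n_lo // 10), n_lo // 2 + 31))
        lo = rng.uniform(0.002, 0.25, n_lo) * rng.beta(2, 2, n_lo)
        hi = rng.uniform(0.55, 1.0, n_hi)
        vals = np.concatenate([lo, hi])
        ti = threshold_li(vals)
        te = exhaustive_li_threshold(vals)
        agree += int(((vals >= ti) == (vals >= te)).all())
    return {"fraction_identical": agree / n_hist}


# --------------------------------------------------------------------------
# 11. oracle equivalence


def _enumerate_mw_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p by brute-force enumeration of all labelings
    of the pooled sample (independent oracle)."""
    import itertools

    pooled = np.concatenate([a, b])
    n1 = a.size
    idx = range(pooled.size)
    us = []
    for comb in itertools.combinations(idx, n1):
        s = set(comb)
        aa = pooled[list(comb)]
        bb = pooled[[i for i in idx if i not in s]]
        ranks = stats.rankdata(np.concatenate([aa, bb]))
        us.append(float(ranks[:n1].sum() - n1 * (n1 + 1) / 2))
    us = np.asarray(us)
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    tol = 1e-9
    return min(
        1.0,
        2.0
        * min(np.mean(us <= u_obs + tol), np.mean(us >= u_obs - tol)),
    )


def mann_whitney_agreement(seed: int, n_sets: int = 60) -> dict:
    """Exact-branch p-values vs full enumeration on random small samples
    (n_a + n_b <= 10, ties included)."""
    rng = np.random.default_rng(_seed_of(seed, 13))
    n_match = 0
    for _ in range(n_sets):
        n1 = int(rng.integers(2, 6))
        n2 = int(rng.integers(2, 11 - n1))
        a = rng.integers(0, 8, n1).astype(float)
        b = rng.integers(0, 8, n2).astype(float)
        _, p = runstats.mann_whitney(a, b)
        p_oracle = _enumerate_mw_p(a, b)
        n_match += int(abs(p - p_oracle) < 1e-12)
    return {"fraction_equal": n_match / n_sets}


def _brute_force_feret(mask: np.ndarray) -> float:
    from scipy import ndimage as ndi

    boundary = mask & ~ndi.binary_erosion(mask)
    pts = np.argwhere(boundary).astype(float)
    if len(pts) < 2:
        return 0.0
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def feret_agreement(seed: int, n_masks: int = 50) -> dict:
    """Convex-hull Feret diameter vs brute-force pairwise maximum."""
    rng = np.random.default_rng(_seed_of(seed, 14))
    n_match = 0
    for _ in range(n_masks):
        mask = np.zeros((40, 40), dtype=bool)
        n_blobs = int(rng.integers(1, 4))
        for _ in range(n_blobs):
            cy, cx = rng.integers(8, 32, 2)
            r = int(rng.integers(2, 8))
            yy, xx = np.ogrid[:40, :40]
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        d_impl = astro.feret_diameter(mask)
        d_oracle = _brute_force_feret(mask)
        n_match += int(abs(d_impl - d_oracle) < 1e-9)
    return {"fraction_equal": n_match / n_masks}
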