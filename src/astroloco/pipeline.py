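"""End-to-end orchestration.

Composes the stages in acquisition-to-statistics order: temporal binning,
rigid motion correction from the red channel, patch-SVD denoising, dF/F and
active area, then the branch-specific analysis (astrocyte compartments or
neuronal unit segmentation) and the locomotion-coupling statistics.  Every
run writes its resolved configuration and a manifest next to the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity, astro, io, neuro, preprocess, runstats

logger = logging.getLogger("astroloco")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "preprocess_movies"]


@dataclass
class PipelineConfig:
    """Resolved parameters for a full pipeline run."""

    cell_type: str = "astro"  # or "neuro"
    seed: int = 0
    # preprocess
    bin_batch: int = 5
    ref_components: int = 50
    ref_sigma_px: float = 1.0
    patch_px: int = 64
    patch_overlap: int | None = None
    patch_rank: int = 8
    patch_sigma: float = 0.5
    # activity
    baseline_sigma_s: float = 15.0
    dff_threshold_pct: float = 15.0
    min_pixels: int = 16
    min_frames: int = 3
    # astro
    onset_fraction: float = 0.15
    wavelet_band: tuple[float, float] = (0.1, 0.3)
    # neuro
    nmf_patch: int = 100
    k_per_patch: int = 12
    n_final_units: int = 12
    nmf_iters: int = 60
    # runstats
    speed_thr: float = 0.5
    min_run_s: float = 1.0
    merge_gap_s: float = 0.5
    max_lag_s: float = 15.0
    paired_max_gap_s: float = 30.0
    prr_tail_s: float = 10.0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["wavelet_band"] = list(self.wavelet_band)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "wavelet_band" in d:
            d["wavelet_band"] = tuple(d["wavelet_band"])
        return cls(**d)


@dataclass
class PipelineResult:
    dff: activity.DffMovie
    active_area_pct: np.ndarray
    mean_dff_pct: np.ndarray
    episodes: runstats.EpisodeSet
    shifts: preprocess.ShiftSeries
    cells: list[astro.AstroCell] = field(default_factory=list)
    units: list[neuro.ActivityUnit] = field(default_factory=list)
    stats: dict = field(default_factory=dict)


def preprocess_movies(
    green: preprocess.Movie,
    red: preprocess.Movie,
    cfg: PipelineConfig,
    denoise: bool = True,
) -> tuple[preprocess.Movie, preprocess.Movie, preprocess.ShiftSeries]:
    """Bin both channels, estimate shifts on the denoised red channel and
    apply them to the green, then patch-SVD denoise the green channel."""
    g = preprocess.temporal_bin(green, cfg.bin_batch)
    r = preprocess.temporal_bin(red, cfg.bin_batch)
    r_dn = preprocess.denoise_reference(r, cfg.ref_components, cfg.ref_sigma_px)
    shifts = preprocess.estimate_shifts(r_dn)
    g = preprocess.apply_shifts(g, shifts)
    r = preprocess.apply_shifts(r, shifts)
    if denoise:
        g = preprocess.patch_svd_denoise(
            g, cfg.patch_px, cfg.patch_overlap, cfg.patch_rank, cfg.patch_sigma
        )
    return g, r, shifts


def _dff_from_movie(
    g: preprocess.Movie, cfg: PipelineConfig, crop_margin: int = 0
) -> activity.DffMovie:
    mask = activity.stained_mask(g.frames.mean(axis=0))
    if crop_margin > 0:
        # border pixels see replicated content while the frame drifts;
        # exclude a margin of the maximum |shift| from the analysis
        m = crop_margin
        border = np.zeros_like(mask)
        border[m:-m or None, m:-m or None] = True
        mask &= border
    f0 = activity.baseline_envelope(g.frames, g.fs, cfg.baseline_sigma_s)
    f0 = activity.mode_bias_correct(g.frames, f0)
    return activity.compute_dff(g.frames, f0, g.fs, mask)


def run_pipeline(
    cfg: PipelineConfig,
    green: preprocess.Movie,
    red: preprocess.Movie,
    speed: runstats.SpeedTrace,
    roi_masks: dict[int, dict[str, np.ndarray]] | None = None,
    out_dir: str | Path | None = None,
    denoise: bool = True,
) -> PipelineResult:
    """Run the full analysis for one recording.

    ``roi_masks`` (per-cell domain/soma masks) are required for the astro
    branch.  When ``out_dir`` is given, all per-module outputs plus the
    resolved config and a manifest are written there.
    """
    if cfg.cell_type not in ("astro", "neuro"):
        raise ValueError("cell_type must be 'astro' or 'neuro'")
    if cfg.cell_type == "astro" and not roi_masks:
        raise ValueError(
            "astro branch requires ROI masks (per-cell domain and soma)"
        )
    logger.info("preprocessing (%d raw frames)", green.n_frames)
    g, _, shifts = preprocess_movies(green, red, cfg, denoise=denoise)
    margin = int(np.abs(shifts.shifts).max())
    d = _dff_from_movie(g, cfg, crop_margin=margin)
    segs = activity.detect_active_segments(
        d, cfg.dff_threshold_pct, cfg.min_pixels, cfg.min_frames
    )
    area = activity.active_area_trace(segs, d.stained)
    mean_dff = activity.frame_mean_dff(d)

    # resample speed to the binned frame clock
    step = speed.fs / g.fs
    idx = np.clip((np.arange(g.n_frames) * step).astype(int), 0,
                  speed.speed.size - 1)
    speed_b = runstats.SpeedTrace(speed.speed[idx], g.fs)
    episodes = runstats.segment_episodes(
        speed_b, cfg.speed_thr, cfg.min_run_s, cfg.merge_gap_s
    )

    result = PipelineResult(d, area, mean_dff, episodes, shifts)

    if cfg.cell_type == "astro":
        for cid, masks in sorted(roi_masks.items()):
            result.cells.append(
                astro.analyze_cell(
                    d, cid, masks["domain"], masks["soma"],
                    pixel_size_um=green.pixel_size_um or 1.0,
                    fraction=cfg.onset_fraction, band=cfg.wavelet_band,
                )
            )
    else:
        result.units = neuro.segment_units(
            d.dff, patch=cfg.nmf_patch, k_per_patch=cfg.k_per_patch,
            n_final=cfg.n_final_units, n_iter=cfg.nmf_iters, seed=cfg.seed,
        )
        neuro.unit_classification(result.units, episodes)

    r_peak, lag = runstats.speed_dff_crosscorr(mean_dff, speed_b, cfg.max_lag_s)
    pairs = runstats.find_paired_runs(episodes, cfg.paired_max_gap_s)
    result.stats = {
        "ql_ratio_dff": runstats.ql_ratio(mean_dff, episodes),
        "ql_ratio_area": runstats.ql_ratio(area, episodes),
        "crosscorr_peak_r": r_peak,
        "crosscorr_lag_s": lag,
        "prr_dff": [
            runstats.paired_run_ratio(mean_dff, p, g.fs, cfg.prr_tail_s)
            for p in pairs
        ],
        "prr_area": [
            runstats.paired_run_ratio(area, p, g.fs, cfg.prr_tail_s)
            for p in pairs
        ],
        "n_paired_runs": len(pairs),
    }
    if out_dir is not None:
        _write_outputs(Path(out_dir), cfg, g, d, segs, area, mean_dff, result)
    return result


def _write_outputs(out, cfg, g, d, segs, area, mean_dff, result) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(cfg.to_json())
    io.write_movie(out / "dff.tif", preprocess.Movie(
        np.clip(d.dff, 0, None), d.fs, "green"))
    io.write_shifts(out / "shifts.csv", result.shifts)
    t = np.arange(g.n_frames) / g.fs
    pd.DataFrame(
        {"time_s": t, "active_area_pct": area, "mean_dff_pct": mean_dff}
    ).to_csv(out / "active_area.csv", index=False, float_format="%.6g")
    if result.cells:
        pd.DataFrame(
            [
                {
                    "cell_id": c.cell_id,
                    "latency_s": c.latency_s,
                    "soma_peak_pct": c.soma_peak_pct,
                    "proc_peak_pct": c.proc_peak_pct,
                    "soma_power": c.soma_power,
                    "proc_power": c.proc_power,
                    "feret_um": c.feret_um,
                }
                for c in result.cells
            ]
        ).to_csv(out / "astro_cells.csv", index=False, float_format="%.6g")
    if result.units:
        traces = pd.DataFrame(
            {"time_s": t}
            | {f"unit_{i+1}": u.trace for i, u in enumerate(result.units)}
        )
        traces.to_csv(out / "unit_traces.csv", index=False,
                      float_format="%.6g")
        io.write_json(
            out / "units.json",
            {
                "labels": [u.label for u in result.units],
                "members": [u.members for u in result.units],
            },
        )
    io.write_json(out / "stats.json", result.stats)
    manifest = {
        "stages": ["preprocess", "activity",
                   cfg.cell_type, "runstats"],
        "n_frames": int(g.n_frames),
        "fs_hz": float(g.fs),
        "config_sha256": hashlib.sha256(
            cfg.to_json().encode()
        ).hexdigest(),
    }
    io.write_json(out / "manifest.json", manifest)
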