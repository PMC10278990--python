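# astroloco

Analysis of two-photon Ca²⁺ imaging from cortical **astro**cytes and
neurons during **loco**motion, for labs recording GCaMP indicators in
head-fixed running mice. Astrocytes and neurons couple to locomotion in
characteristically different ways — astrocytic Ca²⁺ rises seconds after
run onset, starts in the distal processes before reaching the soma, and is
refractory to closely repeated runs, while neuronal activity tracks speed
at near-zero lag and responds reliably to every run. `astroloco`
implements the measurements that quantify these differences, from raw
two-channel movies to statistics, plus a synthetic-recording generator
with full ground truth for validating every stage.

## What it computes

* **Preprocessing** — temporal binning (Σ of 5 frames), rigid motion
  correction by phase correlation on the PCA-denoised autofluorescence
  channel, and patch-based truncated-SVD denoising under an Anscombe
  variance-stabilizing transform, x ↦ 2√(x + 3/8).
* **ΔF/F and active area** — per-pixel baseline F₀ as a smoothed lower
  envelope (running minimum, Gaussian σ = 15 s), bias-corrected so the
  residual mode is zero; ΔF/F = (F − F₀)/F₀ × 100%. Active segments are
  8-connected clusters with ΔF/F ≥ 15%, larger than 16 px, persisting with
  spatial overlap for ≥ 3 consecutive frames; the active area is the % of
  the stained field they cover per frame.
* **Astrocytes** — soma vs process ΔF/F timecourses, the soma–process
  onset latency at 15% of peak (positive = centripetal), Morlet wavelet
  band power in 0.1–0.3 Hz (slow somatic oscillations), maximum Feret
  diameter, latency-vs-size regression.
* **Neurons** — activity-unit segmentation by patchwise non-negative
  matrix factorization (HALS, 100×100 patches, 12 components/patch, global
  refinement), Li minimum-cross-entropy footprint clipping, and Ward
  merging of unit dynamics into 12 final ROIs, with
  locomotion-active/quiescent-active labelling.
* **Locomotion coupling** — episode segmentation, quiescence/locomotion
  (Q/L) activity ratio, speed–ΔF/F cross-correlation peak and lag,
  paired-run detection (< 30 s gap) and the paired-run ratio
  PRR = response₂ / response₁, Mann–Whitney U test (exact for small n).

See `docs/methods.md` for models, defaults, and numerical choices.

## Worked example

Simulate a small astrocyte recording and run the full pipeline on it:

```python
import numpy as np
from astroloco import synthdata, pipeline

cfg = synthdata.ScenarioConfig(
    duration_s=60, fov=(48, 48), n_astro=1,
    astro_domain_radius_px=18, astro_soma_radius_px=5,
    mean_quiet_s=20, paired_run_prob=0.0, seed=42,
)
rec = synthdata.simulate_recording(cfg)

masks = {cid: {"domain": rec.scene.domain_mask(cid),
               "soma": rec.scene.soma_mask(cid)}
         for cid in rec.scene.astro_ids}
result = pipeline.run_pipeline(
    pipeline.PipelineConfig(cell_type="astro"),
    rec.green, rec.red, rec.speed, roi_masks=masks,
)

cell = result.cells[0]
print(f"latency {cell.latency_s:.2f} s (truth "
      f"{rec.truth.soma_delay_s[cell.cell_id]:.1f} s)")
print(f"soma peak {cell.soma_peak_pct:.0f}% vs processes "
      f"{cell.proc_peak_pct:.0f}%")
print(f"crosscorr lag {result.stats['crosscorr_lag_s']:.2f} s, "
      f"Q/L {result.stats['ql_ratio_dff']:.3f}")
```

prints

```
latency 4.50 s (truth 4.7 s)
soma peak 368% vs processes 144%
crosscorr lag 3.17 s, Q/L 0.145
```

— the recovered centripetal latency matches the injected 4.7 s delay to
about one binned frame; the somatic response is amplified relative to the
processes (the generator injects 2.7×; compartment averaging and noise
account for the remainder); and the field ΔF/F follows the speed trace
with the expected multi-second astrocytic lag and a small
quiescence-to-locomotion activity ratio.

The same workflow runs from the shell:

```bash
astroloco simulate --seed 42 --duration 60 --fov 48 --out sim/
astroloco run --data sim/ --cell-type astro --out results/
```

ROI mask files are label TIFFs: the soma of cell *k* carries label
*k* + 1000 inside the domain labelled *k*.

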