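# Methods

`astroloco` analyses two-photon Ca²⁺ imaging of cortical astrocytes and
neurons recorded while a head-fixed mouse alternates between locomotion and
quiescence. It implements the full chain from raw two-channel movies to
locomotion-coupling statistics, together with a synthetic-movie generator
that provides ground truth for every stage. This note documents the models,
the defaults and why they were chosen, the numerical decisions, and what the
synthetic validation does and does not show.

## Analysis chain

**Temporal binning.** Raw movies (default 30 Hz) are summed in
non-overlapping batches of 5 frames, yielding 6 Hz data with ~5× more
photons per frame. Binning precedes motion correction; the generator's
drift model advances once per bin block, and in real data drift is slow
relative to 1/6 s, so mixing shifted frames within a bin is negligible.

**Rigid motion correction.** Shifts are estimated on the red
(autofluorescence) channel, which carries static morphology only. The red
stack is first denoised by projecting each frame onto its 50 leading
spatial principal components and smoothing the reconstructed frame with a
σ = 1 px Gaussian. The blur is applied to the whole reconstruction (mean
and components alike) because a Gaussian commutes with translation;
smoothing only the centred components would leave a sharp static mean that
drags the correlation peak toward zero shift. Estimation is integer-pixel
phase correlation, two-pass: frames are first registered to a designated
reference frame (a true translation of the scene), then to the median of
the aligned stack, which is robust to noise and transients. A single-pass
median of the *unaligned* stack is a blend of shifted copies and was
observed to bias the peak by ±1 px. The estimated shifts are applied to the
green channel with replicate-edge fill; downstream analysis excludes a
border margin equal to the maximum |shift|, where replicated edges create
spurious intensity jumps.

**Denoising.** The green movie is Anscombe transformed
(x ↦ 2√(x + 3/8), approximately unit-variance for Poisson counts), split
into overlapping square patches (default 64 px, 50% overlap), and each
patch's pixels × time matrix is approximated by a truncated SVD (default
rank 8). Patches are centred over time: the temporal mean averages T frames
and is nearly noise-free, so only the centred (dynamic) spatial components
are Gaussian-smoothed (default σ = 0.5 px). σ = 0.5 was selected on
synthetic movies at the default photon budget, where it removes ~85% of the
MSE against the noise-free truth; σ = 1 px over-blurs compartment
boundaries and degrades MSE below the raw data. Overlapping
reconstructions are averaged with weights that sum to one at every pixel,
and the inverse Anscombe transform is applied last.

**Baseline and ΔF/F.** Per pixel, the baseline F₀ is a lower envelope:
a running minimum over a sliding window (default length = σ_t) followed by
temporal Gaussian smoothing with σ_t = 15 s. Such an envelope is biased
low, so it is shifted per pixel by the constant that zeroes the mode of the
residuals F − F₀ — the most frequent fluctuation is noise, while true Ca²⁺
events are sparse. The mode is estimated from a histogram whose bin width
is half the robust noise SD (1.4826 × MAD); bins are centred on multiples
of the width so that an already-centred residual distribution maps to a
zero offset, making the correction idempotent up to one bin. ΔF/F =
(F − F₀)/F₀ × 100%. Stained pixels whose F₀ dips below 10% of the median
stained baseline are excluded: the ratio there amplifies noise by an order
of magnitude and contaminates every field-level statistic.

**Active area.** The stained area is an Otsu threshold of the mean image
(scale-invariant), holes filled, specks < 16 px removed. Per frame,
8-connected clusters of stained pixels with ΔF/F ≥ 15% and size strictly
greater than 16 pixels are kept; clusters in consecutive frames sharing at
least one pixel are chained, and chains spanning at least 3 distinct frames
become active segments. The active area is the percentage of the stained
area covered by validated segments in each frame. The three thresholds
(≥ 15%, > 16 px, ≥ 3 frames) are implemented bit-exactly as stated.

**Astrocyte compartments.** Each astrocyte is a manually traced domain
mask containing a soma mask; processes = domain − soma. Compartment
timecourses are mean ΔF/F per frame over each mask, peak-normalized. The
soma–process latency is the time difference between the first up-crossings
of 15% of the peak (positive = processes lead, i.e. centripetal
propagation). Oscillation prominence is the mean continuous-wavelet power
of the normalized trace over the 0.1–0.3 Hz band and the samples above 15%
of the peak; the wavelet is a complex Morlet with ω₀ = 6 (PyWavelets
`cmor1.0-0.9549`), nine frequencies spanning the band. Cell size is the
maximum Feret diameter: the largest pairwise distance between boundary
pixel centres, computed over the convex hull (brute force for degenerate
boundaries). The latency–size relation is an OLS regression (slope, R²,
two-sided p).

**Neuronal activity units.** The movie is factorized into non-negative
spatial footprints × temporal traces with no temporal-kinetics or spatial
constraint: plain NMF solved by hierarchical alternating least squares
(HALS), whose objective is monotonically non-increasing. The factorization
runs in overlapping 100 × 100 patches with 12 components (plus one flat
background component) per patch, then a second pass on the whole frame
refines the patch solution. Components are initialized by greedy seeding:
repeatedly take the pixel with the largest residual energy, extract the
local mean trace, regress the residual on it within a small window, and
subtract; random dense initializations converged to poor local optima.
Footprints are clipped with Li's minimum cross-entropy threshold on their
nonzero pixels; the clip is applied only when it separates two populations
whose means differ at least 3-fold, so re-clipping a clipped footprint is a
no-op. After clipping, a footprint is restricted to its largest connected
component (a unit is one structure; scattered speckle belongs to noise),
and components whose trace peak-to-noise ratio (peak − median, over
1.4826 × MAD) falls below 6 are discarded as noise. Surviving components
are merged by Ward agglomerative clustering of their z-scored traces into
a fixed number of final ROIs (default 12); a merged footprint is the sum of
its members, the merged trace their footprint-mass-weighted mean. Units
are labelled locomotion-active or quiescent-active by comparing mean
activity in the two behavioural states.

**Locomotion statistics.** Episodes are segmented by thresholding the
smoothed speed (defaults: 0.5 cm/s threshold, 0.25 s smoothing, gaps
< 0.5 s merged, runs < 1 s dropped); the defaults are exposed in the
config since no standard exists. Q/L is the mean activity over all
quiescence time divided by the mean over all locomotion time. The
speed–ΔF/F cross-correlation computes, for every lag within ±15 s, the
Pearson correlation of the overlapping samples, so the peak lies in
[−1, 1] and an exactly delayed copy scores r = 1 at its delay; positive
lag means activity follows speed. Paired runs are consecutive locomotion
episodes separated by strictly less than 30 s of quiescence, paired
greedily left-to-right. The paired-run ratio (PRR) is the second response
over the first, where a response is the peak (default; the mean is also
computed) of the trace from episode onset to offset + 10 s — the tail
accommodates the several-second astrocytic lag. The Mann–Whitney U test
enumerates the full null distribution of U over all labelings of the
pooled sample when n₁ + n₂ ≤ 12 (exact even under ties; two-sided p =
2·min(P(U ≤ u), P(U ≥ u)) capped at 1) and otherwise uses the
tie-corrected normal approximation with continuity correction.

## Synthetic recordings

The generator emulates the phenomenology the pipeline is designed to
measure. Study-scale defaults are 600 s at 30 Hz, 512 × 512 px,
0.8 µm/px.

* **Behaviour.** Runs (mean 12 s, raised-cosine edges, peak 6–14 cm/s)
  alternate with quiescence (mean 60 s). With probability 0.3 a run is
  followed by a paired run after ~20 s (< 30 s by construction); unpaired
  gaps exceed 31 s, so pairing is unambiguous.
* **Astrocytes.** Star-shaped domains (soma disk + 6–8 tapering radial
  arms) placed on a jittered grid. Ca²⁺ transients are
  difference-of-exponentials (rise 1.5 s, decay 6 s). The process
  compartment responds 2.5 s after run onset with peak ΔF/F 170%; the
  soma follows after a centripetal delay (default 4.7 s, or derived from
  domain radius / centripetal speed when a speed is configured) with a
  2.7× amplified peak. A 0.2 Hz oscillation (depth 0.4) is windowed onto
  the somatic plateau — it begins after the transient peak and dips below
  the envelope — so the 15%-of-peak onset crossings and the peak itself
  are untouched and injected delays remain recoverable. A run starting
  < 30 s after the previous one responds at α × the previous amplitude
  (depletion, default α = 0.35); recovery is complete otherwise. Sparse
  small events (amplitude 8% ΔF/F) on a random 15% subset of process
  pixels provide quiescent activity.
* **Neurons.** Elongated curvilinear footprints. Locomotion-active units
  follow the speed envelope through a fast kernel (rise 0.05 s, decay
  0.3 s) at ~zero lag, with strong per-run amplitude variability
  (×0.5–1.5) and a 15% chance of failing a run (with at least one full response guaranteed per unit, since a unit silent through every run is undetectable by construction) — as unit timecourses in
  awake recordings do; this variability is also what makes units with
  shared drive separable by their dynamics. Quiescent-active units (half
  of all units) fire Poisson transients at 0.8 Hz during quiescence. The
  quiescent-side parameters were calibrated once so that field-level Q/L
  ratios fall near the values reported for cortical neurons (~0.2) and
  astrocytes (~0.07–0.15).
* **Imaging.** Structures are painted onto a spatially correlated
  log-normal texture (1.5 px correlation length) and blurred by a 0.6 px
  Gaussian PSF — sharp binary structures are an artefact no microscope
  produces, and they distort any judgement of spatial smoothing. The
  camera applies a shared integer random-walk drift (clipped at
  ±max_shift, advancing once per bin block so every binned frame carries
  one recoverable shift), then counts = gain · Poisson(x/gain) + read
  noise (variance = gain·mean + σ_read²), rounded to uint16. With gain
  and read noise zero the output equals the input exactly.

**What the generator does not model:** neuropil and vascular background,
photobleaching, non-rigid (within-frame) distortion, spatially propagating
subcellular wavefronts within the process arbour (onset is uniform across
processes; centripetal delay applies at the compartment level), astrocyte
morphological diversity beyond the star model, and correlated noise between
channels. Passing the synthetic battery therefore demonstrates correctness
of the implemented computations under the stated forward model, not
robustness to every artefact of real recordings.

## Validation battery and problem sizes

`scripts/acceptance.py` (and the mirror tests in
`tests/test_acceptance.py`) re-runs the full battery from scratch at a
given seed. Spatial/temporal sizes are reduced — 40–64 px fields, 25–300 s
recordings, 2–3 movies or 20–80 scenes per experiment — which keeps the
whole battery within minutes on one core while leaving every recovery
target measurable; the kinetic, noise and threshold parameters are the
defaults above. The experiments: exact recovery of injected drift
(10 movies); ≥ 50% MSE reduction by the denoising chain; envelope-baseline
and transient-peak recovery on constructed traces; bit-exact behaviour of
the three active-segment rules; recovery of injected centripetal delays
{1, 2, 5, 10 s} within one binned frame (noise-free) and 0.5 s (default
noise) on 20 cells; soma > process band power on > 95% of 40 oscillating
cells; cross-correlation lag recovery within one sample; median PRR within
±0.1 of injected α ∈ {0.25, 0.5, 0.75, 1}; astro-vs-neuro Q/L and lag
contrasts with the package's own rank test (20 scenes per group); 6-unit
factorization recovery (footprint Jaccard, trace correlation — matched by
Hungarian assignment against the optically blurred footprints the movie
actually contains, with the pipeline's own Li support rule applied to truth
and estimate alike); and equality of the exact Mann–Whitney branch with
full enumeration and of the Feret diameter with a brute-force pairwise
maximum.

## Known limitations

* Motion correction is integer-pixel; sub-pixel drift leaves up to half a
  pixel of residual jitter.
* The NMF is a local optimizer; units whose traces are nearly collinear
  (correlation → 1) are not separable by any factorization and merge.
* The exact Mann–Whitney branch enumerates C(n, n₁) labelings and is
  limited to n₁ + n₂ ≤  12 by default.
* Li's iterative threshold can diverge from the global cross-entropy
  minimum when the bright mode holds only a few percent of the pixels; the
  clipping guard skips such degenerate splits rather than resolving them.
* The latency search uses the first 15% up-crossing of the whole
  normalized trace; recordings with multiple episodes measure the first
  strong response rather than a per-episode average.
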