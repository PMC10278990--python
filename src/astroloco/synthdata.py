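"""Synthetic two-photon recordings with full ground truth.

Generates two-channel movies (green = Ca2+ indicator, red = static
autofluorescence morphology), an alternating run/quiescence speed trace, and
label masks, emulating the phenomenology of layer-1 cortical recordings in a
head-fixed running mouse:

* astrocytes respond to locomotion with a lag of a few seconds, the response
  rising in the processes first and reaching the soma after a centripetal
  delay, amplified in the soma and carrying a slow (0.1-0.3 Hz) oscillation
  on the somatic plateau;
* the astrocytic response to the second of two closely spaced runs
  (< 30 s gap) is depleted by a factor alpha;
* neuronal processes respond at near-zero lag, follow the speed envelope,
  respond equally to every run, and a fraction of units is instead active
  during quiescence;
* the camera applies a rigid random-walk drift (identical in both channels)
  and Poisson-Gaussian photon/read noise.

Every generated quantity is recorded in :class:`GroundTruth` so downstream
stages have parameter-recovery targets.  All generators are pure functions of
the configuration (including its seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .preprocess import Movie
from .runstats import SpeedTrace

__all__ = [
    "ScenarioConfig",
    "Scene",
    "GroundTruth",
    "SimulatedRecording",
    "generate_speed_trace",
    "generate_scene",
    "simulate_fluorescence",
    "apply_camera",
    "simulate_recording",
]


class PlacementError(RuntimeError):
    """Raised when the requested cells cannot be placed in the field of view."""


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic recording session.

    Defaults reproduce the acquisition conditions of the emulated
    experiments: 10 min at 30 Hz, 512x512 pixels.  Smaller fields and shorter
    durations may be passed for fast tests; the kinetic parameters are
    independent of the spatial/temporal extent.
    """

    duration_s: float = 600.0
    fs_raw: float = 30.0
    fov: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.8
    n_astro: int = 4
    n_neuro_units: int = 0
    seed: int = 0

    # episode model
    mean_run_s: float = 12.0
    mean_quiet_s: float = 60.0
    paired_run_prob: float = 0.3
    paired_gap_s: float = 20.0  # must stay < 30 s to qualify as a pair

    # astrocyte morphology (pixels)
    astro_domain_radius_px: int = 30
    astro_soma_radius_px: int = 7

    # astrocyte kinetics
    astro_onset_lag_s: float = 2.5
    soma_delay_s: float = 4.7
    centripetal_speed_um_s: float | None = None  # overrides soma_delay_s
    soma_amplification: float = 2.7
    osc_freq_hz: float = 0.2
    osc_depth: float = 0.4
    depletion_alpha: float = 0.35
    astro_rise_s: float = 1.5
    astro_decay_s: float = 6.0
    proc_peak_dff: float = 1.7  # fractional dF/F (1.7 = 170%)
    quiescent_event_rate_hz: float = 0.02  # astro micro-events, per cell
    quiescent_event_amp: float = 0.08

    # neuronal kinetics
    neuro_len_px: int = 25
    neuro_lag_s: float = 0.0
    neuro_rise_s: float = 0.05
    neuro_decay_s: float = 0.3
    neuro_peak_dff: float = 0.8
    quiescent_active_fraction: float = 0.5
    quiescent_rate_hz: float = 0.8  # transients of quiescent-active units
    quiescent_amp_frac: float = 1.0  # their amplitude vs locomotion units

    # imaging / camera
    baseline_level: float = 100.0
    background_level: float = 10.0
    red_level: float = 80.0
    psf_sigma_px: float = 0.6  # optical point-spread blur
    photon_gain: float = 1.0
    read_noise_sd: float = 1.5
    max_shift_px: int = 3
    shift_step_frames: int = 5  # drift advances once per binning block

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs_raw <= 0:
            raise ValueError("duration_s and fs_raw must be positive")
        if not 0.0 < self.depletion_alpha <= 1.0:
            raise ValueError("depletion_alpha must lie in (0, 1]")
        if not 0.1 <= self.osc_freq_hz <= 0.3:
            raise ValueError("osc_freq_hz must lie in [0.1, 0.3] Hz")
        if self.n_astro < 0 or self.n_neuro_units < 0:
            raise ValueError("cell counts must be >= 0")
        if not 0.0 <= self.paired_run_prob <= 1.0:
            raise ValueError("paired_run_prob must lie in [0, 1]")
        if self.paired_gap_s >= 30.0:
            raise ValueError("paired_gap_s must be < 30 s")
        if self.photon_gain < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def n_samples_raw(self) -> int:
        return int(round(self.duration_s * self.fs_raw))

    def to_json(self) -> str:
        d = asdict(self)
        d["fov"] = list(self.fov)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        d = json.loads(text)
        d["fov"] = tuple(d["fov"])
        return cls(**d)

    @classmethod
    def neuro_default(cls, **kw) -> "ScenarioConfig":
        kw.setdefault("n_astro", 0)
        kw.setdefault("n_neuro_units", 12)
        return cls(**kw)


@dataclass
class Scene:
    """Static morphology: label masks and neuronal footprints."""

    astro_domain_labels: np.ndarray  # (H, W) int, 0 = background
    astro_soma_labels: np.ndarray
    astro_micro_masks: list[np.ndarray]  # per cell, subset of processes
    neuro_footprints: list[np.ndarray]  # per unit, (H, W) float, peak 1
    stained_mask: np.ndarray  # (H, W) bool
    astro_centers: list[tuple[int, int]]
    astro_radius_px: list[float]

    @property
    def astro_ids(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.astro_domain_labels) if v)

    def domain_mask(self, cell_id: int) -> np.ndarray:
        return self.astro_domain_labels == cell_id

    def soma_mask(self, cell_id: int) -> np.ndarray:
        return self.astro_soma_labels == cell_id

    def processes_mask(self, cell_id: int) -> np.ndarray:
        return self.domain_mask(cell_id) & ~self.soma_mask(cell_id)


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis should recover."""

    run_intervals: list[tuple[float, float]]  # (start_s, end_s)
    paired_intervals: list[tuple[int, int]]  # indices into run_intervals
    depletion_alpha: float
    soma_delay_s: dict[int, float]  # per astro cell
    onset_lag_s: float
    run_amplitudes: dict[int, list[float]]  # per astro cell, per run
    astro_proc_traces: dict[int, np.ndarray]  # fractional dF/F at fs_raw
    astro_soma_traces: dict[int, np.ndarray]
    neuro_traces: list[np.ndarray]
    neuro_labels: list[str]  # "locomotion" or "quiescent"
    neuro_effective_footprints: list[np.ndarray] = field(default_factory=list)
    # ^ PSF-blurred, intensity-weighted footprints as present in the movie,
    #   peak-normalized: the support a segmentation can actually recover
    shifts: np.ndarray | None = None  # (T, 2) content displacement, px


@dataclass
class SimulatedRecording:
    cfg: ScenarioConfig
    scene: Scene
    speed: SpeedTrace
    green: Movie  # noisy
    red: Movie  # noisy
    clean_green: Movie
    clean_red: Movie
    truth: GroundTruth


# --------------------------------------------------------------------------
# speed / episodes


def _run_profile(n: int, fs: float, peak: float) -> np.ndarray:
    """Speed bump with half-cosine ramps (~0.5 s) and a flat plateau."""
    ramp = min(int(round(0.5 * fs)), max(n // 4, 1))
    prof = np.full(n, peak)
    up = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp)))
    prof[:ramp] *= up
    prof[n - ramp :] *= up[::-1]
    return prof


def generate_speed_trace(
    cfg: ScenarioConfig,
) -> tuple[SpeedTrace, list[tuple[float, float]], list[tuple[int, int]]]:
    """Alternating run/quiescence speed trace.

    Returns the trace, the true run intervals, and the index pairs of runs
    generated as close pairs (gap < 30 s).  Unpaired consecutive runs are
    separated by more than 30 s by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples_raw
    fs = cfg.fs_raw
    speed = np.zeros(n)
    runs: list[tuple[float, float]] = []
    pairs: list[tuple[int, int]] = []

    t = max(5.0, rng.uniform(0.5, 1.0) * cfg.mean_quiet_s)
    while True:
        run_len = cfg.mean_run_s * rng.uniform(0.7, 1.3)
        if t + run_len > cfg.duration_s - 1.0:
            break
        runs.append((t, t + run_len))
        t += run_len
        if rng.random() < cfg.paired_run_prob:
            gap = min(cfg.paired_gap_s * rng.uniform(0.85, 1.1), 29.0)
            run2 = cfg.mean_run_s * rng.uniform(0.7, 1.3)
            if t + gap + run2 <= cfg.duration_s - 1.0:
                runs.append((t + gap, t + gap + run2))
                pairs.append((len(runs) - 2, len(runs) - 1))
                t += gap + run2
        t += max(31.0, rng.exponential(cfg.mean_quiet_s))

    for a, b in runs:
        i0, i1 = int(round(a * fs)), int(round(b * fs))
        speed[i0:i1] = _run_profile(i1 - i0, fs, rng.uniform(6.0, 14.0))
    return SpeedTrace(speed, fs), runs, pairs


# --------------------------------------------------------------------------
# scene


def _disk(shape: tuple[int, int], cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _star_domain(
    shape: tuple[int, int],
    cy: int,
    cx: int,
    soma_r: int,
    dom_r: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Soma disk plus radial tapering arms; returns (domain, soma) masks."""
    soma = _disk(shape, cy, cx, soma_r)
    domain = soma.copy()
    n_arm = int(rng.integers(6, 9))
    angles = np.linspace(0, 2 * np.pi, n_arm, endpoint=False)
    angles += rng.uniform(-0.15, 0.15, n_arm)
    for ang in angles:
        length = dom_r * rng.uniform(0.75, 1.0)
        for frac in np.linspace(0.0, 1.0, int(2 * length)):
            rr = soma_r * 0.5 + frac * (length - soma_r * 0.5)
            y = cy + rr * np.sin(ang)
            x = cx + rr * np.cos(ang)
            width = max(1.0, 3.0 * (1.0 - 0.7 * frac))
            domain |= _disk(shape, y, x, width)
    return domain, soma


def _grid_centers(
    shape: tuple[int, int], n: int, spacing: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    h, w = shape
    ny, nx = h // spacing, w // spacing
    if ny * nx < n:
        raise PlacementError(
            f"cannot place {n} cells of spacing {spacing} px in a "
            f"{h}x{w} field (capacity {ny * nx})"
        )
    cells = [(i, j) for i in range(ny) for j in range(nx)]
    rng.shuffle(cells)
    centers = []
    for i, j in cells[:n]:
        cy = i * spacing + spacing // 2 + int(rng.integers(-2, 3))
        cx = j * spacing + spacing // 2 + int(rng.integers(-2, 3))
        centers.append((int(np.clip(cy, 2, h - 3)), int(np.clip(cx, 2, w - 3))))
    return centers


def _curvilinear_footprint(
    shape: tuple[int, int], cy: int, cx: int, length: int, rng: np.random.Generator
) -> np.ndarray:
    """Elongated process-like footprint: a smoothed random-curvature path."""
    h, w = shape
    img = np.zeros(shape)
    ang = rng.uniform(0, 2 * np.pi)
    y, x = float(cy), float(cx)
    for _ in range(length):
        ang += rng.normal(0, 0.25)
        y = float(np.clip(y + np.sin(ang), 1, h - 2))
        x = float(np.clip(x + np.cos(ang), 1, w - 2))
        img[int(round(y)), int(round(x))] = 1.0
    img = ndimage.gaussian_filter(img, 1.0)
    if img.max() > 0:
        img /= img.max()
    img[img < 0.05] = 0.0
    return img


def generate_scene(cfg: ScenarioConfig) -> Scene:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    shape = tuple(cfg.fov)
    dom_lbl = np.zeros(shape, dtype=np.int32)
    soma_lbl = np.zeros(shape, dtype=np.int32)
    micro_masks: list[np.ndarray] = []
    centers: list[tuple[int, int]] = []
    radii: list[float] = []

    if cfg.n_astro > 0:
        spacing = 2 * cfg.astro_domain_radius_px + 4
        centers = _grid_centers(shape, cfg.n_astro, spacing, rng)
        for k, (cy, cx) in enumerate(centers, start=1):
            domain, soma = _star_domain(
                shape, cy, cx, cfg.astro_soma_radius_px,
                cfg.astro_domain_radius_px, rng,
            )
            domain &= dom_lbl == 0  # disjoint by construction; belt-and-braces
            soma &= domain
            dom_lbl[domain] = k
            soma_lbl[soma] = k
            proc = domain & ~soma
            micro = proc & (rng.random(shape) < 0.15)
            micro_masks.append(micro)
            ys, xs = np.nonzero(domain)
            radii.append(float(np.hypot(ys - cy, xs - cx).max()))

    footprints: list[np.ndarray] = []
    if cfg.n_neuro_units > 0:
        spacing = max(cfg.neuro_len_px + 6, 12)
        ncenters = _grid_centers(shape, cfg.n_neuro_units, spacing, rng)
        for cy, cx in ncenters:
            footprints.append(
                _curvilinear_footprint(shape, cy, cx, cfg.neuro_len_px, rng)
            )

    stained = dom_lbl > 0
    for fp in footprints:
        stained |= fp > 0
    return Scene(dom_lbl, soma_lbl, micro_masks, footprints, stained,
                 centers, radii)


# --------------------------------------------------------------------------
# fluorescence dynamics


def _dexp_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalized, zero for t < 0."""
    tp = np.clip(t, 0.0, None)
    k = np.where(t >= 0, np.exp(-tp / decay_s) - np.exp(-tp / rise_s), 0.0)
    peak = k.max()
    return k / peak if peak > 0 else k


def _dexp_peak_time(rise_s: float, decay_s: float) -> float:
    return (
        np.log(decay_s / rise_s) * rise_s * decay_s / (decay_s - rise_s)
        if decay_s != rise_s
        else rise_s
    )


def _smoothstep(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    u = np.clip((t - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)
    return u * u * (3 - 2 * u)


def _astro_run_amplitudes(
    runs: list[tuple[float, float]], alpha: float
) -> list[float]:
    """Depletion: a run starting < 30 s after the previous run's end responds
    at alpha times the previous amplitude; otherwise recovery is complete."""
    amps: list[float] = []
    for i, (a, _) in enumerate(runs):
        if i > 0 and a - runs[i - 1][1] < 30.0:
            amps.append(amps[-1] * alpha)
        else:
            amps.append(1.0)
    return amps


def _quiescence_intervals(
    runs: list[tuple[float, float]], duration_s: float
) -> list[tuple[float, float]]:
    out = []
    t = 0.0
    for a, b in runs:
        if a > t:
            out.append((t, a))
        t = b
    if duration_s > t:
        out.append((t, duration_s))
    return out


def simulate_fluorescence(
    cfg: ScenarioConfig,
    scene: Scene,
    speed: SpeedTrace,
    run_intervals: list[tuple[float, float]],
    pairs: list[tuple[int, int]] | None = None,
) -> tuple[Movie, Movie, GroundTruth]:
    """Noise-free two-channel movie plus ground truth.

    Green carries the Ca2+ dynamics as fractional dF/F modulations of a
    textured static baseline; red carries the static morphology only.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n = cfg.n_samples_raw
    fs = cfg.fs_raw
    t = np.arange(n) / fs
    shape = tuple(cfg.fov)

    amps = _astro_run_amplitudes(run_intervals, cfg.depletion_alpha)
    quiet = _quiescence_intervals(run_intervals, cfg.duration_s)
    t_pk = _dexp_peak_time(cfg.astro_rise_s, cfg.astro_decay_s)

    soma_delay: dict[int, float] = {}
    proc_traces: dict[int, np.ndarray] = {}
    soma_traces: dict[int, np.ndarray] = {}
    micro_traces: dict[int, np.ndarray] = {}
    run_amp: dict[int, list[float]] = {}

    for idx, cid in enumerate(scene.astro_ids):
        if cfg.centripetal_speed_um_s is not None:
            delay = (
                scene.astro_radius_px[idx]
                * cfg.pixel_size_um
                / cfg.centripetal_speed_um_s
            )
        else:
            delay = cfg.soma_delay_s
        soma_delay[cid] = delay
        proc = np.zeros(n)
        soma = np.zeros(n)
        cell_amps = [a * rng.uniform(0.95, 1.05) for a in amps]
        run_amp[cid] = cell_amps
        for (a, _), amp in zip(run_intervals, cell_amps):
            t0 = a + cfg.astro_onset_lag_s
            proc += amp * cfg.proc_peak_dff * _dexp_kernel(
                t - t0, cfg.astro_rise_s, cfg.astro_decay_s
            )
            ts = t0 + delay
            env = _dexp_kernel(t - ts, cfg.astro_rise_s, cfg.astro_decay_s)
            # oscillation lives on the plateau (after the transient peak) and
            # dips below the envelope, leaving onset and peak untouched
            w = _smoothstep(t, ts + 0.8 * t_pk, ts + 1.6 * t_pk)
            osc = 1.0 - 0.5 * cfg.osc_depth * w * (
                1.0 - np.sin(2 * np.pi * cfg.osc_freq_hz * (t - ts))
            )
            soma += amp * cfg.soma_amplification * cfg.proc_peak_dff * env * osc
        # sparse small events during quiescence (micro-domain activity)
        micro = np.zeros(n)
        for q0, q1 in quiet:
            n_ev = rng.poisson(cfg.quiescent_event_rate_hz * (q1 - q0))
            for te in rng.uniform(q0, q1, n_ev):
                micro += cfg.quiescent_event_amp * _dexp_kernel(
                    t - te, 0.5, 2.0
                )
        proc_traces[cid] = proc
        soma_traces[cid] = soma
        micro_traces[cid] = micro

    # neuronal units: near-zero-lag speed followers vs quiescent-active
    n_kernel = _dexp_kernel(
        np.arange(0, 5 * cfg.neuro_decay_s, 1 / fs),
        cfg.neuro_rise_s,
        cfg.neuro_decay_s,
    )
    n_kernel_area = n_kernel / n_kernel.sum()
    run_indicator = np.zeros(n)
    for a, b in run_intervals:
        run_indicator[int(round(a * fs)) : int(round(b * fs))] = 1.0
    lag_samp = int(round(cfg.neuro_lag_s * fs))

    n_units = len(scene.neuro_footprints)
    n_quiescent = int(round(cfg.quiescent_active_fraction * n_units))
    quiescent_set = set(rng.permutation(n_units)[:n_quiescent].tolist())
    neuro_traces: list[np.ndarray] = []
    neuro_labels: list[str] = []
    for u in range(n_units):
        q = np.zeros(n)
        if u in quiescent_set:
            amp = cfg.quiescent_amp_frac * cfg.neuro_peak_dff
            for q0, q1 in quiet:
                n_ev = rng.poisson(cfg.quiescent_rate_hz * (q1 - q0))
                for te in rng.uniform(q0, q1, n_ev):
                    q += amp * rng.uniform(0.6, 1.0) * _dexp_kernel(
                        t - te, cfg.neuro_rise_s, cfg.neuro_decay_s
                    )
            neuro_labels.append("quiescent")
        else:
            # units respond to each run with strong amplitude variability
            # and occasional failures (as seen in unit timecourses of awake
            # recordings); this is also what makes their dynamics
            # distinguishable to trace-based merging
            q = np.zeros(n)
            amps = []
            for a, b in run_intervals:
                fail = rng.random() < 0.15
                amp = 0.0 if fail else rng.uniform(0.5, 1.5)
                amps.append(amp)
            if run_intervals and max(amps) < 0.5:
                # a unit silent through every run would be undetectable by
                # construction; guarantee at least one full response
                amps[int(rng.integers(len(amps)))] = 1.0
            for (a, b), amp in zip(run_intervals, amps):
                if amp == 0.0:
                    continue
                ind = np.zeros(n)
                ind[int(round(a * fs)) : int(round(b * fs))] = 1.0
                resp = np.convolve(ind, n_kernel_area)[:n]
                q += cfg.neuro_peak_dff * amp * resp
            if lag_samp > 0:
                q = np.concatenate([np.zeros(lag_samp), q[:-lag_samp]])
            # faint residual activity between runs
            for q0, q1 in quiet:
                n_ev = rng.poisson(0.02 * (q1 - q0))
                for te in rng.uniform(q0, q1, n_ev):
                    q += 0.2 * cfg.neuro_peak_dff * _dexp_kernel(
                        t - te, cfg.neuro_rise_s, cfg.neuro_decay_s
                    )
            neuro_labels.append("locomotion")
        neuro_traces.append(q)

    # static images: textured so that registration has features to lock
    # onto; the texture is spatially correlated (as real morphology is),
    # so it survives the sigma ~ 1 px smoothing of the reference denoiser
    texture = np.exp(
        ndimage.gaussian_filter(rng.normal(0.0, 0.45, shape), 1.5)
    )
    structures = (scene.stained_mask).astype(float)

    def _psf(img: np.ndarray) -> np.ndarray:
        # optical point-spread blur; applied to the static base and to each
        # compartment weight image, which keeps the movie separable
        if cfg.psf_sigma_px > 0:
            return ndimage.gaussian_filter(img, cfg.psf_sigma_px)
        return img

    base_green = _psf(
        cfg.background_level + cfg.baseline_level * structures * texture
    )
    base_red = _psf(
        cfg.background_level + cfg.red_level * structures * texture
    )
    raw_green = (
        cfg.background_level + cfg.baseline_level * structures * texture
    )

    green = np.empty((n, *shape), dtype=np.float32)
    green[:] = base_green[None, :, :].astype(np.float32)

    def _add(mask_or_weight: np.ndarray, trace: np.ndarray) -> np.ndarray:
        w = _psf(mask_or_weight * raw_green)
        sup = w > 1e-6
        if sup.any():
            green[:, sup] += (
                trace[:, None] * w[sup][None, :]
            ).astype(np.float32)
        return w

    for idx, cid in enumerate(scene.astro_ids):
        _add(scene.processes_mask(cid).astype(float), proc_traces[cid])
        _add(scene.soma_mask(cid).astype(float), soma_traces[cid])
        _add(scene.astro_micro_masks[idx].astype(float), micro_traces[cid])
    effective_fps = []
    for fp, q in zip(scene.neuro_footprints, neuro_traces):
        w = _add(fp, q)
        effective_fps.append(w / w.max() if w.max() > 0 else w)

    red = np.repeat(base_red[None].astype(np.float32), n, axis=0)
    truth = GroundTruth(
        run_intervals=run_intervals,
        paired_intervals=pairs or [],
        depletion_alpha=cfg.depletion_alpha,
        soma_delay_s=soma_delay,
        onset_lag_s=cfg.astro_onset_lag_s,
        run_amplitudes=run_amp,
        astro_proc_traces=proc_traces,
        astro_soma_traces=soma_traces,
        neuro_traces=neuro_traces,
        neuro_labels=neuro_labels,
        neuro_effective_footprints=effective_fps,
    )
    g = Movie(green, fs, "green", cfg.pixel_size_um)
    r = Movie(red, fs, "red", cfg.pixel_size_um)
    return g, r, truth


# --------------------------------------------------------------------------
# camera


def generate_shifts(cfg: ScenarioConfig, n_frames: int) -> np.ndarray:
    """Integer random-walk rigid drift clipped to +/- max_shift_px.

    The walk advances once per ``shift_step_frames`` block (default = the
    temporal binning batch), so every binned frame carries a single,
    exactly recoverable shift.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    if cfg.max_shift_px == 0:
        return np.zeros((n_frames, 2))
    step = max(1, cfg.shift_step_frames)
    n_blocks = int(np.ceil(n_frames / step))
    steps = rng.integers(-1, 2, size=(n_blocks, 2)).astype(float)
    steps[0] = 0
    walk = np.clip(np.cumsum(steps, axis=0), -cfg.max_shift_px,
                   cfg.max_shift_px)
    return np.repeat(walk, step, axis=0)[:n_frames]


def apply_camera(
    clean: Movie,
    cfg: ScenarioConfig,
    shifts: np.ndarray | None = None,
    noise_seed_tag: int = 4,
) -> tuple[Movie, np.ndarray]:
    """Rigid drift plus Poisson-Gaussian photon noise.

    ``shifts`` (content displacement per frame) should be shared between the
    two channels of a recording; when None they are generated from the
    config.  With ``photon_gain == 0`` and ``read_noise_sd == 0`` the output
    equals the (shifted) input exactly.
    """
    if shifts is None:
        shifts = generate_shifts(cfg, clean.n_frames)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, noise_seed_tag])
    )
    out = np.empty(clean.frames.shape, dtype=np.float32)
    for i, frame in enumerate(clean.frames):
        dy, dx = shifts[i]
        if dy or dx:
            out[i] = ndimage.shift(frame, (dy, dx), order=0, mode="nearest")
        else:
            out[i] = frame
    noiseless = cfg.photon_gain == 0 and cfg.read_noise_sd == 0
    if not noiseless:
        if cfg.photon_gain > 0:
            lam = out if cfg.photon_gain == 1 else out / cfg.photon_gain
            out = rng.poisson(lam).astype(np.float32)
            if cfg.photon_gain != 1:
                out *= cfg.photon_gain
        if cfg.read_noise_sd > 0:
            out += rng.standard_normal(out.shape, dtype=np.float32) * np.float32(
                cfg.read_noise_sd
            )
        np.rint(out, out=out)
        out = np.clip(out, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return clean.with_frames(out), np.asarray(shifts, dtype=float)


def simulate_recording(cfg: ScenarioConfig) -> SimulatedRecording:
    """End-to-end generator: speed, scene, clean movies, camera, truth."""
    speed, runs, pairs = generate_speed_trace(cfg)
    scene = generate_scene(cfg)
    green_clean, red_clean, truth = simulate_fluorescence(
        cfg, scene, speed, runs, pairs
    )
    shifts = generate_shifts(cfg, green_clean.n_frames)
    green, _ = apply_camera(green_clean, cfg, shifts, noise_seed_tag=4)
    red, _ = apply_camera(red_clean, cfg, shifts, noise_seed_tag=5)
    truth.shifts = shifts
    return SimulatedRecording(
        cfg, scene, speed, green, red, green_clean, red_clean, truth
    )
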