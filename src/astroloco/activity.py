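"""Pixel-wise dF/F and active-area event detection.

The baseline F0 is a lower envelope running through the local minima of each
pixel's fluorescence trace (running minimum over a sliding window, then
Gaussian smoothing with sigma = 15 s).  Because such an envelope is
negatively biased, it is shifted per pixel by the constant that zeroes the
mode of the residuals: the most frequent fluctuations are noise while real
Ca2+ events are sparse, so the residual mode marks the noise floor offset.

Activity is then summarized by "active segments" -- connected clusters of
pixels with dF/F >= 15% that are larger than 16 pixels within a frame and
overlap spatially across at least 3 consecutive frames -- and by the "active
area", the percentage of the stained field covered by validated segments in
each frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import filters

from .preprocess import Movie

__all__ = [
    "DffMovie",
    "ActiveSegmentSet",
    "baseline_envelope",
    "mode_bias_correct",
    "compute_dff",
    "stained_mask",
    "detect_active_segments",
    "active_area_trace",
    "frame_mean_dff",
]


@dataclass
class DffMovie:
    """Per-pixel relative fluorescence change in percent."""

    dff: np.ndarray  # (T, H, W), percent
    fs: float
    stained: np.ndarray  # (H, W) bool
    f0: np.ndarray | None = None  # (T, H, W) baseline

    def __post_init__(self) -> None:
        if self.dff.ndim != 3:
            raise ValueError("dff must be (T, H, W)")
        if self.stained.shape != self.dff.shape[1:]:
            raise ValueError("stained mask shape mismatch")

    @property
    def n_frames(self) -> int:
        return self.dff.shape[0]


@dataclass
class ActiveSegmentSet:
    """Validated suprathreshold clusters linked over consecutive frames."""

    labels: np.ndarray  # (T, H, W) int32, 0 = background, else segment id
    summary: pd.DataFrame  # per segment: id, first/last frame, total pixels

    @property
    def n_segments(self) -> int:
        return len(self.summary)

    def active_mask(self) -> np.ndarray:
        return self.labels > 0


def baseline_envelope(
    f: np.ndarray, fs: float, sigma_t: float = 15.0, window_s: float | None = None
) -> np.ndarray:
    """Lower-envelope baseline per pixel.

    Running minimum over a sliding window (default length = ``sigma_t``)
    followed by temporal Gaussian smoothing with sigma ``sigma_t`` seconds.
    ``f`` is (T, ...) with time on axis 0.
    """
    f = np.asarray(f, dtype=float)
    if f.shape[0] < 3:
        raise ValueError("need at least 3 frames to estimate a baseline")
    if window_s is None:
        window_s = sigma_t
    win = max(3, int(round(window_s * fs)))
    win = min(win, f.shape[0])
    env = ndimage.minimum_filter1d(f, size=win, axis=0, mode="nearest")
    return ndimage.gaussian_filter1d(
        env, sigma=sigma_t * fs, axis=0, mode="nearest"
    )


def _residual_mode(res: np.ndarray) -> np.ndarray:
    """Histogram mode of residuals along axis 0, with bin width half the
    MAD-based robust noise SD (per pixel).  ``res`` is (T, P)."""
    med = np.median(res, axis=0)
    mad = np.median(np.abs(res - med), axis=0)
    bw = np.maximum(0.5 * 1.4826 * mad, 1e-12)
    # bins centred on multiples of bw, so an already-centred residual
    # distribution maps to offset zero (makes the correction idempotent)
    bins = np.floor(res / bw + 0.5).astype(np.int64)
    mode_bin = stats.mode(bins, axis=0, keepdims=False).mode
    return mode_bin * bw


def mode_bias_correct(f: np.ndarray, f0: np.ndarray) -> np.ndarray:
    """Shift the baseline per pixel so the mode of the residuals is ~0."""
    f = np.asarray(f, dtype=float)
    f0 = np.broadcast_to(np.asarray(f0, dtype=float), f.shape)
    res = (f - f0).reshape(f.shape[0], -1)
    spread = res.max(axis=0) - res.min(axis=0)
    offset = np.where(spread > 0, _residual_mode(res), res[0])
    return f0 + offset.reshape(f.shape[1:])


def compute_dff(
    f: np.ndarray,
    f0: np.ndarray,
    fs: float,
    stained: np.ndarray,
    f0_floor_frac: float = 0.1,
) -> DffMovie:
    """dF/F = (F - F0) / F0 * 100%, masked to stained pixels.

    Stained pixels where F0 is non-positive -- or dips below
    ``f0_floor_frac`` times the median stained baseline, where the ratio
    becomes numerically meaningless -- are excluded with a warning.
    """
    f = np.asarray(f, dtype=float)
    f0 = np.broadcast_to(np.asarray(f0, dtype=float), f.shape)
    stained = stained.astype(bool).copy()
    f0_min = f0.min(axis=0)
    floor = f0_floor_frac * max(np.median(f0_min[stained]), 0.0)
    bad = stained & ~(f0_min > max(floor, 0.0))
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} stained pixels with non-positive F0",
            stacklevel=2,
        )
        stained &= ~bad
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (f - f0) / f0 * 100.0
    dff[:, ~stained] = 0.0
    return DffMovie(dff.astype(np.float32), fs, stained, f0=None)


def stained_mask(mean_image: np.ndarray, min_size: int = 16) -> np.ndarray:
    """Boolean mask of the stained (labelled) structures from a mean image.

    Otsu threshold on the intensity distribution (invariant to a global
    intensity scale), holes filled and specks below ``min_size`` removed.
    """
    img = np.asarray(mean_image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("mean image must be finite")
    if np.ptp(img) == 0:
        raise ValueError("mean image has no contrast; cannot find stain")
    thr = filters.threshold_otsu(img)
    mask = img > thr
    mask = ndimage.binary_fill_holes(mask)
    lbl, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(lbl.ravel())
    mask = (sizes > min_size)[lbl] & (lbl > 0)
    if not mask.any():
        raise ValueError("stained mask is empty")
    return mask


def detect_active_segments(
    d: DffMovie,
    thr: float = 15.0,
    min_pixels: int = 16,
    min_frames: int = 3,
) -> ActiveSegmentSet:
    """Find validated active segments.

    Per frame, 8-connected clusters of stained pixels with dF/F >= ``thr``
    and size strictly greater than ``min_pixels`` are kept; clusters of
    consecutive frames sharing at least one pixel are chained, and chains
    spanning at least ``min_frames`` frames are retained.
    """
    t_frames = d.n_frames
    struct = np.ones((3, 3), dtype=int)  # 8-connectivity
    supra = (d.dff >= thr) & d.stained[None]

    frame_labels = np.zeros_like(d.dff, dtype=np.int32)
    cluster_ids: list[tuple[int, int]] = []  # (frame, local label)
    offsets = np.zeros(t_frames + 1, dtype=np.int64)
    for ti in range(t_frames):
        lbl, n = ndimage.label(supra[ti], structure=struct)
        if n:
            sizes = np.bincount(lbl.ravel())
            keep = np.flatnonzero(sizes > min_pixels)
            keep = keep[keep > 0]
            remap = np.zeros(n + 1, dtype=np.int32)
            remap[keep] = np.arange(1, keep.size + 1)
            lbl = remap[lbl]
            n = keep.size
        frame_labels[ti] = lbl
        offsets[ti + 1] = offsets[ti] + n
        cluster_ids.extend((ti, j + 1) for j in range(n))

    n_clusters = offsets[-1]
    parent = np.arange(n_clusters, dtype=np.int64)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for ti in range(t_frames - 1):
        a, b = frame_labels[ti], frame_labels[ti + 1]
        both = (a > 0) & (b > 0)
        if not both.any():
            continue
        pairs = np.unique(
            np.stack([a[both], b[both]], axis=1), axis=0
        )
        for la, lb in pairs:
            union(offsets[ti] + la - 1, offsets[ti + 1] + lb - 1)

    roots = np.array([find(i) for i in range(n_clusters)], dtype=np.int64)
    # span (distinct frames) per chain; links join consecutive frames only,
    # so the frame set of each chain is contiguous
    frames_of = {}
    for ci, (ti, _) in enumerate(cluster_ids):
        frames_of.setdefault(roots[ci], set()).add(ti)
    kept_roots = {r for r, fr in frames_of.items() if len(fr) >= min_frames}
    root_to_seg = {r: k + 1 for k, r in enumerate(sorted(kept_roots))}

    seg_labels = np.zeros_like(frame_labels)
    rows = []
    for ci, (ti, lj) in enumerate(cluster_ids):
        r = roots[ci]
        if r in root_to_seg:
            seg_labels[ti][frame_labels[ti] == lj] = root_to_seg[r]
    for r in sorted(kept_roots):
        fr = sorted(frames_of[r])
        sid = root_to_seg[r]
        rows.append(
            {
                "segment": sid,
                "first_frame": fr[0],
                "last_frame": fr[-1],
                "n_frames": len(fr),
                "total_pixels": int((seg_labels == sid).sum()),
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=["segment", "first_frame", "last_frame", "n_frames",
                 "total_pixels"],
    )
    return ActiveSegmentSet(seg_labels, summary)


def active_area_trace(segs: ActiveSegmentSet, stained: np.ndarray) -> np.ndarray:
    """Per-frame active area as percent of the stained area."""
    n_stained = int(stained.sum())
    if n_stained == 0:
        raise ValueError("stained mask is empty")
    active = (segs.labels > 0) & stained[None]
    return 100.0 * active.reshape(active.shape[0], -1).sum(axis=1) / n_stained


def frame_mean_dff(d: DffMovie) -> np.ndarray:
    """Frame-level dF/F timecourse: mean over stained pixels per frame."""
    if not d.stained.any():
        raise ValueError("stained mask is empty")
    return d.dff[:, d.stained].mean(axis=1)
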