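"""Neuronal activity-unit segmentation.

Decomposes a neuronal movie into non-negative spatial footprints times
non-negative temporal traces ("activity units": synchronously active
structures, not necessarily single cells).  Following the lifted-constraint
variant of CNMF, no temporal-kinetics or spatial-localization constraint is
imposed: the factorization is a plain non-negative matrix factorization
solved by hierarchical alternating least squares (HALS), run first in
overlapping spatial patches and then refined on the whole frame from the
patch initialization.  Footprints are cleaned with Li's minimum
cross-entropy threshold on their nonzero pixels, and redundant components
are merged by Ward agglomerative clustering of their temporal dynamics down
to a fixed number of final ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_li
from sklearn.cluster import AgglomerativeClustering

from .runstats import EpisodeSet

__all__ = [
    "Component",
    "ActivityUnit",
    "hals_nmf",
    "patch_decompose",
    "refine_global",
    "clip_footprint_li",
    "merge_units",
    "unit_classification",
    "segment_units",
]


@dataclass
class Component:
    footprint: np.ndarray  # (H, W) >= 0
    trace: np.ndarray  # (T,) >= 0
    patch_origin: tuple[int, int] | None = None
    is_background: bool = False


@dataclass
class ActivityUnit:
    footprint: np.ndarray
    trace: np.ndarray
    members: list[int] = field(default_factory=list)  # pre-merge component ids
    label: str | None = None  # "locomotion-active" / "quiescent-active"


def _objective(y: np.ndarray, a: np.ndarray, c: np.ndarray) -> float:
    return float(np.linalg.norm(y - a @ c) ** 2)


def hals_nmf(
    y: np.ndarray,
    a: np.ndarray,
    c: np.ndarray,
    n_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Non-negative factorization Y ~ A C by hierarchical alternating least
    squares, updating one component at a time with projection onto >= 0.

    ``y`` is (P, T), ``a`` (P, K), ``c`` (K, T).  Returns the factors and
    the objective value after each sweep (monotonically non-increasing).
    """
    a = a.copy()
    c = c.copy()
    k = a.shape[1]
    history: list[float] = []
    prev = np.inf
    for _ in range(n_iter):
        # update temporal factors
        ata = a.T @ a
        aty = a.T @ y
        for j in range(k):
            denom = ata[j, j]
            if denom <= 0:
                continue
            resid = aty[j] - ata[j] @ c + denom * c[j]
            c[j] = np.maximum(resid / denom, 0.0)
        # update spatial factors
        cct = c @ c.T
        yct = y @ c.T
        for j in range(k):
            denom = cct[j, j]
            if denom <= 0:
                continue
            resid = yct[:, j] - a @ cct[:, j] + denom * a[:, j]
            a[:, j] = np.maximum(resid / denom, 0.0)
        obj = _objective(y, a, c)
        history.append(obj)
        if np.isfinite(prev) and prev - obj <= tol * max(prev, 1.0):
            break
        prev = obj
    return a, c, history


def _nonneg(frames: np.ndarray) -> np.ndarray:
    lo = frames.min()
    return frames - lo if lo < 0 else frames


def _greedy_init(
    block: np.ndarray, shape: tuple[int, int], k: int, radius: int = 10
) -> tuple[np.ndarray, np.ndarray, int]:
    """Greedy seeded initialization: repeatedly place a component at the
    pixel with the largest residual energy, take the local mean trace, form
    the rank-1 footprint within a window of ``radius`` pixels, and subtract.

    ``block`` is (P, T) with P = prod(shape).  Returns (A, C, n_seeded).
    """
    h, w = shape
    t = block.shape[1]
    resid = block.reshape(h, w, t).copy()
    a = np.zeros((h * w, k))
    c = np.zeros((k, t))
    n = 0
    for j in range(k):
        energy = (np.clip(resid, 0, None) ** 2).sum(axis=2)
        y0, x0 = np.unravel_index(np.argmax(energy), energy.shape)
        if energy[y0, x0] <= 0:
            break
        tr = np.clip(
            resid[
                max(y0 - 1, 0) : y0 + 2, max(x0 - 1, 0) : x0 + 2
            ].mean(axis=(0, 1)),
            0.0,
            None,
        )
        if tr.max() <= 0:
            break
        ys = slice(max(y0 - radius, 0), min(y0 + radius + 1, h))
        xs = slice(max(x0 - radius, 0), min(x0 + radius + 1, w))
        local = resid[ys, xs].reshape(-1, t)
        fp = np.clip(local @ tr, 0.0, None) / float(tr @ tr)
        fp_img = np.zeros((h, w))
        fp_img[ys, xs] = fp.reshape(
            ys.stop - ys.start, xs.stop - xs.start
        )
        a[:, j] = fp_img.ravel()
        c[j] = tr
        resid[ys, xs] -= (fp[:, None] * tr[None, :]).reshape(
            ys.stop - ys.start, xs.stop - xs.start, t
        )
        n += 1
    return a, c, n


def _patch_starts(size: int, patch: int, step: int) -> list[int]:
    starts = list(range(0, size - patch + 1, step))
    if not starts:
        starts = [0]
    if starts[-1] != size - patch:
        starts.append(size - patch)
    return starts


def patch_decompose(
    frames: np.ndarray,
    patch: int = 100,
    k_per_patch: int = 12,
    overlap: int | None = None,
    n_iter: int = 60,
    background: bool = True,
    seed: int = 0,
    init_radius: int = 6,
) -> list[Component]:
    """Patchwise non-negative factorization.

    The movie (T, H, W) is split into overlapping square patches (50%
    overlap by default); each patch is factorized into ``k_per_patch``
    components, initialized by greedy energy-peak seeding, plus optionally
    one background component initialized flat.  All-zero patches yield no
    components.  Footprints are returned embedded in the full frame, tagged
    with their patch origin.
    """
    t, h, w = frames.shape
    patch = min(patch, h, w)
    if overlap is None:
        overlap = patch // 2
    step = max(patch - overlap, 1)
    x = _nonneg(np.asarray(frames, dtype=float))
    comps: list[Component] = []
    for pi, y0 in enumerate(_patch_starts(h, patch, step)):
        for pj, x0 in enumerate(_patch_starts(w, patch, step)):
            block = x[:, y0 : y0 + patch, x0 : x0 + patch].reshape(t, -1).T
            if block.max() <= 0:
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, pi, pj])
            )
            k = k_per_patch + int(background)
            a0, c0, n_seeded = _greedy_init(
                block, (patch, patch), k_per_patch, radius=init_radius
            )
            if background:
                a0 = np.concatenate(
                    [a0, np.ones((a0.shape[0], 1))], axis=1
                )
                c0 = np.concatenate(
                    [c0, np.full((1, t), block.mean())], axis=0
                )
            # unseeded slots get a faint random start so HALS can use them
            scale = np.sqrt(max(block.mean(), 1e-12) / k)
            for j in range(n_seeded, k_per_patch):
                a0[:, j] = rng.uniform(0, 0.1, a0.shape[0]) * scale
                c0[j] = rng.uniform(0, 0.1, t) * scale
            a, c, _ = hals_nmf(block, a0, c0, n_iter=n_iter)
            for j in range(k):
                if a[:, j].max() <= 0 or c[j].max() <= 0:
                    continue
                # normalize: footprint peak 1, amplitude carried by trace
                amp = a[:, j].max()
                fp = np.zeros((h, w))
                fp[y0 : y0 + patch, x0 : x0 + patch] = (
                    a[:, j].reshape(patch, patch) / amp
                )
                comps.append(
                    Component(
                        fp,
                        c[j] * amp,
                        patch_origin=(y0, x0),
                        is_background=background and j == k - 1,
                    )
                )
    return comps


def refine_global(
    frames: np.ndarray,
    components: list[Component],
    n_iter: int = 60,
) -> list[Component]:
    """Second factorization pass on the entire frame, initialized from the
    patch-based components.  The HALS objective can only decrease from the
    initialization."""
    if not components:
        raise ValueError("need a nonempty initialization")
    t, h, w = frames.shape
    y = _nonneg(np.asarray(frames, dtype=float)).reshape(t, -1).T
    a0 = np.stack([c.footprint.ravel() for c in components], axis=1)
    c0 = np.stack([c.trace for c in components], axis=0)
    a, c, _ = hals_nmf(y, a0, c0, n_iter=n_iter)
    out = []
    for j, comp in enumerate(components):
        if a[:, j].max() <= 0 or c[j].max() <= 0:
            continue
        amp = a[:, j].max()
        out.append(
            Component(
                a[:, j].reshape(h, w) / amp,
                c[j] * amp,
                patch_origin=comp.patch_origin,
                is_background=comp.is_background,
            )
        )
    return out


def clip_footprint_li(
    footprint: np.ndarray, mode_separation_min: float = 3.0
) -> np.ndarray:
    """Zero out sub-threshold weights using Li's minimum cross-entropy
    threshold computed on the nonzero pixels of the footprint.

    The clip is applied only when the threshold separates two clearly
    distinct populations (kept mean at least ``mode_separation_min`` times
    the removed mean); a unimodal weight distribution — e.g. a footprint
    that has already been clipped — is returned unchanged, which makes the
    operation idempotent.
    """
    fp = np.asarray(footprint, dtype=float)
    nz = fp[fp > 0]
    if np.unique(nz).size < 2:
        warnings.warn("footprint has < 2 distinct nonzero values; not clipped",
                      stacklevel=2)
        return fp.copy()
    thr = threshold_li(nz)
    removed, kept = nz[nz < thr], nz[nz >= thr]
    if removed.size == 0 or kept.mean() < mode_separation_min * removed.mean():
        return fp.copy()
    out = fp.copy()
    out[out < thr] = 0.0
    return out


def merge_units(
    components: list[Component], n_final: int = 12
) -> list[ActivityUnit]:
    """Merge components with similar dynamics into ``n_final`` units.

    Traces are z-scored and clustered by Ward agglomeration (Euclidean
    distance, the classical Ward setting, equivalent to grouping by trace
    correlation); each cluster's footprint is the sum of its members and its
    trace the footprint-mass-weighted mean of the member traces.
    """
    comps = [c for c in components if not c.is_background]
    if len(comps) == 0:
        return []
    if len(comps) <= n_final:
        if len(comps) < n_final:
            warnings.warn(
                f"only {len(comps)} components for {n_final} units; no merge",
                stacklevel=2,
            )
        return [
            ActivityUnit(c.footprint.copy(), c.trace.copy(), members=[i])
            for i, c in enumerate(comps)
        ]
    traces = np.stack([c.trace for c in comps])
    sd = traces.std(axis=1, keepdims=True)
    z = (traces - traces.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1)
    labels = AgglomerativeClustering(
        n_clusters=n_final, linkage="ward"
    ).fit_predict(z)
    units = []
    for lab in range(n_final):
        members = [i for i, l in enumerate(labels) if l == lab]
        fps = [comps[i].footprint for i in members]
        weights = np.array([fp.sum() for fp in fps])
        weights = weights / weights.sum() if weights.sum() > 0 else None
        trace = np.average(
            np.stack([comps[i].trace for i in members]), axis=0, weights=weights
        )
        units.append(ActivityUnit(np.sum(fps, axis=0), trace, members=members))
    return units


def unit_classification(
    units: list[ActivityUnit], episodes: EpisodeSet
) -> list[str]:
    """Label each unit locomotion-active or quiescent-active by comparing its
    mean activity during locomotion vs quiescence."""
    labels = []
    for u in units:
        mask = episodes.label_array(u.trace.size)
        if not mask.any() or mask.all():
            u.label = None
            labels.append("unlabeled")
            continue
        l_mean = u.trace[mask].mean()
        q_mean = u.trace[~mask].mean()
        u.label = (
            "locomotion-active" if l_mean > q_mean else "quiescent-active"
        )
        labels.append(u.label)
    return labels


def segment_units(
    frames: np.ndarray,
    patch: int = 100,
    k_per_patch: int = 12,
    n_final: int = 12,
    n_iter: int = 60,
    seed: int = 0,
    min_trace_pnr: float = 6.0,
) -> list[ActivityUnit]:
    """End-to-end unit segmentation: patch factorization, global refinement,
    Li footprint clipping, noise-component rejection, Ward merging."""
    comps = patch_decompose(
        frames, patch=patch, k_per_patch=k_per_patch, n_iter=n_iter, seed=seed
    )
    comps = refine_global(frames, comps, n_iter=n_iter)
    for c in comps:
        if not c.is_background and np.unique(c.footprint[c.footprint > 0]).size >= 2:
            fp = clip_footprint_li(c.footprint)
            # a unit is one connected structure; residual speckle scattered
            # over the field belongs to other sources or noise
            lbl, n = ndimage.label(fp > 0, structure=np.ones((3, 3), int))
            if n > 1:
                sizes = np.bincount(lbl.ravel())
                fp[lbl != (sizes[1:].argmax() + 1)] = 0.0
            c.footprint = fp
    comps = [c for c in comps if c.footprint.max() > 0 and c.trace.max() > 0]
    # drop components whose trace is indistinguishable from noise: real
    # units carry transients far above their own fluctuation floor
    def _pnr(tr: np.ndarray) -> float:
        med = np.median(tr)
        mad = np.median(np.abs(tr - med))
        return (tr.max() - med) / max(1.4826 * mad, 1e-12)

    comps = [c for c in comps if _pnr(c.trace) >= min_trace_pnr]
    return merge_units(comps, n_final=n_final)
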