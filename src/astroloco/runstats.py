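"""Locomotion-coupling statistics.

Segments a speed trace into alternating locomotion/quiescence episodes and
computes the behaviour-coupled summaries: per-episode means, the
quiescence/locomotion (Q/L) activity ratio, the speed-vs-dFF cross-correlation
peak and lag, paired-run detection (two runs separated by < 30 s of
quiescence) and the paired-run ratio (PRR, second response / first response),
plus a Mann-Whitney U rank test with an exact small-sample branch.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "SpeedTrace",
    "Episode",
    "EpisodeSet",
    "PairedRun",
    "segment_episodes",
    "episode_means",
    "ql_ratio",
    "speed_dff_crosscorr",
    "find_paired_runs",
    "paired_run_ratio",
    "mann_whitney",
]

LOCOMOTION = "locomotion"
QUIESCENCE = "quiescence"


@dataclass
class SpeedTrace:
    """Uniformly sampled locomotion speed (cm/s, >= 0)."""

    speed: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float)
        if self.speed.ndim != 1 or self.speed.size == 0:
            raise ValueError("speed must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.speed)) or self.speed.min() < 0:
            raise ValueError("speed must be finite and non-negative")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.speed.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.speed.size / self.fs


@dataclass(frozen=True)
class Episode:
    start_s: float
    end_s: float
    label: str

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def sample_slice(self, fs: float) -> slice:
        return slice(int(round(self.start_s * fs)), int(round(self.end_s * fs)))


@dataclass
class EpisodeSet:
    """Ordered disjoint intervals labelled locomotion or quiescence that
    cover the recording with no two adjacent same-label intervals."""

    episodes: list[Episode]
    fs: float

    def __post_init__(self) -> None:
        eps = self.episodes
        for a, b in zip(eps, eps[1:]):
            if not math.isclose(a.end_s, b.start_s, abs_tol=1e-9):
                raise ValueError("episodes must tile the recording")
            if a.label == b.label:
                raise ValueError("adjacent episodes must alternate labels")

    def __iter__(self):
        return iter(self.episodes)

    def __len__(self) -> int:
        return len(self.episodes)

    def runs(self) -> list[Episode]:
        return [e for e in self.episodes if e.label == LOCOMOTION]

    def quiet(self) -> list[Episode]:
        return [e for e in self.episodes if e.label == QUIESCENCE]

    def label_array(self, n: int) -> np.ndarray:
        """Boolean per-sample locomotion indicator of length ``n``."""
        out = np.zeros(n, dtype=bool)
        for e in self.runs():
            out[e.sample_slice(self.fs)] = True
        return out


@dataclass(frozen=True)
class PairedRun:
    first: Episode
    second: Episode

    @property
    def gap_s(self) -> float:
        return self.second.start_s - self.first.end_s


def segment_episodes(
    s: SpeedTrace,
    speed_thr: float = 0.5,
    min_run_s: float = 1.0,
    merge_gap_s: float = 0.5,
    smooth_s: float = 0.25,
) -> EpisodeSet:
    """Partition the recording into alternating locomotion/quiescence episodes.

    Locomotion = maximal intervals where the (Gaussian-smoothed) speed exceeds
    ``speed_thr``; sub-``merge_gap_s`` gaps between them are merged and runs
    shorter than ``min_run_s`` discarded.  Everything else is quiescence.
    """
    fs = s.fs
    sm = ndimage.gaussian_filter1d(s.speed, max(smooth_s * fs, 1e-9))
    moving = sm > speed_thr
    # merge short gaps
    gap = max(1, int(round(merge_gap_s * fs)))
    moving = ndimage.binary_closing(moving, structure=np.ones(gap + 1))
    # drop short runs
    lbl, n = ndimage.label(moving)
    for i in range(1, n + 1):
        idx = np.flatnonzero(lbl == i)
        if idx.size < min_run_s * fs:
            moving[idx] = False

    episodes: list[Episode] = []
    edges = np.flatnonzero(np.diff(moving.astype(int))) + 1
    bounds = np.concatenate(([0], edges, [moving.size]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        label = LOCOMOTION if moving[a] else QUIESCENCE
        episodes.append(Episode(a / fs, b / fs, label))
    return EpisodeSet(episodes, fs)


def episode_means(x: np.ndarray, e: EpisodeSet) -> pd.DataFrame:
    """Per-episode mean of a per-frame trace ``x`` sharing the episode set's
    time base.  Episodes shorter than one frame are skipped."""
    x = np.asarray(x, dtype=float)
    rows = []
    for i, ep in enumerate(e):
        seg = x[ep.sample_slice(e.fs)]
        if seg.size == 0:
            continue
        rows.append(
            {
                "episode": i,
                "label": ep.label,
                "start_s": ep.start_s,
                "end_s": ep.end_s,
                "mean": float(seg.mean()),
            }
        )
    return pd.DataFrame(rows)


def ql_ratio(x: np.ndarray, e: EpisodeSet) -> float:
    """Mean activity over all quiescence time divided by mean activity over
    all locomotion time.  NaN when either label is absent or the locomotion
    mean is zero."""
    x = np.asarray(x, dtype=float)
    mask = e.label_array(x.size)
    if not mask.any() or mask.all():
        return float("nan")
    l_mean = x[mask].mean()
    q_mean = x[~mask].mean()
    if l_mean == 0:
        return float("nan")
    return float(q_mean / l_mean)


def speed_dff_crosscorr(
    x: np.ndarray, s: SpeedTrace, max_lag_s: float = 15.0
) -> tuple[float, float]:
    """Peak normalized cross-correlation between an activity trace and speed.

    Returns ``(r_peak, lag_s)`` where a positive lag means the activity
    follows the speed.  Each lag's coefficient is the Pearson correlation of
    the overlapping samples, so ``r`` is in [-1, 1] and an exact delayed copy
    yields r = 1 at its delay.
    """
    x = np.asarray(x, dtype=float)
    v = s.speed
    if x.size != v.size:
        raise ValueError("trace and speed must share the time base")
    if np.std(x) == 0 or np.std(v) == 0:
        return float("nan"), float("nan")
    max_lag = int(round(max_lag_s * s.fs))
    max_lag = min(max_lag, x.size - 2)
    best_r, best_lag = -np.inf, 0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = x[lag:], v[: v.size - lag]
        else:
            a, b = x[:lag], v[-lag:]
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if r > best_r:
            best_r, best_lag = r, lag
    return best_r, best_lag / s.fs


def find_paired_runs(e: EpisodeSet, max_gap_s: float = 30.0) -> list[PairedRun]:
    """Consecutive locomotion episodes separated by strictly less than
    ``max_gap_s`` of quiescence; greedy left-to-right so each episode joins
    at most one pair."""
    runs = e.runs()
    pairs: list[PairedRun] = []
    i = 0
    while i < len(runs) - 1:
        gap = runs[i + 1].start_s - runs[i].end_s
        if gap < max_gap_s:
            pairs.append(PairedRun(runs[i], runs[i + 1]))
            i += 2
        else:
            i += 1
    return pairs


def _episode_response(
    x: np.ndarray, ep: Episode, fs: float, tail_s: float, how: str
) -> float:
    i0 = int(round(ep.start_s * fs))
    i1 = min(int(round((ep.end_s + tail_s) * fs)), x.size)
    seg = x[i0:i1]
    if seg.size == 0:
        return float("nan")
    return float(seg.max() if how == "peak" else seg.mean())


def paired_run_ratio(
    x: np.ndarray,
    p: PairedRun,
    fs: float,
    tail_s: float = 10.0,
    how: str = "peak",
) -> float:
    """PRR = response to the second run / response to the first run.

    The response window extends from episode onset to offset + ``tail_s``
    (to accommodate the delayed astrocytic response); ``how`` selects the
    peak (default) or the mean within the window.  NaN when the first
    response is not positive.
    """
    r1 = _episode_response(x, p.first, fs, tail_s, how)
    r2 = _episode_response(x, p.second, fs, tail_s, how)
    if not np.isfinite(r1) or r1 <= 0:
        return float("nan")
    return r2 / r1


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: a.size].sum()
    return float(r1 - a.size * (a.size + 1) / 2.0)


def mann_whitney(
    a: np.ndarray, b: np.ndarray, exact_max_n: int = 12
) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided).

    Returns ``(U, p)`` where U counts pairs (a_i, b_j) with a_i > b_j (ties
    count 1/2).  For ``n_a + n_b <= exact_max_n`` the null distribution of U
    is enumerated over all labelings of the pooled sample (exact even under
    ties); otherwise the tie-corrected normal approximation with continuity
    correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    u = _u_statistic(a, b)

    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([a, b])
        idx = range(n1 + n2)
        us = np.array(
            [
                _u_statistic(pooled[list(comb)],
                             pooled[[i for i in idx if i not in set(comb)]])
                for comb in itertools.combinations(idx, n1)
            ]
        )
        tol = 1e-9
        p_le = np.mean(us <= u + tol)
        p_ge = np.mean(us >= u - tol)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u, float(p)

    mu = n1 * n2 / 2.0
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return u, float(p)
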