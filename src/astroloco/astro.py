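"""Single-astrocyte soma/process analysis.

Each astrocyte is described by a manually traced domain mask containing a
soma mask; the remainder of the domain is the processes compartment.  The
module computes compartment dF/F timecourses, the soma-process onset latency
(time difference between the 15%-of-peak up-crossings; positive = processes
lead, i.e. centripetal propagation), the prominence of slow somatic Ca2+
oscillations as mean Morlet wavelet power in 0.1-0.3 Hz over the active
interval, the maximum Feret diameter of the domain, and the latency-vs-size
regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage, stats
from scipy.spatial import ConvexHull, QhullError

from .activity import DffMovie

__all__ = [
    "AstroCell",
    "compartment_traces",
    "normalize_to_peak",
    "onset_latency",
    "wavelet_band_power",
    "feret_diameter",
    "latency_size_regression",
    "analyze_cell",
]

# pywt complex Morlet with bandwidth 1 and centre frequency 6/(2*pi) Hz at
# scale 1, i.e. the classical Morlet with omega0 = 6
MORLET = "cmor1.0-0.954929658551372"


@dataclass
class AstroCell:
    """Per-cell analysis bundle."""

    cell_id: int
    soma_trace: np.ndarray  # dF/F %, per frame
    proc_trace: np.ndarray
    latency_s: float  # NaN when undefined
    soma_power: float
    proc_power: float
    feret_um: float
    soma_peak_pct: float
    proc_peak_pct: float


def compartment_traces(
    d: DffMovie, soma_mask: np.ndarray, proc_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean dF/F per frame over the soma and the processes masks."""
    for name, m in (("soma", soma_mask), ("processes", proc_mask)):
        if not m.any():
            raise ValueError(f"{name} mask is empty")
        if m.shape != d.dff.shape[1:]:
            raise ValueError(f"{name} mask shape does not match the movie")
    soma = d.dff[:, soma_mask].mean(axis=1)
    proc = d.dff[:, proc_mask].mean(axis=1)
    return soma, proc


def normalize_to_peak(trace: np.ndarray) -> np.ndarray:
    """Scale a trace so its maximum equals 1."""
    trace = np.asarray(trace, dtype=float)
    peak = trace.max()
    if peak <= 0:
        raise ValueError("trace peak must be positive to normalize")
    return trace / peak


def _first_crossing(trace: np.ndarray, level: float) -> int | None:
    idx = np.flatnonzero(trace >= level)
    return int(idx[0]) if idx.size else None


def onset_latency(
    soma_norm: np.ndarray,
    proc_norm: np.ndarray,
    fs: float,
    fraction: float = 0.15,
) -> float:
    """Soma-process onset latency in seconds.

    The onset of each (peak-normalized) trace is its first up-crossing of
    ``fraction``; the latency is t_soma - t_proc, positive when the
    processes lead.  NaN when either trace never crosses.
    """
    i_s = _first_crossing(np.asarray(soma_norm, float), fraction)
    i_p = _first_crossing(np.asarray(proc_norm, float), fraction)
    if i_s is None or i_p is None:
        return float("nan")
    return (i_s - i_p) / fs


def wavelet_band_power(
    trace: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.1, 0.3),
    active_fraction: float = 0.15,
    n_freqs: int = 9,
    wavelet: str = MORLET,
) -> float:
    """Mean continuous-wavelet (Morlet) power of the trace over the active
    interval (samples above ``active_fraction`` of the peak) and the
    frequency band.  NaN when the active interval is empty."""
    trace = np.asarray(trace, dtype=float)
    if fs <= 2 * band[1]:
        raise ValueError("sampling rate too low for the requested band")
    peak = trace.max()
    active = trace > active_fraction * peak
    if peak <= 0 or not active.any():
        return float("nan")
    freqs = np.linspace(band[0], band[1], n_freqs)
    scales = pywt.frequency2scale(wavelet, freqs / fs)
    coefs, _ = pywt.cwt(trace, scales, wavelet, sampling_period=1.0 / fs)
    power = np.abs(coefs) ** 2
    return float(power[:, active].mean())


def feret_diameter(mask: np.ndarray, pixel_size: float = 1.0) -> float:
    """Maximum Feret (caliper) diameter: the largest pairwise distance
    between boundary pixel centers, scaled by the pixel size."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    boundary = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(boundary).astype(float)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) sets: brute force below
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max()) * pixel_size


def latency_size_regression(
    latencies: np.ndarray, diameters: np.ndarray
) -> tuple[float, float, float]:
    """OLS regression of latency on domain size.

    Returns ``(slope, r_squared, p)`` with a two-sided p-value for the
    slope.  Pairs with non-finite entries are dropped.
    """
    lat = np.asarray(latencies, dtype=float)
    dia = np.asarray(diameters, dtype=float)
    ok = np.isfinite(lat) & np.isfinite(dia)
    lat, dia = lat[ok], dia[ok]
    if lat.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(dia) == 0:
        raise ValueError("diameters have zero variance")
    fit = stats.linregress(dia, lat)
    return float(fit.slope), float(fit.rvalue**2), float(fit.pvalue)


def analyze_cell(
    d: DffMovie,
    cell_id: int,
    domain_mask: np.ndarray,
    soma_mask: np.ndarray,
    pixel_size_um: float = 1.0,
    fraction: float = 0.15,
    band: tuple[float, float] = (0.1, 0.3),
) -> AstroCell:
    """Full per-cell summary: traces, latency, band power, Feret diameter."""
    proc_mask = domain_mask & ~soma_mask
    soma, proc = compartment_traces(d, soma_mask, proc_mask)
    if soma.max() > 0 and proc.max() > 0:
        soma_n = normalize_to_peak(soma)
        proc_n = normalize_to_peak(proc)
        lat = onset_latency(soma_n, proc_n, d.fs, fraction)
        sp = wavelet_band_power(soma_n, d.fs, band, fraction)
        pp = wavelet_band_power(proc_n, d.fs, band, fraction)
    else:
        lat, sp, pp = float("nan"), float("nan"), float("nan")
    return AstroCell(
        cell_id=cell_id,
        soma_trace=soma,
        proc_trace=proc,
        latency_s=lat,
        soma_power=sp,
        proc_power=pp,
        feret_um=feret_diameter(domain_mask, pixel_size_um),
        soma_peak_pct=float(soma.max()),
        proc_peak_pct=float(proc.max()),
    )
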