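"""File formats: multi-page TIFF movies, CSV speed traces, label-TIFF masks.

Conventions: CSV times are frame-start seconds with 0-based frame indices
(frame i covers [i, i+1)/fs); in ROI label TIFFs the soma of cell ``k``
carries label ``k + soma_offset`` (default offset 1000) inside the domain
labelled ``k``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .preprocess import Movie, ShiftSeries
from .runstats import SpeedTrace

__all__ = [
    "write_movie",
    "read_movie",
    "write_speed",
    "read_speed",
    "write_masks",
    "read_masks",
    "write_shifts",
    "read_shifts",
    "write_json",
]

SOMA_OFFSET = 1000


def write_movie(path: str | Path, m: Movie) -> None:
    frames = m.frames
    if np.issubdtype(frames.dtype, np.floating):
        frames = frames.astype(np.float32)
    tifffile.imwrite(str(path), frames, metadata={"fs_hz": m.fs,
                                                  "channel": m.channel})


def read_movie(
    path: str | Path, fs: float | None = None, channel: str | None = None
) -> Movie:
    with tifffile.TiffFile(str(path)) as tf:
        frames = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if frames.ndim == 2:
        frames = frames[None]
    fs = fs if fs is not None else float(meta.get("fs_hz", 0) or 0)
    if fs <= 0:
        raise ValueError(f"{path}: frame rate not stored; pass fs explicitly")
    channel = channel or str(meta.get("channel", "green"))
    return Movie(frames, fs, channel)


def write_speed(path: str | Path, s: SpeedTrace) -> None:
    # time needs full precision so the sampling step survives the round
    # trip at any recording length; speed keeps 6 significant digits
    df = pd.DataFrame(
        {
            "time_s": [f"{t:.9g}" for t in s.time_s],
            "speed_cm_s": [f"{v:.6g}" for v in s.speed],
        }
    )
    df.to_csv(path, index=False)


def read_speed(path: str | Path) -> SpeedTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "speed_cm_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    dt_med = float(np.median(dt))
    if dt_med <= 0 or np.abs(dt - dt_med).max() > 0.01 * dt_med:
        raise ValueError(f"{path}: speed trace is not uniformly sampled")
    return SpeedTrace(df["speed_cm_s"].to_numpy(dtype=float), fs=1.0 / dt_med)


def write_masks(
    path: str | Path,
    domain_labels: np.ndarray,
    soma_labels: np.ndarray | None = None,
    soma_offset: int = SOMA_OFFSET,
) -> None:
    out = domain_labels.astype(np.int32).copy()
    if soma_labels is not None:
        soma = soma_labels.astype(np.int32)
        out[soma > 0] = soma[soma > 0] + soma_offset
    tifffile.imwrite(str(path), out)


def read_masks(
    path: str | Path, soma_offset: int = SOMA_OFFSET
) -> dict[int, dict[str, np.ndarray]]:
    """Parse a label TIFF into per-cell domain/soma boolean masks.

    Labels above ``soma_offset`` mark soma pixels of cell
    ``label - soma_offset``; the domain is the union of both label groups.
    """
    lbl = tifffile.imread(str(path)).astype(np.int64)
    cells: dict[int, dict[str, np.ndarray]] = {}
    ids = {int(v) for v in np.unique(lbl) if v > 0}
    base_ids = {i if i <= soma_offset else i - soma_offset for i in ids}
    for cid in sorted(base_ids):
        soma = lbl == cid + soma_offset
        domain = (lbl == cid) | soma
        cells[cid] = {"domain": domain, "soma": soma}
    return cells


def write_shifts(path: str | Path, s: ShiftSeries) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(len(s)),
            "dy_px": s.shifts[:, 0],
            "dx_px": s.shifts[:, 1],
        }
    ).to_csv(path, index=False)


def read_shifts(path: str | Path) -> ShiftSeries:
    df = pd.read_csv(path)
    return ShiftSeries(df[["dy_px", "dx_px"]].to_numpy(dtype=float))


def write_json(path: str | Path, obj: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
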