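"""Readers and writers for sample series, frame stacks and result tables.

All tabular output is plain delimited text with a comment header carrying
the configuration hash and the seed, so any result file can be traced to
the exact settings that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .preprocess import SampleSeries

__all__ = ["read_samples", "write_samples", "read_frames", "write_weights",
           "write_metrics"]

_SAMPLE_COLUMNS = ("t", "x", "y", "pupil", "valid")


class SchemaError(ValueError):
    """Input file does not match the expected schema."""


def _header(config_hash: str = "", seed: Optional[int] = None) -> str:
    parts = ["# pupilfield"]
    if config_hash:
        parts.append(f"config_hash={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts) + "\n"


def write_samples(series: SampleSeries, path: str | Path,
                  config_hash: str = "", seed: Optional[int] = None) -> None:
    """Write a sample series as CSV with columns t, x, y, pupil, valid."""
    df = pd.DataFrame({"t": series.t, "x": series.gaze_x, "y": series.gaze_y,
                       "pupil": series.pupil,
                       "valid": series.valid.astype(int)})
    with open(path, "w") as fh:
        fh.write(_header(config_hash, seed))
        df.to_csv(fh, index=False, float_format="%.9g")


def read_samples(path: str | Path) -> SampleSeries:
    """Read a sample-series CSV (header comment lines start with '#')."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty input file") from None
    if df.empty:
        raise SchemaError(f"{path}: no samples")
    missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    t = df["t"].to_numpy(dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise SchemaError(f"{path}: timestamps not strictly increasing")
    return SampleSeries(t=t, gaze_x=df["x"].to_numpy(dtype=float),
                        gaze_y=df["y"].to_numpy(dtype=float),
                        pupil=df["pupil"].to_numpy(dtype=float),
                        valid=df["valid"].to_numpy().astype(bool))


def read_frames(path: str | Path, max_luminance: float = 100.0,
                gamma: float = 2.2, assume_luma: bool = False) -> np.ndarray:
    """Read a movie as a (frames, h, w) luminance stack in cd/m^2.

    TIFF stacks are read natively; other extensions go through imageio
    (common video containers).  Integer code values v are mapped to
    luminance by ``max_luminance * (v / v_max) ** gamma`` (display gamma);
    floating-point stacks are taken as calibrated cd/m^2.  Colour input is
    rejected unless ``assume_luma`` requests a Rec.601 luma conversion.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4:
        if arr.shape[-1] not in (3, 4):
            raise SchemaError(f"{path}: unsupported frame shape {arr.shape}")
        if not assume_luma:
            raise SchemaError(f"{path}: colour input; pass assume_luma=True "
                              "for a Rec.601 luma conversion")
        arr = (0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2])
    if arr.ndim != 3:
        raise SchemaError(f"{path}: expected a (frames, h, w) stack")
    if np.issubdtype(arr.dtype, np.integer):
        vmax = float(np.iinfo(arr.dtype).max)
        return max_luminance * (arr.astype(float) / vmax) ** gamma
    return arr.astype(float)


def write_weights(weight_table: pd.DataFrame, path: str | Path,
                  config_hash: str = "", seed: Optional[int] = None) -> None:
    """Write a per-region weight table (region id, ring, sector, weight)."""
    with open(path, "w") as fh:
        fh.write(_header(config_hash, seed))
        weight_table.to_csv(fh, float_format="%.10g")


def write_metrics(metrics: dict, path: str | Path,
                  config_hash: str = "", seed: Optional[int] = None) -> None:
    """Write fit/driver metrics as JSON (header fields go inside the object)."""
    payload = dict(metrics)
    if config_hash:
        payload["config_hash"] = config_hash
    if seed is not None:
        payload["seed"] = seed
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")
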