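"""TIFF / JSON / CSV input-output helpers."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import Micrograph, SkeletonImage, TimeSeries, VelocityField

__all__ = [
    "read_micrograph",
    "read_series",
    "write_micrograph",
    "write_series",
    "write_skeleton",
    "read_skeleton",
    "write_truth_json",
    "write_velocity_csv",
]


def read_micrograph(path: str | Path, pixel_size_um: float, channel: str = "actin") -> Micrograph:
    """Read a single-page TIFF as a micrograph."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        arr = arr[0]
    return Micrograph(arr.astype(float), pixel_size_um, channel)


def read_series(
    path: str | Path,
    pixel_size_um: float,
    frame_interval_s: float,
    channel: str = "actin",
    t0_index: int = 0,
) -> TimeSeries:
    """Read a multi-page TIFF stack as a time series (one page per frame)."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    frames = [Micrograph(a.astype(float), pixel_size_um, channel) for a in arr]
    return TimeSeries(frames, frame_interval_s, t0_index)


def write_micrograph(img: Micrograph, path: str | Path) -> None:
    tifffile.imwrite(str(path), img.pixels.astype(np.float32))


def write_series(ts: TimeSeries, path: str | Path) -> None:
    stack = ts.as_array().astype(np.float32)
    tifffile.imwrite(str(path), stack)


def write_skeleton(skel: SkeletonImage, path: str | Path) -> None:
    tifffile.imwrite(str(path), (skel.mask.astype(np.uint8) * 255))


def read_skeleton(path: str | Path, pixel_size_um: float) -> SkeletonImage:
    arr = tifffile.imread(str(path))
    return SkeletonImage(arr > 0, pixel_size_um)


def write_truth_json(truth, path: str | Path) -> None:
    """Serialize a SynthTruth record (filaments, nodes, directors) to JSON."""
    payload = {
        "filaments": [f.tolist() for f in truth.filaments],
        "orientations": truth.orientations.tolist(),
        "multiplicities": truth.multiplicities.tolist(),
        "node_coords": truth.node_coords.tolist(),
        "director_field": truth.director_field.tolist(),
        "domain_directors": truth.domain_directors.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def write_velocity_csv(fields: "list[VelocityField]", path: str | Path) -> None:
    """Tidy CSV of velocity vectors: time_s, x_um, y_um, u_um_s, v_um_s, valid."""
    rows = []
    for f in fields:
        rows.append(
            pd.DataFrame(
                {
                    "time_s": f.time_s,
                    "x_um": f.x_um.ravel(),
                    "y_um": f.y_um.ravel(),
                    "u_um_s": f.u_um_s.ravel(),
                    "v_um_s": f.v_um_s.ravel(),
                    "valid": f.valid.ravel(),
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
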