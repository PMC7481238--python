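"""Minimal raster I/O: single-band TIFF with a JSON georeference sidecar.

Rasters are plain 2-D numpy arrays. Georeference (origin, pixel size, nodata)
travels in a ``<name>.tif.json`` sidecar so that round trips preserve it; the
pipeline itself only ever needs pixel size, since all inputs must share one
grid (misalignment is an error, reprojection is out of scope).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass(frozen=True)
class GridRef:
    """Georeference of an axis-aligned north-up grid."""

    x_origin: float = 0.0
    y_origin: float = 0.0
    pixel_size_m: float = 30.0
    nodata: float | int | None = 0


def write_raster(path, array: np.ndarray, ref: GridRef | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if array.ndim != 2:
        raise ValueError("write_raster expects a single-band 2-D array")
    tifffile.imwrite(path, np.ascontiguousarray(array))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(asdict(ref or GridRef()), indent=1))
    return path


def read_raster(path) -> tuple[np.ndarray, GridRef]:
    path = Path(path)
    array = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    ref = GridRef(**json.loads(sidecar.read_text())) if sidecar.exists() else GridRef()
    return array, ref


def check_aligned(*arrays: np.ndarray) -> tuple[int, int]:
    """Return the common shape, or raise if the grids disagree."""
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"misaligned grids: shapes {sorted(shapes)}")
    return next(iter(shapes))
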