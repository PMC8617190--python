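"""Single-band raster I/O.

Rasters are written as plain single-band TIFFs (float32 for elevation and
probability, uint8/int16/uint32 for masks and labels) via tifffile; the
affine transform lives in the region manifest rather than in geo-tags,
since the synthetic region needs only a trivial pixel-to-metre mapping.
All rasters of one region share dimensions and transform; a mismatch is a
hard error, never a silent resample.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile


class RasterMismatchError(ValueError):
    """Raster dimensions or transform differ from the region's."""


def write_raster(path, array: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.ascontiguousarray(array))


def read_raster(path, like: np.ndarray | None = None) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if like is not None and arr.shape != like.shape:
        raise RasterMismatchError(
            f"{path}: shape {arr.shape} != expected {like.shape}"
        )
    return arr


def write_manifest(path, *, shape: tuple[int, int], cell_area_m2: float,
                   extra: dict | None = None) -> None:
    cell = float(np.sqrt(cell_area_m2))
    manifest = {
        "shape": list(shape),
        "cell_area_m2": cell_area_m2,
        # affine (a, b, c, d, e, f): x = a*col + b*row + c, y = d*col + e*row + f
        "transform": [cell, 0.0, 0.0, 0.0, -cell, shape[0] * cell],
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
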