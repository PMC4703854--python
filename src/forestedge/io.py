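"""Raster and table I/O.

Rasters are written as plain TIFF (uint8 masks, float32 fields, 12-band
precipitation stacks) via tifffile, with pixel size, nodata value and band
meaning recorded in a JSON sidecar next to the file.  Tables go through
pandas CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .raster import SubRegion

FLOAT_NODATA = -9999.0


def write_raster(path, array: np.ndarray, pixel_size_km: float, nodata=None, description: str = "") -> None:
    path = Path(path)
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    elif np.issubdtype(arr.dtype, np.floating):
        arr = np.where(np.isfinite(arr), arr, FLOAT_NODATA).astype(np.float32)
        nodata = FLOAT_NODATA
    tifffile.imwrite(path, arr)
    sidecar = {
        "pixel_size_km": pixel_size_km,
        "nodata": nodata,
        "crs": "synthetic-equal-area",
        "description": description,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_raster(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    arr = tifffile.imread(path)
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if meta.get("nodata") is not None and np.issubdtype(arr.dtype, np.floating):
        arr = np.where(arr == meta["nodata"], np.nan, arr.astype(float))
    return arr, meta


def subregions_to_frame(tiles: list[SubRegion], pixel_size_km: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [t.id for t in tiles],
            "row_start": [t.row_start for t in tiles],
            "row_stop": [t.row_stop for t in tiles],
            "col_start": [t.col_start for t in tiles],
            "col_stop": [t.col_stop for t in tiles],
            "forest_pixels": [t.forest_pixels for t in tiles],
            "area_km2": [t.area_km2(pixel_size_km) for t in tiles],
            "skipped": [t.skipped for t in tiles],
        }
    )
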