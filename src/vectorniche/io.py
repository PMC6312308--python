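"""Readers and writers for single-band GeoTIFF rasters and occurrence CSVs.

GeoTIFFs are written north-up in geographic WGS84 coordinates with the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, a minimal
GeoKey directory declaring EPSG:4326, and the GDAL nodata tag).  Continuous
layers are stored as float32, categorical layers as uint8 with 255 as the
nodata code.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grids import Layer, RasterGrid
from .occurrences import COLUMNS, OccurrenceSet

__all__ = [
    "read_raster",
    "write_raster",
    "read_occurrences",
    "write_occurrences",
    "write_manifest",
]

TAG_MODEL_PIXEL_SCALE = 33550
TAG_MODEL_TIEPOINT = 33922
TAG_GEO_KEY_DIRECTORY = 34735
TAG_GDAL_NODATA = 42113

# GeoKey directory: version 1.1, 3 keys -> geographic model, pixel-is-area,
# geographic CRS EPSG:4326.
_GEO_KEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)

UINT8_NODATA = 255


class RasterFormatError(ValueError):
    """Raised when a raster file violates the single-band square-cell contract."""


def write_raster(layer: Layer, path: str | os.PathLike, dtype: str = "float32") -> None:
    """Write a layer as a single-band georeferenced GeoTIFF.

    ``dtype='float32'`` stores continuous values with the grid's nodata
    sentinel; ``dtype='uint8'`` stores categorical codes with 255 as nodata.
    """
    grid = layer.grid
    if dtype == "float32":
        sentinel = float(grid.nodata)
        data = np.where(np.isnan(layer.values), sentinel, layer.values).astype(np.float32)
    elif dtype == "uint8":
        sentinel = UINT8_NODATA
        data = np.where(np.isnan(layer.values), sentinel, layer.values).astype(np.uint8)
    else:
        raise ValueError(f"unsupported raster dtype {dtype!r}")
    extratags = [
        (TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.resolution, grid.resolution, 0.0)),
        (TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x_min, grid.y_max, 0.0)),
        (TAG_GEO_KEY_DIRECTORY, "H", len(_GEO_KEYS), _GEO_KEYS),
        (TAG_GDAL_NODATA, "s", 0, repr(float(sentinel))),
    ]
    tifffile.imwrite(os.fspath(path), data, extratags=extratags)


def read_raster(path: str | os.PathLike, name: str | None = None) -> Layer:
    """Read a single-band GeoTIFF written in geographic coordinates.

    Raises :class:`RasterFormatError` for multi-band files or files whose
    geotransform implies non-square cells.
    """
    path = os.fspath(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise RasterFormatError(
                f"{path}: expected a single band, found {len(tif.pages)}"
            )
        page = tif.pages[0]
        spp = page.tags.get(277)
        if spp is not None and spp.value not in (1,):
            raise RasterFormatError(
                f"{path}: expected a single band, found {spp.value} samples per pixel"
            )
        scale_tag = page.tags.get(TAG_MODEL_PIXEL_SCALE)
        tie_tag = page.tags.get(TAG_MODEL_TIEPOINT)
        if scale_tag is None or tie_tag is None:
            raise RasterFormatError(f"{path}: missing georeferencing tags")
        sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
        if not np.isclose(sx, sy, rtol=1e-9, atol=0.0):
            raise RasterFormatError(
                f"{path}: non-square cells (x scale {sx}, y scale {sy})"
            )
        tie = tie_tag.value
        x_min = float(tie[3]) - float(tie[0]) * sx
        y_max = float(tie[4]) + float(tie[1]) * sy
        arr = page.asarray()
        nodata_tag = page.tags.get(TAG_GDAL_NODATA)
        sentinel = float(nodata_tag.value) if nodata_tag is not None else None

    values = arr.astype(np.float64)
    if sentinel is not None:
        if arr.dtype == np.uint8:
            values[arr == int(sentinel)] = np.nan
        else:
            values[arr == np.asarray(sentinel, dtype=arr.dtype)] = np.nan
    grid_nodata = sentinel if sentinel is not None and arr.dtype != np.uint8 else -9999.0
    grid = RasterGrid(
        n_rows=arr.shape[0],
        n_cols=arr.shape[1],
        x_min=x_min,
        y_max=y_max,
        resolution=sx,
        nodata=grid_nodata,
    )
    return Layer(grid, name if name is not None else Path(path).stem, values)


def read_occurrences(path: str | os.PathLike) -> OccurrenceSet:
    """Read an occurrence CSV with columns species, longitude, latitude.

    An optional ``precision`` column gives the decimal places of the source
    coordinates; records with one decimal or fewer on both coordinates are
    flagged low-precision (coarser than a 2.5-arcmin pixel).  Without that
    column the decimal places are counted from the coordinate text itself.
    Rows with unparseable or out-of-range coordinates are dropped but counted
    in the returned ``counts_log``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("species", "longitude", "latitude"):
        if col not in raw.columns:
            raise ValueError(f"occurrence file {path}: missing column {col!r}")

    lon = pd.to_numeric(raw["longitude"], errors="coerce")
    lat = pd.to_numeric(raw["latitude"], errors="coerce")
    unparseable = lon.isna() | lat.isna()
    out_of_range = (~unparseable) & (lat.abs() > 90)
    keep = ~(unparseable | out_of_range)

    if "precision" in raw.columns:
        decimals = pd.to_numeric(raw["precision"], errors="coerce")
        low = decimals <= 1
    else:
        low = raw["longitude"].map(_decimal_places).le(1) & raw["latitude"].map(
            _decimal_places
        ).le(1)

    df = pd.DataFrame(
        {
            "species": raw["species"],
            "longitude": _wrap_longitude(lon.to_numpy(dtype=float)),
            "latitude": lat.to_numpy(dtype=float),
            "precision_flag": np.where(low, "low", "exact"),
            "source_id": raw["source_id"]
            if "source_id" in raw.columns
            else [f"row{i}" for i in range(len(raw))],
        }
    )[keep].reset_index(drop=True)
    log = {
        "rows_in_file": len(raw),
        "unparseable_coordinates": int(unparseable.sum()),
        "out_of_range_coordinates": int(out_of_range.sum()),
    }
    return OccurrenceSet(df, "raw", log)


def write_occurrences(occ: OccurrenceSet, path: str | os.PathLike) -> None:
    """Write an occurrence set back to CSV (precision in decimal places)."""
    df = occ.df[COLUMNS].copy()
    df["precision"] = np.where(df.pop("precision_flag") == "low", 1, 6)
    df.to_csv(path, index=False)


def write_manifest(path: str | os.PathLike, **entries) -> None:
    """Write a JSON run manifest (inputs, parameters, seeds) with sorted keys."""
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _wrap_longitude(lon: np.ndarray) -> np.ndarray:
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def _decimal_places(text: str) -> int:
    text = text.strip()
    if "e" in text.lower():
        return 12  # scientific notation: treat as precise
    if "." not in text:
        return 0
    return len(text.split(".", 1)[1].rstrip("0"))
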