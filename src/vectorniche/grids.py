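"""Spatial data model: north-up geographic raster grids and aligned layer stacks.

All coordinates are WGS84 decimal degrees.  Cells are square (``resolution``
degrees on a side) and cell ownership is half-open: cell (r, c) covers

    [x_min + c*res, x_min + (c+1)*res)  x  (y_max - (r+1)*res, y_max - r*res]

so every point inside the bounding box maps to exactly one cell.  Row 0 is the
northernmost row.  Missing data (ocean, unanalyzed area) is carried as NaN in
memory and as the grid's ``nodata`` sentinel on disk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RasterGrid",
    "Layer",
    "EnvStack",
    "CalibrationRegion",
]


@dataclass(frozen=True)
class RasterGrid:
    """Georeferenced grid definition shared by all layers of an analysis.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; both at least 1.
    x_min
        Longitude of the left (west) edge of the grid, degrees.
    y_max
        Latitude of the top (north) edge of the grid, degrees.
    resolution
        Cell size in degrees; cells are square.
    nodata
        Sentinel written to disk for missing cells.
    """

    n_rows: int
    n_cols: int
    x_min: float
    y_max: float
    resolution: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.resolution

    @property
    def y_min(self) -> float:
        return self.y_max - self.n_rows * self.resolution

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    # -- point-to-cell assignment -------------------------------------------

    def cells_of(
        self, lons: np.ndarray, lats: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to cell indices under the half-open convention.

        Returns ``(rows, cols, inside)`` where ``inside`` marks points whose
        coordinates fall within the grid bounding box; rows/cols of outside
        points are clipped and must be ignored.
        """
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        cols = np.floor((lons - self.x_min) / self.resolution).astype(np.int64)
        # latitude interval is open at the bottom, closed at the top:
        # lat == y_max - r*res belongs to row r.
        t = (self.y_max - lats) / self.resolution
        rows = np.floor(t).astype(np.int64)
        inside = (
            (cols >= 0)
            & (cols < self.n_cols)
            & (lats <= self.y_max)
            & (lats > self.y_min)
            & (lons >= self.x_min)
            & (lons < self.x_max)
        )
        rows = np.clip(rows, 0, self.n_rows - 1)
        cols = np.clip(cols, 0, self.n_cols - 1)
        return rows, cols, inside

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Cell index of a single point, or None if outside the grid."""
        r, c, ok = self.cells_of(np.array([lon]), np.array([lat]))
        if not ok[0]:
            return None
        return int(r[0]), int(c[0])

    # -- cell geometry -------------------------------------------------------

    def cell_center(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lon = self.x_min + (np.asarray(cols) + 0.5) * self.resolution
        lat = self.y_max - (np.asarray(rows) + 0.5) * self.resolution
        return lon, lat

    def center_latitudes(self) -> np.ndarray:
        """Latitude of each row's cell centers (length n_rows, north to south)."""
        return self.y_max - (np.arange(self.n_rows) + 0.5) * self.resolution

    def center_longitudes(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.resolution


@dataclass
class Layer:
    """One named raster surface on a grid; NaN marks nodata cells."""

    grid: RasterGrid
    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"does not match grid shape {self.grid.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "Layer":
        return Layer(self.grid, name if name is not None else self.name, values)


@dataclass
class EnvStack:
    """Ordered set of aligned environmental layers plus a scenario tag.

    ``scenario_tag`` is ``"present"`` or a ``(gcm, rcp, period)`` tuple.
    """

    grid: RasterGrid
    layers: list[Layer]
    scenario_tag: object = "present"

    def __post_init__(self) -> None:
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique within a stack")
        for l in self.layers:
            if l.grid != self.grid:
                raise ValueError(f"layer {l.name!r} is on a different grid")
        if self.layers:
            m0 = self.layers[0].valid_mask
            for l in self.layers[1:]:
                if not np.array_equal(l.valid_mask, m0):
                    raise ValueError(
                        f"layer {l.name!r} has a different nodata mask than "
                        f"{self.layers[0].name!r}"
                    )

    @property
    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def get(self, name: str) -> Layer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.layers[0].valid_mask

    def table(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Cell-by-layer value matrix over ``mask`` (default: all valid cells)."""
        if mask is None:
            mask = self.valid_mask
        return np.column_stack([l.values[mask] for l in self.layers])

    def values_at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_points, n_layers) matrix of layer values at the given cells."""
        return np.column_stack([l.values[rows, cols] for l in self.layers])

    def subset(self, names: Sequence[str]) -> "EnvStack":
        return EnvStack(self.grid, [self.get(n) for n in names], self.scenario_tag)


@dataclass(frozen=True)
class CalibrationRegion:
    """Accessible area M: a latitude band, optionally bounded in longitude.

    The accessible area is the part of the world assumed reachable by the
    species; background points are drawn from it and models calibrated on it.
    """

    lat_max: float
    lat_min: float
    lon_min: float | None = None
    lon_max: float | None = None

    def __post_init__(self) -> None:
        if not self.lat_min < self.lat_max:
            raise ValueError("lat_min must be below lat_max")
        if (self.lon_min is None) != (self.lon_max is None):
            raise ValueError("lon_min and lon_max must be given together")
        if self.lon_min is not None and not self.lon_min < self.lon_max:
            raise ValueError("lon_min must be below lon_max")

    def mask(self, grid: RasterGrid) -> np.ndarray:
        """Boolean membership of each cell, judged by its center."""
        lats = grid.center_latitudes()[:, None]
        in_band = (lats >= self.lat_min) & (lats <= self.lat_max)
        m = np.broadcast_to(in_band, grid.shape).copy()
        if self.lon_min is not None:
            lons = grid.center_longitudes()[None, :]
            m &= np.broadcast_to(
                (lons >= self.lon_min) & (lons <= self.lon_max), grid.shape
            )
        return m
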