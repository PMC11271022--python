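"""Gridded land-cover and elevation layers.

Rasters live on the equal-area plane of :mod:`habrange.geo` with square
cells (100 m by default, matching CORINE-style land-cover products).
Values are stored row-major with row 0 at the *top* (largest y), the
convention of the Esri ASCII grid text format used for I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "RasterHeader",
    "CategoricalRaster",
    "ElevationRaster",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass(frozen=True)
class RasterHeader:
    """Georeferencing header shared by land-cover and elevation grids.

    ``origin_x, origin_y`` are the coordinates of the *lower-left*
    corner in meters on the projected plane; cell area is exactly
    ``cell_size**2`` everywhere (equal-area plane).
    """

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 100.0
    nodata_code: int = -9999

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("raster dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size ** 2 / 1e6

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates, each shaped (n_rows, n_cols)."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.n_rows)[::-1] + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cells containing projected points.

        Half-open cells; points outside the raster get index -1 in the
        offending axis marked via out-of-range values (caller checks
        with :meth:`contains`).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row_from_bottom = np.floor((y - self.origin_y) / self.cell_size).astype(int)
        row = self.n_rows - 1 - row_from_bottom
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.index_of(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


@dataclass
class _BaseRaster:
    header: RasterHeader
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.header.n_rows, self.header.n_cols):
            raise ValueError(
                f"value matrix {self.values.shape} does not match header "
                f"({self.header.n_rows}, {self.header.n_cols})"
            )

    def sample(self, x, y) -> np.ndarray:
        """Values at projected points; nodata for points off the raster."""
        row, col = self.header.index_of(x, y)
        inside = self.header.contains(x, y)
        row = np.clip(row, 0, self.header.n_rows - 1)
        col = np.clip(col, 0, self.header.n_cols - 1)
        out = self.values[row, col]
        return np.where(inside, out, self._nodata_value())

    def _nodata_value(self):
        return self.header.nodata_code


@dataclass
class CategoricalRaster(_BaseRaster):
    """Integer class-code mosaic; sea / off-island is the nodata code."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(int)

    @property
    def land_mask(self) -> np.ndarray:
        return self.values != self.header.nodata_code

    @property
    def class_codes(self) -> set[int]:
        return set(np.unique(self.values[self.land_mask]).tolist())


@dataclass
class ElevationRaster(_BaseRaster):
    """Elevation in meters; sea / off-island cells are NaN."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(float)

    def _nodata_value(self):
        return np.nan

    @property
    def land_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def write_ascii_grid(raster: _BaseRaster, path: str | Path) -> None:
    """Write a raster as an Esri ASCII grid (plain-text) file."""
    h = raster.header
    vals = raster.values
    if isinstance(raster, ElevationRaster):
        vals = np.where(np.isfinite(vals), vals, h.nodata_code)
        fmt = "%.3f"
    else:
        fmt = "%d"
    with open(path, "w") as fh:
        fh.write(f"ncols {h.n_cols}\n")
        fh.write(f"nrows {h.n_rows}\n")
        fh.write(f"xllcorner {h.origin_x!r}\n")
        fh.write(f"yllcorner {h.origin_y!r}\n")
        fh.write(f"cellsize {h.cell_size!r}\n")
        fh.write(f"NODATA_value {h.nodata_code}\n")
        np.savetxt(fh, vals, fmt=fmt)


def read_ascii_grid(path: str | Path, kind: str = "categorical"):
    """Read an Esri ASCII grid written by :func:`write_ascii_grid`.

    ``kind`` selects the container: ``"categorical"`` or ``"elevation"``
    (elevation nodata cells become NaN).
    """
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, val = line.split()
            meta[key.lower()] = float(val)
            pos = fh.tell()
        fh.seek(pos)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    header = RasterHeader(
        n_rows=int(meta["nrows"]),
        n_cols=int(meta["ncols"]),
        origin_x=meta["xllcorner"],
        origin_y=meta["yllcorner"],
        cell_size=meta["cellsize"],
        nodata_code=int(meta["nodata_value"]),
    )
    if kind == "categorical":
        return CategoricalRaster(header, data.astype(int))
    if kind == "elevation":
        vals = data.astype(float)
        vals[vals == header.nodata_code] = np.nan
        return ElevationRaster(header, vals)
    raise ValueError(f"unknown raster kind {kind!r}")
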