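"""Planar analysis grid and gridded density surfaces.

All geometry lives in one flat projected coordinate system in metres with the
origin at the lower-left corner of the study region; no geodesy is involved.
Rasters are stored row-major with row 0 at the *bottom* of the region so that
array indices map directly to (row = y, col = x) cell coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "DensityRaster", "write_ascii_grid", "read_ascii_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Regular square-cell grid over a rectangular region.

    Parameters
    ----------
    origin : (float, float)
        (x, y) of the lower-left corner in metres.
    cell_size_m : float
        Side length of the square cells, metres.
    n_cols, n_rows : int
        Grid dimensions.
    """

    origin: tuple[float, float]
    cell_size_m: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be > 0")
        if self.n_cols <= 0 or self.n_rows <= 0:
            raise ValueError("grid dimensions must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size_m**2

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the gridded region."""
        x0, y0 = self.origin
        return (
            x0,
            y0,
            x0 + self.n_cols * self.cell_size_m,
            y0 + self.n_rows * self.cell_size_m,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (xs, ys) of cell-centre coordinates, shape (n_rows, n_cols)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size_m
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size_m
        return np.meshgrid(xs, ys)

    def point_to_cell(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) indices plus an in-grid mask."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size_m).astype(int)
        row = np.floor((y - y0) / self.cell_size_m).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return row, col, inside


@dataclass
class DensityRaster:
    """A gridded nonnegative density surface with an explicit validity mask."""

    grid: GridSpec
    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    year: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if self.valid is None:
            self.valid = np.ones(self.grid.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.grid.shape:
                raise ValueError("valid mask shape does not match grid")
        if np.any(self.values[self.valid] < 0):
            raise ValueError("densities must be nonnegative on valid cells")

    @property
    def mass(self) -> float:
        """Integral of the surface over valid cells (value x cell area)."""
        return float(self.values[self.valid].sum() * self.grid.cell_area_m2)


# -- plain-text raster I/O (ESRI ASCII grid) ---------------------------------

_NODATA = -9999.0


def write_ascii_grid(path: str | Path, raster: DensityRaster) -> None:
    """Write a density raster as an ESRI ASCII grid (text, nodata=-9999)."""
    g = raster.grid
    vals = np.where(raster.valid, raster.values, _NODATA)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin[0]:.6f}\n"
        f"yllcorner {g.origin[1]:.6f}\n"
        f"cellsize {g.cell_size_m:.6f}\n"
        f"NODATA_value {_NODATA:.1f}\n"
    )
    # ASCII grids are written top row first
    body = "\n".join(
        " ".join(f"{v:.8g}" for v in row) for row in vals[::-1]
    )
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> DensityRaster:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    for line in lines[:6]:
        key, val = line.split()
        hdr[key.lower()] = float(val)
    grid = GridSpec(
        origin=(hdr["xllcorner"], hdr["yllcorner"]),
        cell_size_m=hdr["cellsize"],
        n_cols=int(hdr["ncols"]),
        n_rows=int(hdr["nrows"]),
    )
    vals = np.array(
        [[float(v) for v in line.split()] for line in lines[6:] if line.strip()]
    )[::-1]
    nodata = hdr.get("nodata_value", _NODATA)
    valid = vals != nodata
    vals = np.where(valid, vals, 0.0)
    return DensityRaster(grid=grid, values=vals, valid=valid)
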