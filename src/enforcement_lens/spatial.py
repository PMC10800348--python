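"""Spatial-targeting statistic: kernel heatmaps and masked pixel correlation.

The statistic asks how well the spatial concentration of enforcement events
(geolocated infraction notices) matches the concentration of deforestation in
the same year.  Both event sets are rasterized onto a common grid, smoothed
into kernel-density heatmaps, the lowest quantile of each positive surface is
nulled so that only hotspots enter the comparison, and the two maps are
correlated pixel by pixel (Pearson) over the cells valid in both.  A trailing
moving average summarises the annual series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from shapely.geometry.base import BaseGeometry

from .grid import DensityRaster, GridSpec

__all__ = [
    "SpatialMatchConfig",
    "rasterize_events",
    "kernel_density",
    "quartile_mask",
    "spatial_match_correlation",
    "match_series",
]


@dataclass(frozen=True)
class SpatialMatchConfig:
    """Parameters of the heatmap/correlation stage.

    bandwidth_m : kernel support radius (quartic) or truncation radius
        (gaussian, sigma = bandwidth/3).  Default 30 km, the biome-scale
        choice; scale it with the region when working on small test regions.
    kernel : "quartic" (biweight, the common GIS kernel-density convention)
        or "gaussian".
    mask_quantile : fraction of the positive density cells nulled before
        correlation (default: the lowest quartile).
    cell_size_m : analysis cell size.
    """

    bandwidth_m: float = 30_000.0
    kernel: str = "quartic"
    mask_quantile: float = 0.25
    cell_size_m: float = 100.0

    def __post_init__(self) -> None:
        if self.bandwidth_m <= 0:
            raise ValueError("bandwidth_m must be > 0")
        if not 0 <= self.mask_quantile < 1:
            raise ValueError("mask_quantile must be in [0, 1)")
        if self.kernel not in ("quartic", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


class EmptyDensityError(ValueError):
    """No in-grid events to build a density surface from."""


class GridMismatchError(ValueError):
    """Rasters do not share a grid."""


class UndefinedCorrelationError(ValueError):
    """Pearson r undefined (constant surface or too few joint cells)."""


def rasterize_events(events, grid: GridSpec) -> np.ndarray:
    """Bin events onto the grid.

    ``events`` is either an (n, 2) array of point coordinates, in which case
    the result holds per-cell point counts, or an iterable of shapely
    polygons, in which case each cell holds the polygon area falling in it
    divided by the cell area (so values x cell area sum to the total in-grid
    polygon area).
    """
    out = np.zeros(grid.shape, dtype=float)
    events = list(events) if not isinstance(events, np.ndarray) else events
    if len(events) == 0:
        return out
    if isinstance(events[0], BaseGeometry):
        for geom in events:
            _burn_polygon(out, geom, grid)
        return out
    pts = np.asarray(events, dtype=float).reshape(-1, 2)
    row, col, inside = grid.point_to_cell(pts[:, 0], pts[:, 1])
    np.add.at(out, (row[inside], col[inside]), 1.0)
    return out


def _burn_polygon(out: np.ndarray, geom: BaseGeometry, grid: GridSpec) -> None:
    from shapely.geometry import box

    if geom.is_empty or geom.area == 0:
        warnings.warn("skipping degenerate zero-area polygon")
        return
    x0, y0 = grid.origin
    cs = grid.cell_size_m
    minx, miny, maxx, maxy = geom.bounds
    c0 = max(int(np.floor((minx - x0) / cs)), 0)
    c1 = min(int(np.ceil((maxx - x0) / cs)), grid.n_cols)
    r0 = max(int(np.floor((miny - y0) / cs)), 0)
    r1 = min(int(np.ceil((maxy - y0) / cs)), grid.n_rows)
    for r in range(r0, r1):
        for c in range(c0, c1):
            cell = box(x0 + c * cs, y0 + r * cs, x0 + (c + 1) * cs, y0 + (r + 1) * cs)
            a = geom.intersection(cell).area
            if a > 0:
                out[r, c] += a / grid.cell_area_m2


def _kernel_footprint(config: SpatialMatchConfig, cell: float) -> np.ndarray:
    """Kernel weights sampled at cell centres, per square metre."""
    h = config.bandwidth_m
    n = int(np.ceil(h / cell))
    offs = np.arange(-n, n + 1) * cell
    dx, dy = np.meshgrid(offs, offs)
    r2 = dx**2 + dy**2
    if config.kernel == "quartic":
        k = np.where(r2 <= h**2, 3.0 / (np.pi * h**2) * (1.0 - r2 / h**2) ** 2, 0.0)
    else:  # gaussian, sigma = h/3 truncated at h, renormalised for truncation
        sigma = h / 3.0
        k = np.where(
            r2 <= h**2,
            np.exp(-r2 / (2 * sigma**2)) / (2 * np.pi * sigma**2),
            0.0,
        )
        k /= 1.0 - np.exp(-4.5)
    return k


def kernel_density(events, config: SpatialMatchConfig, grid: GridSpec, year: int | None = None) -> DensityRaster:
    """Kernel-density heatmap of point events or deforestation polygons.

    Events are snapped to grid cells and convolved with the kernel, so the
    surface integrates to the in-grid event count (points) or total patch
    area (polygons), up to discretization, for events away from the border.
    No edge correction is applied.
    """
    counts = rasterize_events(events, grid)
    if counts.sum() == 0:
        raise EmptyDensityError("no in-grid events")
    k = _kernel_footprint(config, grid.cell_size_m)
    dens = signal.fftconvolve(counts, k, mode="same")
    np.clip(dens, 0.0, None, out=dens)  # fft round-off can go slightly negative
    return DensityRaster(grid=grid, values=dens, year=year)


def quartile_mask(raster: DensityRaster, q: float | None = None) -> DensityRaster:
    """Null the lowest-``q`` quantile of the positive density cells.

    The threshold is the linear-interpolation sample quantile of the strictly
    positive valid cells; cells strictly below it, and all zero cells, become
    nodata.  Ties at the threshold survive, so at most a fraction ``q`` of
    the positive cells is removed.
    """
    if q is None:
        q = 0.25
    if not 0 <= q < 1:
        raise ValueError("q must be in [0, 1)")
    pos = raster.valid & (raster.values > 0)
    if not pos.any():
        raise ValueError("raster has no positive valid cells")
    thresh = float(np.quantile(raster.values[pos], q))
    keep = pos & (raster.values >= thresh)
    return DensityRaster(grid=raster.grid, values=raster.values, valid=keep, year=raster.year)


def spatial_match_correlation(a: DensityRaster, b: DensityRaster) -> tuple[float, int]:
    """Pearson r between two density rasters over their jointly valid cells."""
    if a.grid != b.grid:
        raise GridMismatchError("rasters are on different grids")
    joint = a.valid & b.valid
    n = int(joint.sum())
    if n < 2:
        raise UndefinedCorrelationError("fewer than 2 jointly valid cells")
    va, vb = a.values[joint], b.values[joint]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise UndefinedCorrelationError("constant raster over the joint support")
    r = float(stats.pearsonr(va, vb).statistic)
    return r, n


def match_series(
    annual_fines: dict[int, np.ndarray],
    annual_deforestation: dict[int, list],
    config: SpatialMatchConfig,
    grid: GridSpec,
    ma_window: int = 4,
) -> pd.DataFrame:
    """Annual spatial-match series with a trailing moving average.

    Parameters
    ----------
    annual_fines : mapping year -> (n, 2) array of geolocated notice points.
    annual_deforestation : mapping year -> list of patch polygons.
    ma_window : moving-average window (default 4 years, trailing, defined
        only where the window is full).

    Returns a DataFrame indexed by year with columns ``r``, ``n_cells`` and
    ``ma`` (NaN where undefined).
    """
    years = sorted(set(annual_fines) & set(annual_deforestation))
    if not years:
        raise ValueError("no overlapping years between fines and deforestation")
    rows = []
    for year in years:
        fines = annual_fines[year]
        patches = annual_deforestation[year]
        if len(fines) == 0 or len(patches) == 0:
            rows.append((year, np.nan, 0))
            continue
        try:
            dens_f = quartile_mask(kernel_density(fines, config, grid, year), config.mask_quantile)
            dens_d = quartile_mask(kernel_density(patches, config, grid, year), config.mask_quantile)
            r, n = spatial_match_correlation(dens_f, dens_d)
        except (EmptyDensityError, UndefinedCorrelationError):
            rows.append((year, np.nan, 0))
            continue
        rows.append((year, r, n))
    df = pd.DataFrame(rows, columns=["year", "r", "n_cells"]).set_index("year")
    df["ma"] = df["r"].rolling(ma_window, min_periods=ma_window).mean()
    return df
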