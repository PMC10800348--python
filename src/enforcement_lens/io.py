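"""Plain-text I/O: GeoJSON vector layers, CSV tables, ASCII-grid rasters.

Geometries are written in the flat projected plane of the analysis (metres);
coordinates are not geographic, and the GeoJSON files carry an ``x-planar``
marker property to make that explicit.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .grid import DensityRaster, GridSpec, read_ascii_grid, write_ascii_grid
from .legality import DeforestationPatch, Landholding, ProtectedArea

__all__ = [
    "write_geojson",
    "read_geojson",
    "write_landscape",
    "read_patches",
    "read_holdings",
    "read_protected_areas",
    "read_streams",
    "write_records_csv",
    "read_records_csv",
]

CSV_FLOAT_FORMAT = "%.10g"


def write_geojson(path: str | Path, features: list[tuple[shapely.Geometry, dict]]) -> None:
    fc = {
        "type": "FeatureCollection",
        "crs-note": "x-planar: local projected metres, origin at region corner",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_geojson(path: str | Path) -> list[tuple[shapely.Geometry, dict]]:
    fc = json.loads(Path(path).read_text())
    return [(shape(f["geometry"]), f.get("properties", {})) for f in fc["features"]]


def write_records_csv(path: str | Path, records: pd.DataFrame) -> None:
    df = records.copy()
    for col in ("date", "filed_date", "stage_date"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def read_records_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("date", "filed_date", "stage_date"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


def write_landscape(outdir: str | Path, landscape) -> None:
    """Write a synthetic landscape as GeoJSON + ASCII grid + CSV files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_geojson(
        out / "holdings.geojson",
        [
            (h.polygon, {"holding_id": h.holding_id, "category": h.category,
                         "lr_deficit_truth": h.holding_id in landscape.deficit_holding_ids})
            for h in landscape.holdings
        ],
    )
    write_geojson(
        out / "protected_areas.geojson",
        [(pa.polygon, {"pa_id": pa.pa_id, "pa_class": pa.pa_class}) for pa in landscape.protected_areas],
    )
    write_geojson(
        out / "streams.geojson",
        [(s, {"stream_id": i}) for i, s in enumerate(landscape.streams)],
    )
    write_geojson(
        out / "patches.geojson",
        [(p.polygon, {"patch_id": p.patch_id, "year": p.year, "area_ha": round(p.area_ha, 4)})
         for p in landscape.patches],
    )
    write_ascii_grid(
        out / "native_map.asc",
        DensityRaster(grid=landscape.grid, values=landscape.native_map.astype(float),
                      valid=landscape.native_map != 255),
    )
    landscape.ground_truth.to_csv(out / "ground_truth_patches.csv", index=False,
                                  float_format=CSV_FLOAT_FORMAT)


def read_holdings(path: str | Path) -> list[Landholding]:
    return [
        Landholding(p["holding_id"], geom, p.get("category", "landholding"))
        for geom, p in read_geojson(path)
    ]


def read_protected_areas(path: str | Path) -> list[ProtectedArea]:
    return [ProtectedArea(p["pa_id"], geom, p["pa_class"]) for geom, p in read_geojson(path)]


def read_streams(path: str | Path):
    return [geom for geom, _ in read_geojson(path)]


def read_patches(path: str | Path) -> list[DeforestationPatch]:
    return [
        DeforestationPatch(p["patch_id"], geom, int(p["year"])) for geom, p in read_geojson(path)
    ]


def read_native_map(path: str | Path) -> tuple[GridSpec, "object"]:
    raster = read_ascii_grid(path)
    import numpy as np

    native = raster.values.astype(np.uint8)
    native[~raster.valid] = 255
    return raster.grid, native
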