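"""File formats: NetCDF rasters, GeoJSON polygons, CSV tables.

Raster stacks (land use, biome maps) travel as CF-style NetCDF with
``(time, lat, lon)`` dimensions — one variable per land-use class, the
variant recorded as a global attribute. Species extents of occurrence are
GeoJSON FeatureCollections with ``species_id``/``group`` properties plus a
CSV preference table; the habitat-category crosswalk and all tidy outputs
are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import xarray as xr

from .grid import GridSpec, polygon_coverage
from .landuse import CLASSES, LandUseSeries
from .ranges import BiomeMap, HabitatCrosswalk, SpeciesRecord

_ENGINE = "scipy"  # NetCDF3 classic


def _grid_coords(grid: GridSpec) -> dict:
    return {"lat": grid.lat_centers(), "lon": grid.lon_centers()}


def grid_from_coords(lat: np.ndarray, lon: np.ndarray) -> GridSpec:
    """Reconstruct an edge-registered GridSpec from cell-centre coordinates."""
    res = float(abs(lat[1] - lat[0])) if len(lat) > 1 else float(abs(lon[1] - lon[0]))
    lat_max = float(max(lat)) + res / 2
    lat_min = float(min(lat)) - res / 2
    lon_min = float(min(lon)) - res / 2
    lon_max = float(max(lon)) + res / 2
    return GridSpec(res, lat_min, lat_max, lon_min, lon_max)


def write_landuse(series: LandUseSeries, path, variant: str = "baseline") -> None:
    """One variant of a land-use series as NetCDF (variables per class)."""
    ds = xr.Dataset(
        {c: (("time", "lat", "lon"), series.data[(c, variant)]) for c in CLASSES},
        coords={"time": series.years, **_grid_coords(series.grid)},
        attrs={"variant": variant},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_landuse(paths) -> LandUseSeries:
    """Read one or more per-variant NetCDF files into a LandUseSeries."""
    paths = [paths] if isinstance(paths, (str, Path)) else list(paths)
    data, grid, years = {}, None, None
    for p in paths:
        with xr.open_dataset(p, engine=_ENGINE) as ds:
            variant = ds.attrs.get("variant", "baseline")
            g = grid_from_coords(ds["lat"].values, ds["lon"].values)
            y = ds["time"].values.astype(int)
            if grid is None:
                grid, years = g, y
            elif g != grid or not np.array_equal(y, years):
                raise ValueError(f"{p}: grid/time mismatch across variants")
            for c in CLASSES:
                data[(c, variant)] = ds[c].values.copy()
    return LandUseSeries(grid=grid, years=years, data=data)


def write_biomes(maps: list[BiomeMap], path) -> None:
    grid = maps[0].grid
    codes = np.stack([m.codes for m in maps])
    ds = xr.Dataset(
        {"biome": (("time", "lat", "lon"), codes.astype(np.int32))},
        coords={"time": [m.year for m in maps], **_grid_coords(grid)},
        attrs={"code_list": ",".join(str(c) for c in maps[0].code_list)},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_biomes(path) -> list[BiomeMap]:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        grid = grid_from_coords(ds["lat"].values, ds["lon"].values)
        code_list = tuple(
            int(c) for c in str(ds.attrs.get("code_list", "")).split(",") if c
        )
        return [
            BiomeMap(int(t), grid, ds["biome"].values[i].copy(), code_list=code_list)
            for i, t in enumerate(ds["time"].values)
        ]


def write_species_geojson(features: list[tuple[str, str, shapely.Geometry]], path) -> None:
    """``features`` is a list of (species_id, group, polygon)."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"species_id": sid, "group": group},
                "geometry": shapely.geometry.mapping(geom),
            }
            for sid, group, geom in features
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_species(
    geojson_path,
    preferences_csv,
    crosswalk: HabitatCrosswalk,
    fine_grid: GridSpec,
    coarse_grid: GridSpec,
) -> list[SpeciesRecord]:
    """Species from EOO polygons (GeoJSON) and a habitat-preference table.

    The preference CSV has columns species_id, habitat_categories
    (";"-separated category codes); suitable biome and artificial-class
    sets are derived through the crosswalk. Species whose EOO overlaps no
    fine-cell centre are dropped.
    """
    fc = json.loads(Path(geojson_path).read_text())
    prefs = pd.read_csv(preferences_csv)
    cats = {
        row["species_id"]: [c for c in str(row["habitat_categories"]).split(";") if c]
        for _, row in prefs.iterrows()
    }
    out = []
    for feat in fc["features"]:
        sid = feat["properties"]["species_id"]
        group = feat["properties"].get("group", "")
        geom = shapely.geometry.shape(feat["geometry"])
        eoo = polygon_coverage(geom, fine_grid, coarse_grid)
        if eoo.sum() <= 0 or sid not in cats:
            continue
        out.append(
            SpeciesRecord(
                species_id=sid,
                group=group,
                eoo_fraction=eoo,
                suitable_biomes=crosswalk.suitable_biomes(cats[sid]),
                suitable_artificial=crosswalk.suitable_artificial(cats[sid]),
            )
        )
    return out


def read_crosswalk(path) -> HabitatCrosswalk:
    return HabitatCrosswalk.from_frame(pd.read_csv(path))


def write_crosswalk(cw: HabitatCrosswalk, path) -> None:
    rows = [
        {
            "category_code": cat,
            "biome_codes": ";".join(str(b) for b in sorted(cw.natural.get(cat, ()))),
            "artificial_flags": ";".join(sorted(cw.artificial.get(cat, ()))),
        }
        for cat in sorted(set(cw.natural) | set(cw.artificial))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
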