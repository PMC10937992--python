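"""File formats: NetCDF fields, GeoJSON/label-raster regions, CSV tables.

NetCDF is written through xarray's scipy backend (classic NetCDF) with
CF-style coordinate variables ``time, lat, lon``; round-trips preserve
values, coordinates, the units attribute and the missing-data mask
exactly.  Regions are exchanged either as GeoJSON polygon features (one
feature per region, rasterized by the cell-center-in-polygon rule) or as
an integer label raster.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from shapely.geometry import box, shape, mapping
from shapely.ops import unary_union

from .grids import ConcentrationField, Grid, PopulationGrid, RegionSet
from .indicators import GuidelineSet, PollutantGuideline

__all__ = [
    "write_field",
    "read_field",
    "write_population",
    "read_population",
    "write_regions_geojson",
    "read_regions",
    "write_label_raster",
    "write_stations_csv",
    "read_stations_csv",
    "read_guidelines",
    "write_guidelines",
]

_ENGINE = "scipy"


def write_field(field: ConcentrationField, path) -> None:
    """Write a daily concentration field as NetCDF (time, lat, lon)."""
    da = field.to_dataarray()
    ds = da.to_dataset(name=field.pollutant)
    ds[field.pollutant].attrs["units"] = field.units
    ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
    ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
    ds.to_netcdf(path, engine=_ENGINE)


def read_field(path, pollutant: str | None = None) -> ConcentrationField:
    """Read a daily concentration field from NetCDF.

    The file must carry ``time``, ``lat`` and ``lon`` coordinate
    variables with a contiguous daily time axis and monotone coordinates;
    descending axes are normalized to ascending.
    """
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = ds.load()
    for coord in ("time", "lat", "lon"):
        if coord not in ds.coords and coord not in ds.variables:
            raise ValueError(f"NetCDF file lacks required coordinate {coord!r}")
    if pollutant is None:
        names = [v for v in ds.data_vars if set(ds[v].dims) == {"time", "lat", "lon"}]
        if len(names) != 1:
            raise ValueError(
                f"expected exactly one (time, lat, lon) variable, found {names}"
            )
        pollutant = names[0]
    return ConcentrationField.from_dataarray(ds[pollutant], pollutant=pollutant)


def write_population(pop: PopulationGrid, path) -> None:
    da = xr.DataArray(
        pop.counts,
        dims=("lat", "lon"),
        coords={"lat": pop.grid.lat, "lon": pop.grid.lon},
        name="population",
        attrs={"units": "persons"},
    )
    da.to_dataset().to_netcdf(path, engine=_ENGINE)


def read_population(path) -> PopulationGrid:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = ds.load()
    if "population" not in ds:
        raise ValueError("NetCDF file lacks a 'population' variable")
    da = ds["population"]
    lat = np.asarray(da["lat"].values, dtype=float)
    lon = np.asarray(da["lon"].values, dtype=float)
    vals = np.asarray(da.values, dtype=float)
    if lat.size > 1 and lat[0] > lat[-1]:
        lat, vals = lat[::-1], vals[::-1, :]
    if lon.size > 1 and lon[0] > lon[-1]:
        lon, vals = lon[::-1], vals[:, ::-1]
    return PopulationGrid(grid=Grid(lat=lat, lon=lon), counts=vals)


# ---------------------------------------------------------------------------
# regions


def _cell_box(grid: Grid, i: int, j: int):
    h = grid.resolution / 2.0
    return box(grid.lon[j] - h, grid.lat[i] - h, grid.lon[j] + h, grid.lat[i] + h)


def write_regions_geojson(regions: RegionSet, grid: Grid, path) -> None:
    """Write regions as GeoJSON polygon features (union of member cells)."""
    features = []
    for rid in regions.region_ids:
        m = regions.mask(rid)
        cells = [_cell_box(grid, i, j) for i, j in zip(*np.nonzero(m))]
        geom = unary_union(cells)
        features.append(
            {
                "type": "Feature",
                "properties": {"region_id": rid},
                "geometry": mapping(geom),
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(fc))


def write_label_raster(regions: RegionSet, grid: Grid, path) -> None:
    """Write the cell-to-region assignment as an integer label raster with
    the region-id table stored as an attribute."""
    da = xr.DataArray(
        regions.labels,
        dims=("lat", "lon"),
        coords={"lat": grid.lat, "lon": grid.lon},
        name="region_label",
        attrs={"region_ids": json.dumps(list(regions.region_ids))},
    )
    da.to_dataset().to_netcdf(path, engine=_ENGINE)


def read_regions(path, grid: Grid | None = None) -> RegionSet:
    """Read a RegionSet from GeoJSON polygons or a label raster.

    GeoJSON features are rasterized onto ``grid`` by the
    cell-center-in-polygon rule; overlapping polygons are resolved by
    first-listed priority with a warning.  A non-geographic CRS is
    rejected.  Label rasters pass through directly.
    """
    path = Path(path)
    if path.suffix.lower() in {".json", ".geojson"}:
        if grid is None:
            raise ValueError("rasterizing GeoJSON regions requires a grid")
        return _read_regions_geojson(path, grid)
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = ds.load()
    if "region_label" not in ds:
        raise ValueError("label raster lacks a 'region_label' variable")
    da = ds["region_label"]
    ids = json.loads(da.attrs["region_ids"])
    return RegionSet(region_ids=ids, labels=np.asarray(da.values, dtype=int))


_GEOGRAPHIC_CRS = {
    "urn:ogc:def:crs:OGC:1.3:CRS84",
    "urn:ogc:def:crs:EPSG::4326",
    "EPSG:4326",
    "CRS84",
}


def _read_regions_geojson(path: Path, grid: Grid) -> RegionSet:
    fc = json.loads(Path(path).read_text())
    crs = fc.get("crs", {}).get("properties", {}).get("name")
    if crs is not None and crs not in _GEOGRAPHIC_CRS:
        raise ValueError(f"regions must be in geographic lat-lon, got CRS {crs!r}")
    n_lat, n_lon = grid.shape
    labels = np.full((n_lat, n_lon), -1, dtype=int)
    ids: list[str] = []
    overlap = 0
    lon_grid, lat_grid = np.meshgrid(grid.lon, grid.lat)
    try:
        from shapely import points as _mk_points, covers as _covers

        pts = _mk_points(np.column_stack([lon_grid.ravel(), lat_grid.ravel()]))
    except ImportError:  # pragma: no cover - older shapely
        from shapely.geometry import Point

        pts = np.array([Point(x, y) for x, y in
                        zip(lon_grid.ravel(), lat_grid.ravel())], dtype=object)
        _covers = np.vectorize(lambda g, p: g.covers(p))
    for k, feat in enumerate(fc.get("features", [])):
        rid = str(feat.get("properties", {}).get("region_id", k))
        geom = shape(feat["geometry"])
        inside = _covers(geom, pts).reshape(n_lat, n_lon)
        overlap += int(np.sum(inside & (labels >= 0)))
        take = inside & (labels < 0)
        labels[take] = len(ids)
        ids.append(rid)
        if not take.any():
            warnings.warn(f"region {rid!r} contains no (unclaimed) cell centers",
                          stacklevel=3)
    if overlap:
        warnings.warn(
            f"{overlap} cell(s) covered by multiple region polygons; "
            "resolved by first-listed priority",
            stacklevel=3,
        )
    if np.any(labels < 0):
        n_missing = int(np.sum(labels < 0))
        raise ValueError(f"{n_missing} grid cell(s) fall outside every region polygon")
    return RegionSet(region_ids=ids, labels=labels)


# ---------------------------------------------------------------------------
# station CSV


def write_stations_csv(samples, path) -> None:
    """Write station samples as CSV (station_id, lat, lon, pollutant,
    ISO-8601 date, value in µg/m³)."""
    from .synth import stations_to_frame

    df = samples if isinstance(samples, pd.DataFrame) else stations_to_frame(samples)
    df = df.copy()
    df["date"] = pd.DatetimeIndex(df["date"]).strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_stations_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"station_id", "lat", "lon", "pollutant", "date", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"station CSV lacks columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# guideline configuration


def write_guidelines(gs: GuidelineSet, path) -> None:
    doc = {
        "compliance_fraction": gs.compliance_fraction,
        "pollutants": {
            p: {
                "short_term_limit": g.short_term_limit,
                "long_term_limit": g.long_term_limit,
                "long_term_basis": g.long_term_basis,
            }
            for p, g in gs.limits.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc))


def read_guidelines(path) -> GuidelineSet:
    doc = yaml.safe_load(Path(path).read_text())
    limits = {
        p: PollutantGuideline(
            short_term_limit=float(v["short_term_limit"]),
            long_term_limit=float(v["long_term_limit"]),
            long_term_basis=v.get("long_term_basis", "annual"),
        )
        for p, v in doc["pollutants"].items()
    }
    return GuidelineSet(limits=limits,
                        compliance_fraction=float(doc.get("compliance_fraction", 0.99)))
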