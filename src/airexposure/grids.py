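"""Grid containers and grid algebra.

Conventions
-----------
Coordinates are *cell centers* on a regular geographic (lat-lon) grid with
uniform spacing; a cell is the half-open box
``[center - res/2, center + res/2)`` in each axis.  All distances, buffers
and areas are expressed in geographic degrees (no projection).

The containers here are deliberately thin: a :class:`ConcentrationField` is
a ``time x lat x lon`` array of daily pollutant concentrations (µg/m³, NaN
for missing), a :class:`PopulationGrid` is a static ``lat x lon`` person
count surface, and a :class:`RegionSet` assigns every cell to a reporting
region (integer labels, or fractional weights for border cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "Grid",
    "ConcentrationField",
    "PopulationGrid",
    "RegionSet",
    "bilinear_resample",
    "nearest_resample",
    "extract_at_station",
    "pw_regional_series",
]

_SPACING_RTOL = 1e-6


def _check_axis(name: str, centers: np.ndarray) -> float:
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 1 or centers.size < 1:
        raise ValueError(f"{name} centers must be a 1-d array")
    if centers.size == 1:
        return np.nan
    steps = np.diff(centers)
    if np.any(steps <= 0):
        raise ValueError(f"{name} centers must be strictly ascending")
    step = steps.mean()
    if not np.allclose(steps, step, rtol=_SPACING_RTOL, atol=step * _SPACING_RTOL):
        raise ValueError(f"{name} centers must be uniformly spaced")
    return float(step)


@dataclass(frozen=True)
class Grid:
    """Regular lat-lon grid of cell centers (degrees, ascending)."""

    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lat", np.asarray(self.lat, dtype=float))
        object.__setattr__(self, "lon", np.asarray(self.lon, dtype=float))
        dlat = _check_axis("lat", self.lat)
        dlon = _check_axis("lon", self.lon)
        res = dlat if np.isfinite(dlat) else dlon
        object.__setattr__(self, "_resolution", res)

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    @property
    def resolution(self) -> float:
        """Grid spacing in degrees (mean of axis spacings)."""
        return self._resolution  # type: ignore[attr-defined]

    @property
    def n_cells(self) -> int:
        return self.lat.size * self.lon.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Grid):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.lat, other.lat)
            and np.allclose(self.lon, other.lon)
        )

    def __hash__(self) -> int:  # frozen dataclass with arrays
        return hash((self.lat.tobytes(), self.lon.tobytes()))

    @classmethod
    def regular(cls, n_lat: int, n_lon: int, resolution: float = 0.1,
                lat0: float = 40.0, lon0: float = 0.0) -> "Grid":
        """Build an ``n_lat x n_lon`` grid with south-west corner cell center
        at ``(lat0, lon0)``."""
        return cls(
            lat=lat0 + resolution * np.arange(n_lat),
            lon=lon0 + resolution * np.arange(n_lon),
        )

    def contains(self, lat: float, lon: float) -> bool:
        """Whether a point lies within the grid's cell coverage."""
        h = self.resolution / 2.0
        return (
            self.lat[0] - h <= lat < self.lat[-1] + h
            and self.lon[0] - h <= lon < self.lon[-1] + h
        )


def _require_daily(dates: pd.DatetimeIndex) -> pd.DatetimeIndex:
    dates = pd.DatetimeIndex(dates)
    if len(dates) > 1:
        deltas = np.unique(np.diff(dates.values).astype("timedelta64[D]"))
        if deltas.size != 1 or deltas[0] != np.timedelta64(1, "D"):
            raise ValueError("dates must be a contiguous daily calendar")
    return dates


@dataclass
class ConcentrationField:
    """Daily pollutant concentrations on a grid (``time x lat x lon``, µg/m³).

    Missing values are NaN.  Present values must be nonnegative.
    """

    pollutant: str
    grid: Grid
    dates: pd.DatetimeIndex
    values: np.ndarray
    units: str = "ug/m3"

    def __post_init__(self) -> None:
        self.dates = _require_daily(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.dates),) + self.grid.shape
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != (time, lat, lon) {expected}"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("concentration values must be nonnegative")

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.dates.year)

    def sel_year(self, year: int) -> "ConcentrationField":
        m = self.dates.year == year
        if not m.any():
            raise ValueError(f"year {year} outside field span")
        return ConcentrationField(
            self.pollutant, self.grid, self.dates[m], self.values[m], self.units
        )

    def to_dataarray(self) -> xr.DataArray:
        da = xr.DataArray(
            self.values,
            dims=("time", "lat", "lon"),
            coords={"time": self.dates, "lat": self.grid.lat, "lon": self.grid.lon},
            name=self.pollutant,
        )
        da.attrs["units"] = self.units
        return da

    @classmethod
    def from_dataarray(cls, da: xr.DataArray, pollutant: str | None = None
                       ) -> "ConcentrationField":
        lat = np.asarray(da["lat"].values, dtype=float)
        lon = np.asarray(da["lon"].values, dtype=float)
        vals = np.asarray(da.transpose("time", "lat", "lon").values, dtype=float)
        dates = pd.DatetimeIndex(da["time"].values)
        # stored grids may come in descending order; normalize to ascending
        if lat.size > 1 and lat[0] > lat[-1]:
            lat, vals = lat[::-1], vals[:, ::-1, :]
        if lon.size > 1 and lon[0] > lon[-1]:
            lon, vals = lon[::-1], vals[:, :, ::-1]
        return cls(
            pollutant=pollutant or str(da.name),
            grid=Grid(lat=lat, lon=lon),
            dates=dates,
            values=vals,
            units=str(da.attrs.get("units", "ug/m3")),
        )


@dataclass
class PopulationGrid:
    """Static per-cell population counts (persons) on a grid."""

    grid: Grid
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != self.grid.shape:
            raise ValueError("population counts must match the grid shape")
        if np.any(~np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("population counts must be finite and nonnegative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class RegionSet:
    """Cell-to-region assignment.

    ``labels`` holds, per cell, the integer index into ``region_ids``.  An
    optional ``fractions`` mapping supplies fractional cell-region weights
    for border cells (per-cell weights sum to 1 across regions); when absent
    membership is whole-cell.
    """

    region_ids: Sequence[str]
    labels: np.ndarray
    fractions: Mapping[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.region_ids = list(self.region_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.fractions is None:
            present = np.unique(self.labels)
            if present.min() < 0 or present.max() >= len(self.region_ids):
                raise ValueError("labels refer to unknown region indices")
            if present.size < len(self.region_ids):
                missing = set(range(len(self.region_ids))) - set(present.tolist())
                warnings.warn(
                    f"regions with no cells: {[self.region_ids[i] for i in sorted(missing)]}",
                    stacklevel=2,
                )
        else:
            total = np.zeros_like(self.labels, dtype=float)
            for rid, w in self.fractions.items():
                if rid not in self.region_ids:
                    raise ValueError(f"fraction weights for unknown region {rid!r}")
                total += np.asarray(w, dtype=float)
            if not np.allclose(total, 1.0):
                raise ValueError("fractional weights must sum to 1 per cell")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def cell_weights(self, region_id: str) -> np.ndarray:
        """Per-cell membership weight of ``region_id`` (0/1, or fractional)."""
        if self.fractions is not None:
            return np.asarray(self.fractions[region_id], dtype=float)
        idx = self.region_ids.index(region_id)
        return (self.labels == idx).astype(float)

    def mask(self, region_id: str) -> np.ndarray:
        return self.cell_weights(region_id) > 0


# ---------------------------------------------------------------------------
# resampling


def bilinear_resample(field: ConcentrationField, target: Grid) -> ConcentrationField:
    """Bilinearly interpolate a daily field onto ``target`` cell centers.

    Target centers outside the source coverage become missing; fully
    disjoint domains raise.
    """
    src = field.grid
    if (target.lat[0] > src.lat[-1] or target.lat[-1] < src.lat[0]
            or target.lon[0] > src.lon[-1] or target.lon[-1] < src.lon[0]):
        raise ValueError("target grid domain is disjoint from the source grid")
    da = field.to_dataarray()
    out = da.interp(lat=target.lat, lon=target.lon, method="linear")
    return ConcentrationField(
        pollutant=field.pollutant,
        grid=target,
        dates=field.dates,
        values=np.asarray(out.values, dtype=float),
        units=field.units,
    )


def _nearest_indices(src: np.ndarray, tgt: np.ndarray) -> np.ndarray:
    # argmin over |src - t| returns the first (lower-index) minimum, which is
    # the documented tie-break for equidistant midpoints
    return np.argmin(np.abs(src[None, :] - tgt[:, None]), axis=1)


def nearest_resample(values: np.ndarray, source: Grid, target: Grid) -> np.ndarray:
    """Nearest-neighbour resampling for categorical rasters.

    Each target cell takes the category of the nearest source center; exact
    midpoint ties break toward the lower-index source cell.  ``values`` may
    be ``lat x lon`` or ``time x lat x lon``.
    """
    values = np.asarray(values)
    ilat = _nearest_indices(source.lat, target.lat)
    ilon = _nearest_indices(source.lon, target.lon)
    if values.ndim == 2:
        return values[np.ix_(ilat, ilon)]
    if values.ndim == 3:
        return values[:, ilat[:, None], ilon[None, :]]
    raise ValueError("values must be 2-d or 3-d")


# ---------------------------------------------------------------------------
# buffered station extraction


def _axis_overlap(centers: np.ndarray, res: float, lo: float, hi: float) -> np.ndarray:
    cell_lo = centers - res / 2.0
    cell_hi = centers + res / 2.0
    return np.clip(np.minimum(cell_hi, hi) - np.maximum(cell_lo, lo), 0.0, None)


def extract_at_station(
    values: np.ndarray,
    grid: Grid,
    lat: float,
    lon: float,
    buffer_deg: float = 0.05,
    mode: str = "continuous",
):
    """Extract a value at a station via a square degree buffer.

    The buffer is the square ``[lat±buffer_deg] x [lon±buffer_deg]``.
    Continuous mode returns the overlap-area-weighted mean of intersecting
    cells; categorical mode returns the modal category by overlap area, ties
    broken toward the lower category id.  ``values`` may be 2-d (one number)
    or 3-d time-first (a vector over time).
    """
    res = grid.resolution
    wlat = _axis_overlap(grid.lat, res, lat - buffer_deg, lat + buffer_deg)
    wlon = _axis_overlap(grid.lon, res, lon - buffer_deg, lon + buffer_deg)
    w = np.outer(wlat, wlon)
    if w.sum() <= 0:
        raise ValueError("station buffer lies entirely outside the grid domain")
    values = np.asarray(values)
    if mode == "continuous":
        if values.ndim == 2:
            finite = np.isfinite(values)
            den = (w * finite).sum()
            if den <= 0:
                return np.nan
            return float(np.nansum(w * np.where(finite, values, 0.0)) / den)
        finite = np.isfinite(values)
        den = np.einsum("ij,tij->t", w, finite.astype(float))
        num = np.einsum("ij,tij->t", w, np.where(finite, values, 0.0))
        with np.errstate(invalid="ignore"):
            return np.where(den > 0, num / den, np.nan)
    if mode == "categorical":
        if values.ndim != 2:
            raise ValueError("categorical extraction expects a 2-d raster")
        cats = np.unique(values[w > 0])
        areas = np.array([w[(values == c) & (w > 0)].sum() for c in cats])
        return cats[int(np.argmax(areas))]  # first max = lowest category id
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# population-weighted regional aggregation

MASKED_POP_WARN_FRACTION = 0.25


def pw_regional_series(
    field: ConcentrationField,
    pop: PopulationGrid,
    regions: RegionSet,
) -> pd.DataFrame:
    """Daily population-weighted regional concentration series.

    ``PW(r, t) = sum_{g in r} P(g) C(g, t) / sum_{g in r} P(g)``, with
    missing cells excluded from numerator and denominator that day.
    Zero-population regions yield all-NaN columns with a warning; days on
    which more than 25% of a region's population sits under missing cells
    are flagged with a warning.

    Returns a DataFrame indexed by date with one column per region id.
    """
    if field.grid != pop.grid:
        raise ValueError("concentration field and population use different grids")
    vals = field.values.reshape(len(field.dates), -1)
    finite = np.isfinite(vals)
    filled = np.where(finite, vals, 0.0)
    out = {}
    for rid in regions.region_ids:
        w = (regions.cell_weights(rid) * pop.counts).ravel()
        wtot = w.sum()
        if wtot <= 0:
            warnings.warn(f"region {rid!r} has zero population; PW undefined",
                          stacklevel=2)
            out[rid] = np.full(len(field.dates), np.nan)
            continue
        den = finite @ w
        num = filled @ w
        masked_frac = 1.0 - den / wtot
        if np.any(masked_frac > MASKED_POP_WARN_FRACTION):
            nbad = int(np.sum(masked_frac > MASKED_POP_WARN_FRACTION))
            warnings.warn(
                f"region {rid!r}: >{MASKED_POP_WARN_FRACTION:.0%} of population "
                f"masked on {nbad} day(s)",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            out[rid] = np.where(den > 0, num / den, np.nan)
    return pd.DataFrame(out, index=field.dates, columns=list(regions.region_ids))
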