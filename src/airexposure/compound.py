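"""Compound air-pollution episode accounting.

A *compound event day* is a cell-day on which two or more pollutants
simultaneously exceed their WHO daily limits.  Categories are **exact**
pollutant sets and mutually exclusive: a day on which PM2.5, PM10 and NO2
all exceed belongs to the triple category only and is never also counted
under PM25+PM10 or PM25+NO2.  Category labels are "+"-joined sorted
pollutant codes (e.g. ``NO2+PM25``).

Missing data for a pollutant on a cell-day counts as non-exceedance; the
fraction of such cell-days is reported in the field's coverage statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import PopulationGrid, RegionSet
from .indicators import ExceedanceField, _person_day_exposure

__all__ = [
    "CompoundField",
    "category_label",
    "compound_mask",
    "compound_exposure_time",
    "compound_composition",
    "population_with_any_compound",
    "compound_share_of_unclean",
    "seasonal_profile",
]


def category_label(pollutants) -> str:
    """Canonical "+"-joined sorted label for a pollutant set."""
    return "+".join(sorted(pollutants))


@dataclass
class CompoundField:
    """Per cell-day exact set of exceeding pollutants, as a bitmask.

    Bit ``k`` of ``bits`` is set when ``pollutants[k]`` exceeds that
    cell-day; a cell-day is a compound event day when at least two bits
    are set.  ``coverage`` is the fraction of pollutant-cell-days with
    data present.
    """

    pollutants: tuple[str, ...]
    dates: pd.DatetimeIndex
    bits: np.ndarray  # integer time x lat x lon
    n_exceeding: np.ndarray  # popcount of bits
    coverage: float

    @property
    def is_compound(self) -> np.ndarray:
        return self.n_exceeding >= 2

    def category_bits(self, pollutants) -> int:
        b = 0
        for p in pollutants:
            b |= 1 << self.pollutants.index(p)
        return b

    def categories_present(self) -> list[tuple[str, ...]]:
        """Sorted list of exact compound categories occurring in the field."""
        vals = np.unique(self.bits[self.is_compound])
        cats = []
        for v in vals:
            members = tuple(
                sorted(p for k, p in enumerate(self.pollutants) if v >> k & 1)
            )
            cats.append(members)
        return sorted(cats)

    def sel_year(self, year: int) -> "CompoundField":
        m = self.dates.year == year
        if not m.any():
            raise ValueError(f"year {year} outside field span")
        return CompoundField(
            self.pollutants, self.dates[m], self.bits[m], self.n_exceeding[m],
            self.coverage,
        )

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.dates.year)


def compound_mask(exceedances: dict[str, ExceedanceField]) -> CompoundField:
    """Combine per-pollutant exceedance fields into a compound field.

    All fields must share grid and dates.  A pollutant missing on a
    cell-day is treated as not exceeding; overall data coverage is
    reported on the result.
    """
    if len(exceedances) < 2:
        raise ValueError("need at least two pollutants for compound detection")
    pollutants = tuple(exceedances.keys())
    ref = exceedances[pollutants[0]]
    bits = np.zeros(ref.exceeded.shape, dtype=np.int32)
    n_valid = 0
    for k, pol in enumerate(pollutants):
        f = exceedances[pol]
        if f.exceeded.shape != ref.exceeded.shape or not f.dates.equals(ref.dates):
            raise ValueError("exceedance fields must share grid and dates")
        bits |= f.exceeded.astype(np.int32) << k
        n_valid += int(f.valid.sum())
    coverage = n_valid / (len(pollutants) * ref.exceeded.size)
    n_exceeding = np.zeros(bits.shape, dtype=np.int8)
    for k in range(len(pollutants)):
        n_exceeding += (bits >> k & 1).astype(np.int8)
    return CompoundField(
        pollutants=pollutants,
        dates=ref.dates,
        bits=bits,
        n_exceeding=n_exceeding,
        coverage=coverage,
    )


def _select_year(cf: CompoundField, year: int | None) -> CompoundField:
    if year is not None:
        return cf.sel_year(year)
    if cf.years.size > 1:
        raise ValueError("multiple years present; pass year= explicitly")
    return cf


def compound_exposure_time(
    cf: CompoundField,
    pop: PopulationGrid,
    regions: RegionSet,
    year: int | None = None,
    category: tuple[str, ...] | None = None,
) -> pd.Series:
    """Annual compound unclean-air exposure time per region (days).

    With ``category=None`` counts any-compound days (two or more
    pollutants exceeding); with a pollutant tuple counts days whose exact
    exceeding set equals that category.  Same person-day formula as
    single-pollutant unclean exposure time.
    """
    cf = _select_year(cf, year)
    if category is None:
        indicator = cf.is_compound
    else:
        target = cf.category_bits(category)
        if bin(target).count("1") < 2:
            raise ValueError("a compound category needs at least two pollutants")
        indicator = cf.bits == target
    n_days = indicator.sum(axis=0).astype(float)
    return _person_day_exposure(n_days, pop, regions)


def compound_exposure_by_category(
    cf: CompoundField,
    pop: PopulationGrid,
    regions: RegionSet,
    year: int | None = None,
) -> pd.DataFrame:
    """Per-category exposure time table (regions x category labels).

    Categories are exact sets, so rows sum to the any-compound exposure
    time.
    """
    cf = _select_year(cf, year)
    cols = {}
    for cat in cf.categories_present():
        cols[category_label(cat)] = compound_exposure_time(
            cf, pop, regions, category=cat
        )
    if not cols:
        return pd.DataFrame(index=list(regions.region_ids))
    return pd.DataFrame(cols)


def compound_composition(category_days: pd.Series) -> pd.Series:
    """Fraction of compound exposure per category (sums to 1).

    ``category_days`` maps category label -> nonnegative exposure days.
    All-zero input is undefined and returns NaN fractions with a warning.
    """
    if (category_days < 0).any():
        raise ValueError("category exposure days must be nonnegative")
    total = category_days.sum()
    if total <= 0:
        warnings.warn("no compound exposure; composition undefined", stacklevel=2)
        return category_days * np.nan
    return category_days / total


def population_with_any_compound(
    cf: CompoundField,
    pop: PopulationGrid,
    regions: RegionSet,
    year: int | None = None,
    min_days: int = 1,
    mode: str = "cell",
) -> float:
    """Percentage of population experiencing at least ``min_days`` compound
    event days in the year.

    ``mode="cell"`` counts population in grid cells with >= min_days
    compound days; ``mode="region"`` counts population of regions whose
    population-weighted compound exposure time reaches min_days.
    """
    cf = _select_year(cf, year)
    total = pop.total
    if total <= 0:
        return np.nan
    if mode == "cell":
        n_days = cf.is_compound.sum(axis=0)
        return 100.0 * float(pop.counts[n_days >= min_days].sum()) / total
    if mode == "region":
        expo = compound_exposure_time(cf, pop, regions)
        hit = expo[expo >= min_days].index
        persons = sum(
            float((regions.cell_weights(r) * pop.counts).sum()) for r in hit
        )
        return 100.0 * persons / total
    raise ValueError(f"unknown mode {mode!r}")


def compound_share_of_unclean(
    exceedances: dict[str, ExceedanceField],
    cf: CompoundField,
    pop: PopulationGrid,
    regions: RegionSet | None = None,
) -> pd.Series:
    """Per pollutant, the fraction of its exceedance person-days that are
    also compound event days (in [0, 1]).

    Computed over the whole domain and period; a pollutant with zero
    exceedance person-days is undefined (NaN, warned).
    """
    out = {}
    w = pop.counts
    for pol in cf.pollutants:
        exc = exceedances[pol].exceeded
        total_pd = float((exc.sum(axis=0) * w).sum())
        if total_pd <= 0:
            warnings.warn(f"{pol}: no exceedance person-days; share undefined",
                          stacklevel=2)
            out[pol] = np.nan
            continue
        both = exc & cf.is_compound
        out[pol] = float((both.sum(axis=0) * w).sum()) / total_pd
    return pd.Series(out, name="compound_share")


def seasonal_profile(
    cf: CompoundField,
    pop: PopulationGrid,
    regions: RegionSet,
) -> pd.DataFrame:
    """Mean exposure days per calendar month and category.

    Rows are months 1-12, columns category labels plus ``"any"``.  Person-
    day exposure is computed per (year, month, category) over the whole
    domain and averaged over years, so each column sums to that category's
    mean annual exposure time.
    """
    months = cf.dates.month
    years = cf.dates.year
    n_years = cf.years.size
    wtot = pop.total
    if wtot <= 0:
        raise ValueError("population surface is empty")
    cats = cf.categories_present()
    cols = {category_label(c): cf.category_bits(c) for c in cats}
    data = {label: np.zeros(12) for label in cols}
    data["any"] = np.zeros(12)
    for m in range(1, 13):
        sel = months == m
        if not sel.any():
            continue
        bits_m = cf.bits[sel]
        nex_m = cf.n_exceeding[sel]
        for label, target in cols.items():
            n_days = (bits_m == target).sum(axis=0).astype(float)
            data[label][m - 1] = float((n_days * pop.counts).sum()) / wtot / n_years
        n_any = (nex_m >= 2).sum(axis=0).astype(float)
        data["any"][m - 1] = float((n_any * pop.counts).sum()) / wtot / n_years
    return pd.DataFrame(data, index=pd.RangeIndex(1, 13, name="month"))
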