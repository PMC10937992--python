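"""WHO-guideline compliance machinery.

Implements the exposure indicators used throughout the pipeline:

* MDA8 — the maximum daily 8-hour running mean of ozone;
* daily exceedance flags against short-term guideline limits;
* *unclean air exposure time* — the population-weighted mean number of
  days per year a pollutant exceeds its daily limit in a region
  (person-days over population);
* short-term clean-air classification via the 99% compliance rule (a
  region is clean when daily limits are met on at least 99% of days of
  the year, i.e. exceedance days < 3.65 for a 365-day year — the
  "<4 days" rule);
* long-term classification against annual-mean (or, for ozone,
  peak-season-mean) limits;
* population tallies in clean vs unclean air areas.

Boundary conventions (documented and tested): daily exceedance is strict
(``C > L``); the short-term day threshold is strict (``days < (1-f)*N``);
long-term "not exceeded" is non-strict (``metric <= L`` is clean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .grids import ConcentrationField, PopulationGrid, RegionSet

__all__ = [
    "PollutantGuideline",
    "GuidelineSet",
    "WHO_2021",
    "ExceedanceField",
    "mda8",
    "daily_exceedance",
    "unclean_exposure_time",
    "classify_short_term",
    "peak_season_mean",
    "classify_long_term",
    "population_in_clean_air",
]


@dataclass(frozen=True)
class PollutantGuideline:
    """Short- and long-term guideline limits for one pollutant (µg/m³).

    ``short_term_limit`` applies to the 24-h mean (MDA8 for ozone);
    ``long_term_limit`` to the annual mean (peak-season mean for ozone).
    """

    short_term_limit: float
    long_term_limit: float
    long_term_basis: str = "annual"  # "annual" | "peak_season"

    def __post_init__(self) -> None:
        if self.short_term_limit <= 0 or self.long_term_limit <= 0:
            raise ValueError("guideline limits must be positive")


@dataclass(frozen=True)
class GuidelineSet:
    """Per-pollutant guideline limits plus the short-term compliance fraction."""

    limits: dict[str, PollutantGuideline]
    compliance_fraction: float = 0.99

    def __post_init__(self) -> None:
        if not (0.0 < self.compliance_fraction < 1.0):
            raise ValueError("compliance_fraction must lie in (0, 1)")

    def __getitem__(self, pollutant: str) -> PollutantGuideline:
        try:
            return self.limits[pollutant]
        except KeyError:
            raise KeyError(f"no guideline configured for pollutant {pollutant!r}")


#: WHO 2021 air-quality guideline levels.  For O3 the long-term value is the
#: peak-season AQG of 60 µg/m³; interim target 2 (70 µg/m³) is commonly used
#: as an alternative reference threshold where almost no area meets 60.
WHO_2021 = GuidelineSet(
    limits={
        "PM25": PollutantGuideline(15.0, 5.0),
        "PM10": PollutantGuideline(45.0, 15.0),
        "NO2": PollutantGuideline(25.0, 10.0),
        "O3": PollutantGuideline(100.0, 60.0, long_term_basis="peak_season"),
    }
)

O3_INTERIM_TARGET_2 = 70.0


@dataclass
class ExceedanceField:
    """Daily boolean exceedance indicator on a grid.

    ``exceeded`` is boolean ``time x lat x lon``; ``valid`` marks cell-days
    where the underlying concentration was present.
    """

    pollutant: str
    grid: object
    dates: pd.DatetimeIndex
    exceeded: np.ndarray
    valid: np.ndarray

    def sel_year(self, year: int) -> "ExceedanceField":
        m = self.dates.year == year
        if not m.any():
            raise ValueError(f"year {year} outside field span")
        return ExceedanceField(
            self.pollutant, self.grid, self.dates[m], self.exceeded[m], self.valid[m]
        )

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.dates.year)


# ---------------------------------------------------------------------------
# MDA8

MDA8_MIN_HOURS_PER_WINDOW = 6
MDA8_MIN_WINDOWS_PER_DAY = 18


def mda8(hourly: pd.Series | np.ndarray) -> pd.Series | float:
    """Maximum daily 8-hour running mean.

    For each day the running 8-hour means starting 00:00-23:00 are formed;
    windows may extend into the next day but only windows fully contained
    in the series' clock span are considered (a window truncated by the
    end of the record is not a valid window).  A window is valid with at
    least 6 of its 8 clock hours present and is the mean of the present
    hours; a day is valid when at least 75% of its in-span windows are
    valid (18 of 24 for a day followed by another day), else missing.

    Accepts a plain 24-vector (returns a float) or an hourly
    ``pandas.Series`` with a DatetimeIndex spanning one or more days
    (returns a daily Series).
    """
    if not isinstance(hourly, pd.Series):
        arr = np.asarray(hourly, dtype=float)
        if arr.shape != (24,):
            raise ValueError("expected a 24-hour vector or an hourly Series")
        idx = pd.date_range("2000-01-01", periods=24, freq="h")
        out = mda8(pd.Series(arr, index=idx))
        return float(out.iloc[0])

    idx = pd.DatetimeIndex(hourly.index)
    full = pd.date_range(idx.min().floor("D"), idx.max().ceil("D") - pd.Timedelta(hours=1),
                         freq="h")
    series = hourly.reindex(full)
    vals = series.to_numpy(dtype=float)
    n = len(vals)
    n_win = n - 7  # windows fully inside the clock span
    win = np.lib.stride_tricks.sliding_window_view(vals, 8)
    n_present = np.isfinite(win).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        win_mean = np.nanmean(win, axis=1)
    win_mean = np.where(n_present >= MDA8_MIN_HOURS_PER_WINDOW, win_mean, np.nan)

    days = full.floor("D")
    win_days = days[:n_win]
    day_index = pd.DatetimeIndex(sorted(set(days)))
    min_frac = MDA8_MIN_WINDOWS_PER_DAY / 24.0
    out = []
    for d in day_index:
        sel = win_mean[win_days == d]
        n_valid = int(np.isfinite(sel).sum())
        if len(sel) and n_valid >= min_frac * len(sel):
            out.append(np.nanmax(sel))
        else:
            out.append(np.nan)
    return pd.Series(out, index=day_index, name="mda8")


# ---------------------------------------------------------------------------
# daily exceedance and exposure time


def daily_exceedance(field: ConcentrationField, limit: float) -> ExceedanceField:
    """Flag cell-days strictly above ``limit``; missing stays missing."""
    if limit <= 0:
        raise ValueError("limit must be positive")
    valid = np.isfinite(field.values)
    with np.errstate(invalid="ignore"):
        exceeded = (field.values > limit) & valid
    return ExceedanceField(
        pollutant=field.pollutant,
        grid=field.grid,
        dates=field.dates,
        exceeded=exceeded,
        valid=valid,
    )


def _person_day_exposure(
    n_exceed: np.ndarray, pop: PopulationGrid, regions: RegionSet
) -> pd.Series:
    """PW mean exceedance-day count per region from a per-cell day count."""
    out = {}
    for rid in regions.region_ids:
        w = regions.cell_weights(rid) * pop.counts
        wtot = w.sum()
        if wtot <= 0:
            warnings.warn(f"region {rid!r} has zero population; exposure undefined",
                          stacklevel=3)
            out[rid] = np.nan
            continue
        out[rid] = float((w * n_exceed).sum() / wtot)
    return pd.Series(out, name="exposure_days")


def unclean_exposure_time(
    exceed: ExceedanceField,
    pop: PopulationGrid,
    regions: RegionSet,
    year: int | None = None,
) -> pd.Series:
    """Annual unclean-air exposure time per region (days).

    ``E(r) = sum_{g in r} P(g) N_exceed(g) / sum_{g in r} P(g)`` where
    ``N_exceed(g)`` counts the year's exceedance days in cell ``g``
    (person-days divided by the regional population).  Bounded by the
    days in the year.
    """
    if year is not None:
        exceed = exceed.sel_year(year)
    elif exceed.years.size > 1:
        raise ValueError("multiple years present; pass year= explicitly")
    n_exceed = exceed.exceeded.sum(axis=0).astype(float)
    return _person_day_exposure(n_exceed, pop, regions)


def short_term_threshold(days_in_year: int, compliance_fraction: float = 0.99) -> float:
    """Maximum (strict) exceedance-day count compatible with the short-term
    rule: 3.65 days for a 365-day year, 3.66 for a leap year."""
    # rounded so the strict "<" boundary is not perturbed by binary
    # representation of (1 - compliance_fraction)
    return round((1.0 - compliance_fraction) * days_in_year, 9)


def classify_short_term(
    exposure_days: float | pd.Series,
    days_in_year: int = 365,
    compliance_fraction: float = 0.99,
):
    """Short-term clean/unclean classification of regional exposure time.

    Clean iff ``exposure_days < (1 - compliance_fraction) * days_in_year``
    (strict).  For a 365-day year and the 99% rule the threshold is 3.65
    days, so 3 exceedance days are clean and 4 are unclean.  Accepts a
    scalar or a per-region Series; NaN exposure yields a missing
    classification.
    """
    threshold = short_term_threshold(days_in_year, compliance_fraction)
    if isinstance(exposure_days, pd.Series):
        out = exposure_days < threshold
        return out.where(exposure_days.notna())
    if np.isnan(exposure_days):
        return np.nan
    return bool(exposure_days < threshold)


# ---------------------------------------------------------------------------
# long-term metrics


def peak_season_mean(daily: pd.Series) -> float:
    """Peak-season mean: the largest mean over the 12 windows of six
    consecutive calendar months (wrapping the year boundary).

    ``daily`` is one year of daily values (e.g. MDA8) indexed by date.
    Requires data in at least six distinct months, else NaN.
    """
    daily = daily.dropna()
    if daily.empty:
        return np.nan
    months = pd.DatetimeIndex(daily.index).month
    present = np.unique(months)
    if present.size < 6:
        return np.nan
    best = -np.inf
    for start in range(1, 13):
        window = {(start + k - 1) % 12 + 1 for k in range(6)}
        sel = daily[np.isin(months, list(window))]
        if len(sel):
            best = max(best, sel.mean())
    return float(best)


def classify_long_term(metric: float, long_term_limit: float):
    """Long-term clean/unclean: clean iff the annual (or peak-season) metric
    does not exceed the limit (non-strict ``<=``)."""
    if long_term_limit <= 0:
        raise ValueError("limit must be positive")
    if metric is None or (isinstance(metric, float) and np.isnan(metric)):
        return np.nan
    return bool(metric <= long_term_limit)


# ---------------------------------------------------------------------------
# population tallies


def population_in_clean_air(
    classifications: pd.Series,
    regions: RegionSet,
    pop: PopulationGrid,
) -> tuple[float, float]:
    """Population share and absolute count living in clean-air regions.

    ``classifications`` maps region id -> bool (True = clean).  Returns
    ``(percentage, persons)``; clean + unclean population equals the total
    over classified regions.
    """
    total = 0.0
    clean = 0.0
    for rid in regions.region_ids:
        p = float((regions.cell_weights(rid) * pop.counts).sum())
        total += p
        flag = classifications.get(rid, np.nan)
        if flag is True or (isinstance(flag, (bool, np.bool_)) and flag):
            clean += p
    if total <= 0:
        return np.nan, 0.0
    return 100.0 * clean / total, clean
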