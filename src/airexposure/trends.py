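"""Nonparametric trend estimation on annual indicator series.

Theil-Sen slopes (median of all pairwise slopes) quantify the annual rate
of change of population-weighted concentrations or exposure indicators,
expressed as a percentage of the series mean; the Mann-Kendall test
provides a rank-based significance flag.  No autocorrelation
pre-whitening is applied (documented limitation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendResult",
    "theil_sen",
    "mann_kendall",
    "annual_pct_change",
    "trend_table",
]


@dataclass(frozen=True)
class TrendResult:
    """Trend estimate for one annual series."""

    slope: float  # units per year
    annual_pct_change: float  # % of the series mean per year
    mk_S: int
    p_value: float
    significant: bool
    n: int


def theil_sen(values, times=None) -> float:
    """Theil-Sen slope: median of all pairwise slopes ``(y_j - y_i)/(t_j - t_i)``.

    Pairs with identical times are skipped; all times identical is an
    error.  Robust to outliers.
    """
    y = np.asarray(values, dtype=float)
    t = np.arange(len(y), dtype=float) if times is None else np.asarray(times, dtype=float)
    if len(y) != len(t):
        raise ValueError("values and times must have equal length")
    if len(y) < 2:
        raise ValueError("need at least two points")
    ii, jj = np.triu_indices(len(y), k=1)
    dt = t[jj] - t[ii]
    keep = dt != 0
    if not keep.any():
        raise ValueError("all time points are identical")
    slopes = (y[jj] - y[ii])[keep] / dt[keep]
    return float(np.median(slopes))


def _mk_variance(y: np.ndarray) -> float:
    n = len(y)
    var = n * (n - 1) * (2 * n + 5)
    _, counts = np.unique(y, return_counts=True)
    ties = counts[counts > 1]
    if ties.size:
        var -= np.sum(ties * (ties - 1) * (2 * ties + 5))
    return var / 18.0


def mann_kendall(values, exact: bool = False) -> tuple[int, float, float]:
    """Mann-Kendall trend test.

    Returns ``(S, variance, p_value)`` with ``S = sum_{i<j} sign(y_j - y_i)``,
    the tie-corrected variance, and a two-sided p-value from the
    continuity-corrected normal approximation.  With ``exact=True`` (only
    for n <= 10, no ties) the p-value is computed by exact enumeration of
    the null distribution of S over rank permutations.

    An all-tied series yields ``S = 0, p = 1`` (degenerate convention).
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least three values")
    ii, jj = np.triu_indices(n, k=1)
    S = int(np.sum(np.sign(y[jj] - y[ii])))
    var = _mk_variance(y)
    if var <= 0:
        return S, var, 1.0
    if exact:
        if n > 10:
            raise ValueError("exact enumeration supported for n <= 10 only")
        if np.unique(y).size < n:
            raise ValueError("exact enumeration requires no ties")
        dist = _exact_s_distribution(n)
        p = float(sum(prob for s, prob in dist.items() if abs(s) >= abs(S)))
        return S, var, min(p, 1.0)
    if S > 0:
        z = (S - 1) / np.sqrt(var)
    elif S < 0:
        z = (S + 1) / np.sqrt(var)
    else:
        z = 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return S, var, p


def _exact_s_distribution(n: int) -> dict[int, float]:
    """Null distribution of Kendall's S for n untied values, by the
    standard dynamic-programming convolution over insertion positions."""
    # counts[s] for S offset so index 0 <-> S = -n(n-1)/2
    counts = np.array([1.0])
    for k in range(2, n + 1):
        # inserting the k-th largest value contributes a uniform shift over
        # {-(k-1), -(k-3), ..., (k-1)} in steps of 2
        kernel = np.ones(k)
        counts = np.convolve(counts, kernel)
    counts /= counts.sum()
    smin = -n * (n - 1) // 2
    return {smin + 2 * i: c for i, c in enumerate(counts) if c > 0}


def annual_pct_change(values, times=None) -> float:
    """Annual percentage change: ``100 * theil_sen / mean``.

    Undefined (NaN, warned) for a zero-mean series.
    """
    y = np.asarray(values, dtype=float)
    mean = y.mean()
    if mean == 0:
        warnings.warn("series mean is zero; percentage change undefined",
                      stacklevel=2)
        return np.nan
    return 100.0 * theil_sen(y, times) / mean


def trend_result(values, times=None, alpha: float = 0.05) -> TrendResult:
    """Full trend summary (Theil-Sen slope, % change, Mann-Kendall test)."""
    y = np.asarray(values, dtype=float)
    slope = theil_sen(y, times)
    pct = annual_pct_change(y, times)
    S, _, p = mann_kendall(y)
    return TrendResult(
        slope=slope, annual_pct_change=pct, mk_S=S, p_value=p,
        significant=bool(p < alpha), n=len(y),
    )


def trend_table(
    annual: pd.DataFrame,
    alpha: float = 0.05,
    exclude_years=None,
) -> pd.DataFrame:
    """Trend estimates for every column of an annual indicator table.

    ``annual`` is indexed by year with one column per series (region,
    pollutant, ...).  ``exclude_years`` removes designated outlier years
    from both the slope and the mean.  Series with fewer than three
    usable values are skipped with a warning.

    Returns a DataFrame with columns slope, pct_per_year, S, p,
    significant, n.
    """
    if exclude_years:
        annual = annual.loc[~annual.index.isin(list(exclude_years))]
    rows = {}
    for col in annual.columns:
        s = annual[col].dropna()
        if len(s) < 3:
            warnings.warn(f"series {col!r}: fewer than 3 annual values; skipped",
                          stacklevel=2)
            continue
        r = trend_result(s.to_numpy(), s.index.to_numpy(dtype=float), alpha=alpha)
        rows[col] = {
            "slope": r.slope,
            "pct_per_year": r.annual_pct_change,
            "S": r.mk_S,
            "p": r.p_value,
            "significant": r.significant,
            "n": r.n,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
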