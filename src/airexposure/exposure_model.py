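"""Quantile-learning harness with distance-based loss weights.

Monitoring networks are dense in cities and sparse elsewhere, so a model
trained on station-days with a plain loss over-represents the dense areas.
This module implements the counter-measures as a learner-agnostic harness:

* :func:`distance_weights` — per-station loss weights proportional to the
  normalized mean distance to the k nearest neighbouring stations, so
  isolated sites carry more weight than clustered ones;
* :func:`weighted_pinball_loss` and :func:`pinball_grad_hess` — the
  weighted quantile (pinball) objective plus its per-row gradient /
  curvature contract for gradient-boosting plug-ins;
* spatial (leave-stations-out) and temporal (consecutive-year-block)
  cross-validation plans, built so that out-of-sample predictions never
  leak a test station or test period into training;
* :func:`shadow_feature_screen` — Boruta-style screening against shuffled
  shadow features;
* :func:`validation_metrics` — Pearson r, normalized mean bias (NMB) and
  range-normalized RMSE (NRMSE);
* :func:`run_nested_cv` — the out-of-sample prediction loop over a plan.

Any regressor exposing ``fit(X, y, sample_weight=...)`` / ``predict(X)``
satisfies the learner contract; :class:`QuantileBoostingLearner` wraps
scikit-learn's gradient boosting with the quantile objective as the
default, and a LightGBM estimator can be passed in the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "LossWeights",
    "CVPlan",
    "distance_weights",
    "weighted_pinball_loss",
    "pinball_grad_hess",
    "weighted_quantile",
    "spatial_cv_folds",
    "temporal_cv_folds",
    "temporal_year_blocks",
    "shadow_feature_screen",
    "validation_metrics",
    "run_nested_cv",
    "QuantileBoostingLearner",
]

WEIGHT_CLIP = (0.2, 5.0)


@dataclass(frozen=True)
class LossWeights:
    """Per-station loss weights (positive, mean 1 after normalization)."""

    station_ids: tuple[str, ...]
    weights: np.ndarray
    mean_neighbor_distance: np.ndarray

    def for_rows(self, station_id_per_row) -> np.ndarray:
        """Expand station weights to a per-row weight vector."""
        lut = dict(zip(self.station_ids, self.weights))
        return np.array([lut[s] for s in station_id_per_row], dtype=float)


def distance_weights(
    stations: pd.DataFrame, k_neighbors: int = 10
) -> LossWeights:
    """Loss weights from normalized nearest-neighbour distances.

    ``stations`` needs columns ``station_id, lat, lon`` (one row per
    station; duplicates by id are collapsed).  For each station,
    ``d_i`` is the mean Euclidean degree distance to its ``k_neighbors``
    nearest *distinct-location* neighbours; weights are ``d_i / mean(d)``,
    clipped to [0.2, 5] to bound influence, then renormalized to mean 1.
    Stations sharing coordinates draw their distance from the remaining
    neighbours; an all-coincident network is an error.
    """
    st = stations.drop_duplicates("station_id")[["station_id", "lat", "lon"]]
    ids = tuple(st["station_id"])
    coords = st[["lat", "lon"]].to_numpy(dtype=float)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two stations")
    k = min(k_neighbors, n - 1)
    tree = cKDTree(coords)
    # query generously so coincident stations can be skipped
    kq = min(n, max(k + 1, 32))
    dist, _ = tree.query(coords, k=kq)
    d = np.empty(n)
    for i in range(n):
        row = dist[i][1:] if kq > 1 else np.array([])
        nz = row[row > 0]
        if nz.size < k:
            # fall back to brute force against all other stations
            all_d = np.linalg.norm(coords - coords[i], axis=1)
            nz = np.sort(all_d[all_d > 0])
        if nz.size == 0:
            raise ValueError("all stations share one location; distances undefined")
        d[i] = nz[:k].mean()
    w = d / d.mean()
    w = np.clip(w, *WEIGHT_CLIP)
    w = w / w.mean()
    return LossWeights(station_ids=ids, weights=w, mean_neighbor_distance=d)


# ---------------------------------------------------------------------------
# pinball loss


def _check_tau(tau: float) -> None:
    if not (0.0 < tau < 1.0):
        raise ValueError("quantile level tau must lie in (0, 1)")


def weighted_pinball_loss(y, y_hat, tau: float, weights=None) -> float:
    """Weight-normalized pinball (quantile) loss.

    ``loss = sum_i w_i rho_tau(y_i - y_hat_i) / sum_i w_i`` with
    ``rho_tau(u) = u (tau - 1[u < 0])``.  Scaling all weights by a
    constant leaves the loss unchanged.
    """
    _check_tau(tau)
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    u = y - y_hat
    rho = u * (tau - (u < 0))
    return float(np.sum(w * rho) / np.sum(w))


def pinball_grad_hess(y, y_hat, tau: float, weights=None):
    """Per-row gradient and curvature of the weighted pinball objective
    with respect to the prediction, for boosting plug-ins.

    ``grad_i = -w_i (tau - 1[u_i < 0])`` with ``u_i = y_i - y_hat_i``;
    the pinball loss is piecewise linear so a unit pseudo-curvature
    ``hess_i = w_i`` is returned (the convention boosting libraries use
    for L1-type objectives).
    """
    _check_tau(tau)
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    u = y - y_hat
    grad = -w * (tau - (u < 0))
    hess = w.copy()
    return grad, hess


def weighted_quantile(y, tau: float, weights=None) -> float:
    """Weighted empirical tau-quantile: the smallest value at which the
    normalized cumulative weight reaches tau.  This is a minimizer of the
    weighted pinball loss over constants."""
    _check_tau(tau)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    order = np.argsort(y, kind="stable")
    cw = np.cumsum(w[order]) / np.sum(w)
    idx = np.searchsorted(cw, tau, side="left")
    return float(y[order][min(idx, len(y) - 1)])


# ---------------------------------------------------------------------------
# cross-validation plans


@dataclass(frozen=True)
class CVPlan:
    """Row-level fold assignment.

    ``fold`` holds one integer label per table row; ``kind`` is
    ``"spatial"`` (folds partition stations — all rows of a station share
    one fold) or ``"temporal"`` (folds partition consecutive-year blocks).
    """

    kind: str
    fold: np.ndarray
    n_folds: int

    def __post_init__(self) -> None:
        present = np.unique(self.fold)
        if present.min() < 0 or present.max() >= self.n_folds:
            raise ValueError("fold labels out of range")


def spatial_cv_folds(stations: pd.DataFrame, n_folds: int = 5, seed: int = 0) -> CVPlan:
    """Partition *stations* (not rows) into ``n_folds`` near-equal folds.

    ``stations`` is a row table with a ``station_id`` column; every row of
    a station receives that station's fold, so a spatial test fold never
    shares a station with its training folds.
    """
    ids = pd.unique(stations["station_id"])
    if len(ids) < n_folds:
        raise ValueError("fewer stations than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    fold_of_station = np.empty(len(ids), dtype=int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        fold_of_station[chunk] = f
    lut = dict(zip(ids, fold_of_station))
    fold = stations["station_id"].map(lut).to_numpy(dtype=int)
    return CVPlan(kind="spatial", fold=fold, n_folds=n_folds)


def temporal_year_blocks(years) -> list[list[int]]:
    """Split a span of consecutive years into blocks of three consecutive
    years with trailing two-year blocks as needed to cover the span
    exactly (17 years -> five 3-year blocks + one 2-year block)."""
    ys = sorted(set(int(y) for y in years))
    n = len(ys)
    if n < 2:
        raise ValueError("need a span of at least two years")
    n3 = n // 3
    while n3 >= 0 and (n - 3 * n3) % 2 != 0:
        n3 -= 1
    if n3 < 0:  # n is odd and < 3: impossible here since n >= 2
        raise ValueError("cannot tile the span with 3- and 2-year blocks")
    sizes = [3] * n3 + [2] * ((n - 3 * n3) // 2)
    blocks, i = [], 0
    for s in sizes:
        blocks.append(ys[i:i + s])
        i += s
    return blocks


def temporal_cv_folds(dates) -> CVPlan:
    """Fold plan from consecutive-year blocks of the date column."""
    years = pd.DatetimeIndex(dates).year
    blocks = temporal_year_blocks(np.unique(years))
    year_to_fold = {y: f for f, block in enumerate(blocks) for y in block}
    fold = np.array([year_to_fold[y] for y in years], dtype=int)
    return CVPlan(kind="temporal", fold=fold, n_folds=len(blocks))


# ---------------------------------------------------------------------------
# Boruta-style shadow screening


def shadow_feature_screen(
    X: pd.DataFrame,
    y,
    learner_factory=None,
    n_iterations: int = 30,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Shadow-feature (Boruta) screening.

    Each iteration appends a shuffled shadow copy of every feature, fits
    an importance-scoring learner on the augmented table and scores a
    *hit* for each real feature whose importance exceeds the maximum
    shadow importance.  After ``n_iterations`` a one-sided binomial test
    at ``alpha`` against p = 0.5 confirms (more hits than chance) or
    rejects (fewer) each feature; the remainder stay tentative.

    ``learner_factory`` must return an estimator with ``fit(X, y)`` and a
    ``feature_importances_`` attribute; defaults to a small random
    forest.
    """
    if n_iterations < 10:
        raise ValueError("n_iterations must be at least 10")
    if learner_factory is None:
        from sklearn.ensemble import RandomForestRegressor

        def learner_factory(rs):
            return RandomForestRegressor(n_estimators=60, max_depth=6,
                                         random_state=rs, n_jobs=1)

    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    features = list(X.columns)
    hits = {f: 0 for f in features}
    for it in range(n_iterations):
        shadow = X.apply(lambda c: rng.permutation(c.to_numpy()), axis=0)
        shadow.columns = [f"shadow__{c}" for c in X.columns]
        aug = pd.concat([X, shadow], axis=1)
        est = learner_factory(int(rng.integers(2**31)))
        est.fit(aug.to_numpy(), y)
        imp = getattr(est, "feature_importances_", None)
        if imp is None:
            raise ValueError("learner does not expose feature_importances_")
        imp = np.asarray(imp, dtype=float)
        real_imp = imp[: len(features)]
        max_shadow = imp[len(features):].max()
        for f, v in zip(features, real_imp):
            if v > max_shadow:
                hits[f] += 1
    confirmed, rejected, tentative = [], [], []
    for f in features:
        p_hi = stats.binomtest(hits[f], n_iterations, 0.5, alternative="greater").pvalue
        p_lo = stats.binomtest(hits[f], n_iterations, 0.5, alternative="less").pvalue
        if p_hi < alpha:
            confirmed.append(f)
        elif p_lo < alpha:
            rejected.append(f)
        else:
            tentative.append(f)
    return {"confirmed": confirmed, "rejected": rejected, "tentative": tentative,
            "hits": hits}


# ---------------------------------------------------------------------------
# validation metrics


def validation_metrics(obs, pred) -> dict[str, float]:
    """Pearson r, NMB (%) and NRMSE (%) of paired predictions.

    ``NMB = sum(pred - obs) / sum(obs) * 100``;
    ``NRMSE = RMSE / (max(obs) - min(obs)) * 100`` (range-normalized).
    Undefined denominators yield NaN with a warning.  Row order is
    irrelevant; non-finite pairs are dropped.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    keep = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[keep], pred[keep]
    if obs.size < 2:
        raise ValueError("need at least two paired finite values")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        r = np.nan  # correlation undefined for a constant vector
    else:
        r = float(stats.pearsonr(obs, pred).statistic)
    s_obs = obs.sum()
    if s_obs == 0:
        warnings.warn("sum of observations is zero; NMB undefined", stacklevel=2)
        nmb = np.nan
    else:
        nmb = float((pred - obs).sum() / s_obs * 100.0)
    rng_obs = obs.max() - obs.min()
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if rng_obs == 0:
        warnings.warn("observation range is zero; NRMSE undefined", stacklevel=2)
        nrmse = np.nan
    else:
        nrmse = float(rmse / rng_obs * 100.0)
    return {"pearson_r": r, "nmb_pct": nmb, "nrmse_pct": nrmse, "n": int(obs.size)}


# ---------------------------------------------------------------------------
# learner contract + nested CV


class QuantileBoostingLearner:
    """Default learner: gradient boosting with the quantile objective.

    Thin wrapper of scikit-learn's ``GradientBoostingRegressor`` with
    ``loss="quantile"`` at level ``tau`` (0.5 gives the central
    estimate), honouring per-row sample weights.
    """

    def __init__(self, tau: float = 0.5, n_estimators: int = 100,
                 max_depth: int = 3, learning_rate: float = 0.1,
                 random_state: int = 0):
        _check_tau(tau)
        self.tau = tau
        self.params = dict(n_estimators=n_estimators, max_depth=max_depth,
                           learning_rate=learning_rate, random_state=random_state)
        self._est = None

    def fit(self, X, y, sample_weight=None):
        from sklearn.ensemble import GradientBoostingRegressor

        self._est = GradientBoostingRegressor(
            loss="quantile", alpha=self.tau, **self.params
        )
        self._est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float),
                      sample_weight=sample_weight)
        return self

    def predict(self, X):
        if self._est is None:
            raise RuntimeError("learner is not fitted")
        return self._est.predict(np.asarray(X, dtype=float))


def run_nested_cv(
    table: pd.DataFrame,
    plan: CVPlan,
    learner_factory,
    feature_cols: list[str],
    target_col: str = "value",
    loss_weights: LossWeights | None = None,
) -> dict:
    """Out-of-sample prediction loop over a CV plan.

    For every fold a fresh learner from ``learner_factory()`` is fitted
    on the remaining folds (with per-row loss weights when given) and
    predicts the held-out rows, so each row receives exactly one
    out-of-sample prediction.  A learner failure flags the fold and the
    run continues.

    Returns a dict with ``predictions`` (the table plus ``fold`` and
    ``y_hat`` columns), ``fold_metrics``, ``pooled`` metrics and
    ``failed_folds``.
    """
    if len(plan.fold) != len(table):
        raise ValueError("plan does not match the table")
    out = table.copy().reset_index(drop=True)
    out["fold"] = plan.fold
    out["y_hat"] = np.nan
    row_w = None
    if loss_weights is not None:
        row_w = loss_weights.for_rows(out["station_id"])
    X = out[feature_cols].to_numpy(dtype=float)
    y = out[target_col].to_numpy(dtype=float)
    fold_metrics = {}
    failed = []
    for f in range(plan.n_folds):
        test = out["fold"].to_numpy() == f
        train = ~test
        if not test.any() or not train.any():
            failed.append(f)
            continue
        learner = learner_factory()
        try:
            if row_w is not None:
                learner.fit(X[train], y[train], sample_weight=row_w[train])
            else:
                learner.fit(X[train], y[train])
            pred = np.asarray(learner.predict(X[test]), dtype=float)
        except Exception as exc:  # noqa: BLE001 - fold failures must not kill the run
            warnings.warn(f"fold {f} failed: {exc}", stacklevel=2)
            failed.append(f)
            continue
        out.loc[test, "y_hat"] = pred
        fold_metrics[f] = validation_metrics(y[test], pred)
    ok = out["y_hat"].notna()
    pooled = validation_metrics(y[ok], out.loc[ok, "y_hat"]) if ok.sum() >= 2 else None
    return {
        "predictions": out,
        "fold_metrics": fold_metrics,
        "pooled": pooled,
        "failed_folds": failed,
    }
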