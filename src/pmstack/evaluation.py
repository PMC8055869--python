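"""Cross-validation plans and accuracy metrics.

Two fold geometries are supported, matching the two questions one can ask of
an exposure model.  *Random* folds scatter observations regardless of
location and estimate interpolation accuracy at monitored places; *spatial*
folds keep every record of a monitoring site inside one fold and estimate
accuracy at new, unmonitored locations — the setting the prediction surface
actually faces.  Under spatial correlation the random-fold estimate is
optimistic, which is the central reason both are computed.

Before either kind of 10-fold CV a 10% test set is held out — 10% of
locations in spatial mode, 10% of observations in random mode — and never
touches model development.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import clone

from .features import season_of

LEVEL_BOUNDS = (35.0, 60.0, 150.0, 300.0, 500.0, 1000.0)


@dataclass
class FoldPlan:
    """Assignment of table rows to K folds plus a held-out test mask.

    ``fold_of_row`` is -1 for test rows; folds partition the non-test rows.
    In spatial mode all rows of one location share a fold and test locations
    contribute no training rows.
    """

    mode: str
    k: int
    fold_of_row: np.ndarray
    test_mask: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.fold_of_row = np.asarray(self.fold_of_row, dtype=int)
        self.test_mask = np.asarray(self.test_mask, dtype=bool)
        if self.fold_of_row.shape != self.test_mask.shape:
            raise ValueError("fold_of_row and test_mask must align")
        if np.any(self.fold_of_row[self.test_mask] != -1):
            raise ValueError("test rows must carry no fold")

    @property
    def n_rows(self) -> int:
        return self.fold_of_row.size

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_row == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(~self.test_mask & (self.fold_of_row != fold))

    def to_frame(self, keys: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        out = pd.DataFrame(
            {"fold": self.fold_of_row, "is_test": self.test_mask.astype(int)}
        )
        if keys is not None:
            out = pd.concat([keys.reset_index(drop=True), out], axis=1)
        return out


def make_random_folds(table, k: int = 10, holdout_fraction: float = 0.10,
                      seed: int = 0) -> FoldPlan:
    """Random K folds after holding out a random share of observations."""
    n = len(table)
    if n == 0:
        raise ValueError("table is empty")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 101])
    n_test = int(round(holdout_fraction * n))
    if k > n - n_test:
        raise ValueError("more folds than available training rows")
    perm = rng.permutation(n)
    fold = np.full(n, -1, dtype=int)
    train_rows = perm[n_test:]
    fold[train_rows] = np.arange(train_rows.size) % k
    test = np.zeros(n, dtype=bool)
    test[perm[:n_test]] = True
    return FoldPlan("random", k, fold, test, seed)


def make_spatial_folds(table, k: int = 10, holdout_fraction: float = 0.10,
                       seed: int = 0, location_col: str = "location_id") -> FoldPlan:
    """Location-grouped K folds after holding out a random share of locations.

    All rows of one location share a fold; folds are balanced by location
    count, not observation count.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    loc = pd.Series(table[location_col]).to_numpy()
    unique = pd.unique(loc)
    n_loc = unique.size
    if n_loc < k + 1:
        raise ValueError(f"need more than k={k} unique locations, have {n_loc}")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 202])
    perm = rng.permutation(n_loc)
    n_test = int(round(holdout_fraction * n_loc))
    test_locs = set(unique[perm[:n_test]])
    train_locs = unique[perm[n_test:]]
    fold_of_loc = {l: i % k for i, l in enumerate(train_locs)}
    fold = np.array([fold_of_loc.get(l, -1) for l in loc], dtype=int)
    test = np.array([l in test_locs for l in loc], dtype=bool)
    return FoldPlan("spatial", k, fold, test, seed)


@dataclass
class MetricsReport:
    rmse: float
    r2: float
    nrmse: Optional[float]
    n: int
    stratum: str = "all"
    stratum_type: str = "all"
    degenerate: bool = False


def compute_metrics(predicted, observed, r2_method: str = "pearson",
                    stratum: str = "all", stratum_type: str = "all") -> MetricsReport:
    """RMSE, R² and normalized RMSE of predictions against observations.

    ``r2_method='pearson'`` (default) reports the squared Pearson correlation;
    ``'ss'`` reports 1 − SS_res/SS_tot.  Zero variance in either vector makes
    the correlation undefined: R² is then reported as 0 with a warning and the
    ``degenerate`` flag set.  NRMSE is RMSE over the mean of the observations,
    absent when that mean is zero.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size == 0:
        raise ValueError("predicted and observed must be equal-length and nonempty")
    rmse = float(np.sqrt(np.mean((predicted - observed) ** 2)))
    degenerate = False
    if predicted.size < 2 or np.std(predicted) == 0.0 or np.std(observed) == 0.0:
        if r2_method == "pearson":
            warnings.warn("zero variance: R² reported as 0", RuntimeWarning, stacklevel=2)
            r2, degenerate = 0.0, True
        else:
            sst = float(np.sum((observed - observed.mean()) ** 2))
            if sst == 0.0:
                warnings.warn("zero variance: R² reported as 0", RuntimeWarning, stacklevel=2)
                r2, degenerate = 0.0, True
            else:
                r2 = 1.0 - float(np.sum((observed - predicted) ** 2)) / sst
    elif r2_method == "pearson":
        r2 = float(np.corrcoef(predicted, observed)[0, 1] ** 2)
    elif r2_method == "ss":
        sst = float(np.sum((observed - observed.mean()) ** 2))
        r2 = 1.0 - float(np.sum((observed - predicted) ** 2)) / sst
    else:
        raise ValueError(f"unknown r2_method {r2_method!r}")
    mean_obs = float(observed.mean())
    nrmse = rmse / mean_obs if mean_obs != 0.0 else None
    return MetricsReport(rmse, r2, nrmse, predicted.size, stratum, stratum_type, degenerate)


def cross_validate(features, labels, plan: FoldPlan, model_spec, seed: int = 0,
                   r2_method: str = "pearson"):
    """Out-of-fold predictions and metrics for a generic estimator.

    ``model_spec`` is a scikit-learn style regressor; it is cloned and fitted
    per fold on the other folds' rows (test rows excluded throughout) and
    predicts the left-out fold.  Returns ``(oof, per_fold, pooled)`` where
    ``oof`` is NaN on test rows.
    """
    labels = np.asarray(labels, dtype=float)
    X = features.to_numpy() if hasattr(features, "to_numpy") else np.asarray(features)
    if len(X) != plan.n_rows:
        raise ValueError("plan does not cover the table")
    oof = np.full(plan.n_rows, np.nan)
    per_fold = []
    for f in range(plan.k):
        test_idx = plan.fold_indices(f)
        train_idx = plan.train_indices(f)
        if test_idx.size == 0 or train_idx.size == 0:
            raise ValueError(f"fold {f} has no rows")
        est = clone(model_spec)
        try:
            est.fit(X[train_idx], labels[train_idx])
            pred = est.predict(X[test_idx])
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"model failed on fold {f}: {exc}") from exc
        oof[test_idx] = pred
        per_fold.append(
            compute_metrics(pred, labels[test_idx], r2_method,
                            stratum=f"fold_{f}", stratum_type="fold")
        )
    mask = ~plan.test_mask
    pooled = compute_metrics(oof[mask], labels[mask], r2_method)
    return oof, per_fold, pooled


def evaluate_holdout(model, features, labels, plan: FoldPlan,
                     r2_method: str = "pearson") -> MetricsReport:
    """Metrics of a trained model on the held-out test rows only."""
    if not plan.test_mask.any():
        raise ValueError("plan has an empty test set")
    idx = np.flatnonzero(plan.test_mask)
    sub = features.iloc[idx] if hasattr(features, "iloc") else features[idx]
    pred = model.predict(sub)
    pred = pred["pred_ensemble"].to_numpy() if hasattr(pred, "columns") else np.asarray(pred)
    return compute_metrics(pred, np.asarray(labels, dtype=float)[idx], r2_method,
                           stratum="holdout", stratum_type="holdout")


def stratified_metrics(table: pd.DataFrame, predicted_col: str = "predicted",
                       observed_col: str = "observed",
                       r2_method: str = "pearson") -> list[MetricsReport]:
    """Metrics stratified by concentration level, year, state and season.

    Level strata are cumulative ("below c" for c in 35, 60, 150, 300, 500,
    1000 µg/m³ of the observed value); empty strata are omitted.  The table
    needs ``date`` and ``state`` columns alongside the prediction pair.
    """
    obs = table[observed_col].to_numpy(dtype=float)
    pred = table[predicted_col].to_numpy(dtype=float)
    dates = pd.to_datetime(table["date"])
    out: list[MetricsReport] = []
    for bound in LEVEL_BOUNDS:
        mask = obs < bound
        if mask.sum() == 0:
            continue
        out.append(compute_metrics(pred[mask], obs[mask], r2_method,
                                   stratum=f"below_{int(bound)}", stratum_type="level"))
    for year, idx in table.groupby(dates.dt.year).groups.items():
        loc = table.index.get_indexer(idx)
        out.append(compute_metrics(pred[loc], obs[loc], r2_method,
                                   stratum=str(year), stratum_type="year"))
    for state, idx in table.groupby(table["state"]).groups.items():
        loc = table.index.get_indexer(idx)
        out.append(compute_metrics(pred[loc], obs[loc], r2_method,
                                   stratum=str(state), stratum_type="state"))
    seasons = pd.Series(season_of(dates), index=table.index)
    for season, idx in table.groupby(seasons).groups.items():
        loc = table.index.get_indexer(idx)
        out.append(compute_metrics(pred[loc], obs[loc], r2_method,
                                   stratum=str(season), stratum_type="season"))
    return out


def metrics_to_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stratum_type": [r.stratum_type for r in reports],
            "stratum": [r.stratum for r in reports],
            "n": [r.n for r in reports],
            "rmse": [r.rmse for r in reports],
            "r2": [r.r2 for r in reports],
            "nrmse": [r.nrmse for r in reports],
        }
    )
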