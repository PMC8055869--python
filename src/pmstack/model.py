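"""Two-learner stacked ensemble with a linear combiner.

A bagged-tree regressor (random-forest family) and a boosted-tree regressor
(gradient-boosting family) are trained under a fold plan; their out-of-fold
predictions form the design matrix of an ordinary-least-squares combiner with
intercept (a Gaussian identity-link GLM).  Fitting the combiner on
out-of-fold rather than in-sample predictions keeps it from loading onto
whichever base learner overfits harder.  After stacking, both base learners
are refit on all training rows.

Both learners are LightGBM models run single-threaded and deterministic, so a
fixed seed reproduces tuning records, combiner coefficients and predictions
exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import joblib
import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor

from .evaluation import FoldPlan, compute_metrics

_MODEL_FORMAT_VERSION = 1

_COMMON = dict(n_jobs=1, deterministic=True, force_col_wise=True, verbose=-1)

#: Default capacity of the bagged-tree learner.
BAGGED_DEFAULTS = dict(
    boosting_type="rf",
    n_estimators=25,
    num_leaves=64,
    subsample=0.30,
    subsample_freq=1,
    colsample_bytree=0.5,
    max_bin=127,
)

#: Default capacity of the boosted-tree learner.
BOOSTED_DEFAULTS = dict(
    boosting_type="gbdt",
    n_estimators=70,
    num_leaves=31,
    learning_rate=0.25,
    subsample=0.5,
    subsample_freq=1,
    colsample_bytree=0.6,
    max_bin=127,
)


def _make_learner(defaults: dict, params: Optional[dict], seed: int) -> LGBMRegressor:
    merged = dict(defaults)
    if params:
        valid = set(LGBMRegressor().get_params())
        unknown = set(params) - valid
        if unknown:
            raise ValueError(f"unknown learner parameter(s): {sorted(unknown)}")
        merged.update(params)
    return LGBMRegressor(random_state=int(seed) & 0x7FFFFFFF, **_COMMON, **merged)


def make_bagged(params: Optional[dict] = None, seed: int = 0) -> LGBMRegressor:
    """A random-forest-family learner (bagged trees, no shrinkage)."""
    return _make_learner(BAGGED_DEFAULTS, params, seed)


def make_boosted(params: Optional[dict] = None, seed: int = 0) -> LGBMRegressor:
    """A gradient-boosting-family learner."""
    return _make_learner(BOOSTED_DEFAULTS, params, seed)


@dataclass
class StackedModel:
    """Fitted base learners plus the 3-parameter linear combiner."""

    learner_bagged: LGBMRegressor
    learner_boosted: LGBMRegressor
    intercept: float
    w_bagged: float
    w_boosted: float
    feature_names: list[str]
    include_ctm: bool
    seed: int
    params: dict = field(default_factory=dict)
    oof: Optional[pd.DataFrame] = None
    plan: Optional[FoldPlan] = None
    tuning_record: Optional[pd.DataFrame] = None

    @property
    def stacker_coefficients(self) -> np.ndarray:
        return np.array([self.intercept, self.w_bagged, self.w_boosted])

    def _design(self, features: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise KeyError(f"feature column(s) missing: {missing}")
        X = features[self.feature_names]
        if X.isna().to_numpy().any():
            raise ValueError(
                "features contain missing values; run imputation before predicting"
            )
        return X

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        """Per-row base and ensemble predictions (raw, untruncated)."""
        X = self._design(features)
        pred_a = self.learner_bagged.predict(X)
        pred_b = self.learner_boosted.predict(X)
        ens = self.intercept + self.w_bagged * pred_a + self.w_boosted * pred_b
        return pd.DataFrame(
            {"pred_bagged": pred_a, "pred_boosted": pred_b, "pred_ensemble": ens},
            index=features.index,
        )

    def save(self, path) -> None:
        joblib.dump(
            {
                "format_version": _MODEL_FORMAT_VERSION,
                "learner_bagged": self.learner_bagged,
                "learner_boosted": self.learner_boosted,
                "coefficients": self.stacker_coefficients,
                "feature_names": self.feature_names,
                "include_ctm": self.include_ctm,
                "seed": self.seed,
                "params": self.params,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "StackedModel":
        blob = joblib.load(path)
        if blob.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError("unrecognized model archive version")
        b0, wa, wb = blob["coefficients"]
        return cls(
            blob["learner_bagged"], blob["learner_boosted"], float(b0), float(wa),
            float(wb), list(blob["feature_names"]), bool(blob["include_ctm"]),
            int(blob["seed"]), dict(blob["params"]),
        )


def _oof_predictions(X: pd.DataFrame, y: np.ndarray, plan: FoldPlan,
                     params: dict, seed: int):
    """Out-of-fold base-learner predictions under a fold plan (NaN on test rows)."""
    oof_a = np.full(len(X), np.nan)
    oof_b = np.full(len(X), np.nan)
    for f in range(plan.k):
        tr = plan.train_indices(f)
        te = plan.fold_indices(f)
        if tr.size == 0 or te.size == 0:
            raise ValueError(f"fold {f} has no rows")
        a = make_bagged(params.get("bagged"), seed)
        b = make_boosted(params.get("boosted"), seed)
        a.fit(X.iloc[tr], y[tr])
        b.fit(X.iloc[tr], y[tr])
        oof_a[te] = a.predict(X.iloc[te])
        oof_b[te] = b.predict(X.iloc[te])
    return oof_a, oof_b


def fit_ensemble(features: pd.DataFrame, labels, plan: FoldPlan,
                 params: Optional[dict] = None, seed: int = 0,
                 feature_names: Optional[list[str]] = None,
                 refit: bool = True) -> StackedModel:
    """Fit the stacked ensemble under a fold plan.

    Base learners produce out-of-fold predictions; the combiner is OLS of the
    labels on those predictions (intercept included), fitted only on
    out-of-fold rows; the base learners are then refit on all training
    (non-test) rows.  Test-masked rows never enter any fit.
    """
    from .features import predictor_columns

    params = params or {}
    y = np.asarray(labels, dtype=float)
    if feature_names is None:
        feature_names = predictor_columns(features)
    X = features[feature_names]
    if X.isna().to_numpy().any():
        raise ValueError("features contain missing values; impute before fitting")
    if len(X) != plan.n_rows:
        raise ValueError("plan does not cover the feature table")

    oof_a, oof_b = _oof_predictions(X, y, plan, params, seed)
    mask = ~plan.test_mask
    design = np.column_stack([np.ones(mask.sum()), oof_a[mask], oof_b[mask]])
    coef, *_ = np.linalg.lstsq(design, y[mask], rcond=None)
    b0, wa, wb = (float(c) for c in coef)
    oof_ens = b0 + wa * oof_a + wb * oof_b

    if refit:
        tr = np.flatnonzero(mask)
        learner_a = make_bagged(params.get("bagged"), seed)
        learner_b = make_boosted(params.get("boosted"), seed)
        learner_a.fit(X.iloc[tr], y[tr])
        learner_b.fit(X.iloc[tr], y[tr])
    else:
        learner_a = learner_b = None

    oof = pd.DataFrame(
        {"oof_bagged": oof_a, "oof_boosted": oof_b, "oof_ensemble": oof_ens}
    )
    return StackedModel(
        learner_a, learner_b, b0, wa, wb, list(feature_names),
        include_ctm="ctm_pm25" in feature_names, seed=seed, params=params,
        oof=oof, plan=plan,
    )


def oof_metrics(model: StackedModel, labels, r2_method: str = "pearson"):
    """Pooled CV metrics from a fitted model's out-of-fold ensemble predictions."""
    mask = ~model.plan.test_mask
    return compute_metrics(
        model.oof["oof_ensemble"].to_numpy()[mask],
        np.asarray(labels, dtype=float)[mask],
        r2_method,
    )


def tune_hyperparameters(features: pd.DataFrame, labels, grids: dict,
                         plan: FoldPlan, seed: int = 0):
    """Grid-search each base learner by CV RMSE under the fold plan.

    ``grids`` maps learner name ('bagged' / 'boosted') to a list of parameter
    dicts.  Every grid point is evaluated; the argmin wins, ties broken by
    first-listed point.  Returns ``(best_params, record)`` with the full
    evaluation record retained.
    """
    from .features import predictor_columns

    makers = {"bagged": make_bagged, "boosted": make_boosted}
    unknown = set(grids) - set(makers)
    if unknown:
        raise ValueError(f"unknown learner name(s) in grids: {sorted(unknown)}")
    cols = predictor_columns(features)
    X = features[cols]
    y = np.asarray(labels, dtype=float)
    best: dict[str, dict] = {}
    records = []
    for learner, grid in grids.items():
        if not grid:
            raise ValueError(f"empty grid for learner {learner!r}")
        best_rmse, best_point = np.inf, None
        for gi, point in enumerate(grid):
            oof = np.full(len(X), np.nan)
            for f in range(plan.k):
                tr = plan.train_indices(f)
                te = plan.fold_indices(f)
                est = makers[learner](point, seed)
                est.fit(X.iloc[tr], y[tr])
                oof[te] = est.predict(X.iloc[te])
            mask = ~plan.test_mask
            rmse = float(np.sqrt(np.mean((oof[mask] - y[mask]) ** 2)))
            records.append({"learner": learner, "grid_index": gi,
                            "params": dict(point), "cv_rmse": rmse})
            if rmse < best_rmse:  # strict: ties keep the first-listed point
                best_rmse, best_point = rmse, dict(point)
        best[learner] = best_point
    return best, pd.DataFrame(records)


def permutation_importance(model: StackedModel, features: pd.DataFrame, labels,
                           n_repeats: int = 3, seed: int = 0) -> pd.DataFrame:
    """Permutation importance of every feature on the ensemble prediction.

    Importance is the mean (over repeats) increase in RMSE when one feature
    column is shuffled.  The permutation for feature *j*, repeat *r* draws
    from ``default_rng([seed, j, r])``, so results are reproducible
    column-by-column.  Collinear features share credit and can individually
    rank low even when jointly informative.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    y = np.asarray(labels, dtype=float)
    X = model._design(features).reset_index(drop=True)
    base_rmse = float(np.sqrt(np.mean((model.predict(X)["pred_ensemble"].to_numpy() - y) ** 2)))
    n = len(X)
    importances = []
    for j, name in enumerate(model.feature_names):
        deltas = []
        for r in range(n_repeats):
            rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, j, r])
            Xp = X.copy()
            Xp[name] = X[name].to_numpy()[rng.permutation(n)]
            rmse = float(np.sqrt(np.mean((model.predict(Xp)["pred_ensemble"].to_numpy() - y) ** 2)))
            deltas.append(rmse - base_rmse)
        importances.append(float(np.mean(deltas)))
    out = pd.DataFrame({"feature": model.feature_names, "importance": importances})
    order = np.argsort(-out["importance"].to_numpy(), kind="stable")
    rank = np.empty(len(out), dtype=int)
    rank[order] = np.arange(1, len(out) + 1)
    out["rank"] = rank
    return out
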