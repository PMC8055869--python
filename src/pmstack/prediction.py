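"""Areal-unit prediction: imputation, surface prediction, export.

Centroid prediction inputs inevitably have gaps (cloud-masked AOD above all),
and tree learners here require complete design matrices, so missing predictor
cells are filled by chained bagged-tree imputation run separately within each
state — each incomplete column is repeatedly re-predicted from the others
until the imputed values stabilize.  The fitted full model is then applied to
every (centroid, day), negative ensemble values are truncated to zero at
export, and files are written per state with the published column schema.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .features import assemble_features, predictor_columns
from .model import StackedModel, make_bagged

log = logging.getLogger(__name__)

#: Published export schemas; base-learner prediction names follow the
#: deposited files so downstream merges are drop-in compatible.
EXPORT_COLUMNS = {
    "no_ctm": ["County_FIPS", "Tract_code", "ZCTA5_code", "Lon", "Lat", "Date",
               "ranger_preds", "xgbt_preds", "Missing_vars", "Ens_pred"],
    "with_ctm": ["County_FIPS", "Tract_code", "ZCTA5_code", "Lon", "Lat", "Date",
                 "CMAQ_ranger_preds", "CMAQ_xgbt_preds", "Missing_vars", "Ens_pred"],
}

# small leaves: state groups can hold only a few dozen rows
_IMPUTER_PARAMS = dict(n_estimators=25, num_leaves=31, subsample=0.7,
                       subsample_freq=1, colsample_bytree=0.7,
                       min_child_samples=5)


def impute_missing(features: pd.DataFrame, group_col: str = "state",
                   max_iter: int = 10, tol: float = 1e-3,
                   seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Chained bagged-tree imputation of missing predictor cells, per group.

    Within each state: missing cells start at column medians; then each
    incomplete column (in order of increasing missingness) is re-fit with a
    small bagged-tree regressor on the rows where it was observed and its
    missing cells re-predicted, sweeping until the relative change of the
    imputed values drops below ``tol`` or ``max_iter`` sweeps are done.

    Returns the completed table and a per-row flag marking rows where at
    least one cell was imputed.  A column entirely missing within a state
    cannot be imputed and is rejected by name.
    """
    cols = predictor_columns(features)
    out = features.copy()
    na = out[cols].isna()
    missing_vars = na.any(axis=1).to_numpy()
    if not missing_vars.any():
        return out, missing_vars
    incomplete = [c for c in cols if na[c].any()]
    for state, idx in out.groupby(group_col).groups.items():
        sub = out.loc[idx, cols]
        sub_na = na.loc[idx]
        state_incomplete = [c for c in incomplete if sub_na[c].any()]
        if not state_incomplete:
            continue
        for c in state_incomplete:
            if sub_na[c].all():
                raise ValueError(
                    f"column {c!r} is entirely missing within state {state!r}"
                )
        state_incomplete.sort(key=lambda c: (sub_na[c].sum(), c))
        work = sub.copy()
        for c in state_incomplete:
            work.loc[sub_na[c], c] = work[c].median()
        prev = {c: work.loc[sub_na[c], c].to_numpy(copy=True) for c in state_incomplete}
        for sweep in range(max_iter):
            delta_num = delta_den = 0.0
            for ci, c in enumerate(state_incomplete):
                obs_rows = ~sub_na[c].to_numpy()
                mis_rows = sub_na[c].to_numpy()
                other = [o for o in cols if o != c]
                est = make_bagged(_IMPUTER_PARAMS, seed=(int(seed) + 31 * ci) & 0x7FFFFFFF)
                est.fit(work.loc[obs_rows, other], work.loc[obs_rows, c].to_numpy())
                pred = est.predict(work.loc[mis_rows, other])
                work.loc[mis_rows, c] = pred
                delta_num += float(np.sum((pred - prev[c]) ** 2))
                delta_den += float(np.sum(pred**2))
                prev[c] = pred
            if delta_den == 0.0 or delta_num / delta_den < tol:
                break
        out.loc[idx, cols] = work
    return out, missing_vars


def predict_surface(model: StackedModel, centroids: pd.DataFrame, world,
                    dates=None, level: str = "tract",
                    impute_seed: int = 0) -> pd.DataFrame:
    """Ensemble predictions for every (centroid, day) of one areal level.

    ``model`` should be the full refit (trained on all rows including any
    earlier holdout).  Features are assembled at each centroid for each day,
    imputed per state, and predicted; raw (untruncated) ensemble values are
    returned together with the ``missing_vars`` imputation flag.
    """
    units = centroids[centroids["level"] == level].reset_index(drop=True)
    if len(units) == 0:
        raise ValueError(f"no centroids at level {level!r}")
    dates = pd.DatetimeIndex(dates if dates is not None else world.dates)
    world.day_index(dates)  # validates range
    unit_id = _unit_ids(units, level)
    n_u, n_d = len(units), len(dates)
    keys = pd.DataFrame(
        {
            "location_id": np.repeat(unit_id, n_d),
            "lon": np.repeat(units["lon"].to_numpy(), n_d),
            "lat": np.repeat(units["lat"].to_numpy(), n_d),
            "state": np.repeat(units["state"].to_numpy(), n_d),
            "date": np.tile(dates, n_u),
        }
    )
    feats = assemble_features(keys, world, include_ctm=model.include_ctm)
    completed, missing_vars = impute_missing(feats, seed=impute_seed)
    preds = model.predict(completed)
    rec = pd.DataFrame(
        {
            "level": level,
            "county_fips": np.repeat(units["county_fips"].to_numpy(), n_d),
            "tract_code": np.repeat(units["tract_code"].to_numpy(), n_d),
            "zcta5_code": np.repeat(units["zcta5_code"].to_numpy(), n_d),
            "unit_id": keys["location_id"],
            "state": keys["state"],
            "lon": keys["lon"],
            "lat": keys["lat"],
            "date": keys["date"],
            "pred_bagged": preds["pred_bagged"].to_numpy(),
            "pred_boosted": preds["pred_boosted"].to_numpy(),
            "pred_ensemble": preds["pred_ensemble"].to_numpy(),
            "missing_vars": missing_vars.astype(int),
        }
    )
    return rec


def _unit_ids(units: pd.DataFrame, level: str) -> np.ndarray:
    col = {"county": "county_fips", "tract": "tract_code", "zip": "zcta5_code"}.get(level)
    if col is None:
        raise ValueError(f"unknown level {level!r}")
    return units[col].to_numpy(dtype=object)


def truncate_negative(records: pd.DataFrame,
                      column: str = "pred_ensemble") -> pd.DataFrame:
    """Replace negative ensemble predictions with 0 (count logged)."""
    out = records.copy()
    neg = out[column].to_numpy() < 0.0
    out.loc[neg, column] = 0.0
    log.info("truncate_negative: replaced %d negative prediction(s)", int(neg.sum()))
    return out


def write_predictions(records: pd.DataFrame, path, variant: str = "no_ctm",
                      fmt: str = "csv", truncate: bool = True) -> list[Path]:
    """Write one file per state in the published column schema.

    ``variant`` selects the with-CTM or no-CTM column names.  Dates are
    ISO-8601; the files round-trip losslessly through ``pandas.read_csv`` /
    ``read_parquet``.
    """
    if variant not in EXPORT_COLUMNS:
        raise ValueError(f"unknown variant {variant!r}")
    if fmt not in ("csv", "parquet"):
        raise ValueError(f"unknown format {fmt!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = truncate_negative(records) if truncate else records.copy()
    cols = EXPORT_COLUMNS[variant]
    a_col, b_col = cols[6], cols[7]
    table = pd.DataFrame(
        {
            "County_FIPS": out["county_fips"],
            "Tract_code": out["tract_code"],
            "ZCTA5_code": out["zcta5_code"],
            "Lon": out["lon"],
            "Lat": out["lat"],
            "Date": pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d"),
            a_col: out["pred_bagged"],
            b_col: out["pred_boosted"],
            "Missing_vars": out["missing_vars"].astype(int),
            "Ens_pred": out["pred_ensemble"],
            "_state": out["state"],
        }
    )
    tag = "with_CMAQ" if variant == "with_ctm" else "no_CMAQ"
    written = []
    for state, sub in table.groupby("_state", sort=True):
        fname = path / f"Ensemble_preds_{tag}_{state}.{fmt}"
        body = sub.drop(columns="_state")[cols]
        if fmt == "csv":
            body.to_csv(fname, index=False)
        else:
            body.to_parquet(fname, index=False)
        written.append(fname)
    return written


def read_predictions(paths, variant: str = "no_ctm") -> pd.DataFrame:
    """Read exported per-state files back into one table."""
    frames = []
    for p in paths:
        p = Path(p)
        df = pd.read_csv(
            p, dtype={"County_FIPS": str, "Tract_code": str, "ZCTA5_code": str},
            float_precision="round_trip",
        ) if p.suffix == ".csv" else pd.read_parquet(p)
        df["_state"] = p.stem.split("_")[-1]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
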