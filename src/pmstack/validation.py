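"""Validation of the prediction panel against monitor observations.

Each observation is paired with the spatially nearest areal-unit centroid's
same-day ensemble prediction; metrics are reported for all monitors and for
"stable" monitors (at least 31 distinct observation days), since short-lived
deployments — mobile fire monitors above all — sit at extreme conditions and
distort a network-wide comparison.  Per-location time series and seasonal
areal aggregates support the same inspection the study's figures perform.
"""
from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .evaluation import MetricsReport, compute_metrics
from .features import season_of, season_year
from .geo import haversine_km

log = logging.getLogger(__name__)

STABLE_MIN_DAYS = 31


def match_nearest_prediction(observations: pd.DataFrame,
                             predictions: pd.DataFrame) -> pd.DataFrame:
    """Pair each observation with its spatially nearest same-day prediction.

    Nearest is over the unique prediction units (ties to the lowest unit id);
    observations whose date has no prediction record at that unit are dropped
    with a logged count.  Returns one MatchedPair row per retained
    observation: monitor, date, observed, predicted, distance and unit.
    """
    units = (
        predictions[["unit_id", "lon", "lat", "level"]]
        .drop_duplicates("unit_id")
        .sort_values("unit_id", kind="stable")
        .reset_index(drop=True)
    )
    mons = observations[["monitor_id", "lon", "lat"]].drop_duplicates("monitor_id")
    d = haversine_km(
        mons["lon"].to_numpy()[:, None], mons["lat"].to_numpy()[:, None],
        units["lon"].to_numpy()[None, :], units["lat"].to_numpy()[None, :],
    )
    nearest = d.argmin(axis=1)
    match = pd.DataFrame(
        {
            "monitor_id": mons["monitor_id"].to_numpy(),
            "unit_id": units["unit_id"].to_numpy()[nearest],
            "level": units["level"].to_numpy()[nearest],
            "match_distance_km": d[np.arange(len(mons)), nearest],
        }
    )
    obs = observations.copy()
    obs["date"] = pd.to_datetime(obs["date"])
    preds = predictions[["unit_id", "date", "pred_ensemble"]].copy()
    preds["date"] = pd.to_datetime(preds["date"])
    pairs = (
        obs.merge(match, on="monitor_id", how="left")
        .merge(preds, on=["unit_id", "date"], how="inner")
    )
    n_dropped = len(obs) - len(pairs)
    if n_dropped:
        log.info("match_nearest_prediction: dropped %d observation(s) without a "
                 "same-day prediction", n_dropped)
    return pairs.rename(columns={"pm25": "observed", "pred_ensemble": "predicted"})[
        ["monitor_id", "date", "observed", "predicted", "match_distance_km",
         "unit_id", "level", "state"]
    ]


def stable_monitor_filter(pairs: pd.DataFrame,
                          min_days: int = STABLE_MIN_DAYS) -> pd.DataFrame:
    """Drop monitors with fewer than ``min_days`` distinct observation days."""
    days = pairs.groupby("monitor_id")["date"].nunique()
    keep = set(days.index[days >= min_days])
    return pairs[pairs["monitor_id"].isin(keep)].reset_index(drop=True)


def validate_predictions(
    pairs: pd.DataFrame, min_days: int = STABLE_MIN_DAYS,
    r2_method: str = "pearson",
) -> tuple[MetricsReport, Optional[MetricsReport]]:
    """Metrics against all monitors and against the stable-monitor subset."""
    if len(pairs) == 0:
        raise ValueError("no matched pairs to validate")
    all_report = compute_metrics(
        pairs["predicted"].to_numpy(), pairs["observed"].to_numpy(), r2_method,
        stratum="all_monitors", stratum_type="validation",
    )
    stable = stable_monitor_filter(pairs, min_days)
    if len(stable) == 0:
        log.warning("validate_predictions: no stable monitors after filtering")
        return all_report, None
    stable_report = compute_metrics(
        stable["predicted"].to_numpy(), stable["observed"].to_numpy(), r2_method,
        stratum="stable_monitors", stratum_type="validation",
    )
    return all_report, stable_report


def city_time_series(pairs: pd.DataFrame, monitor_id: str,
                     r2_method: str = "pearson"):
    """Date-ordered observed/predicted series and metrics for one monitor.

    The match distance is carried alongside: distant matches degrade the
    per-location metrics and should be read with that in mind.
    """
    sub = pairs[pairs["monitor_id"] == monitor_id]
    if len(sub) == 0:
        raise KeyError(f"monitor {monitor_id!r} not present in matched pairs")
    series = sub.sort_values("date", kind="stable").reset_index(drop=True)[
        ["date", "observed", "predicted", "match_distance_km"]
    ]
    report = compute_metrics(
        series["predicted"].to_numpy(), series["observed"].to_numpy(), r2_method,
        stratum=monitor_id, stratum_type="monitor",
    )
    return series, report


def plot_city_time_series(series: pd.DataFrame, monitor_id: str, path) -> None:
    """Observed (black) vs predicted (red) daily series, saved to PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.plot(series["date"], series["observed"], color="black", lw=0.9, label="observed")
    ax.plot(series["date"], series["predicted"], color="red", lw=0.9, label="predicted")
    ax.set_ylabel("PM$_{2.5}$ (µg/m³)")
    ax.set_title(monitor_id)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def seasonal_aggregate(predictions: pd.DataFrame,
                       season_years: Optional[list[tuple[str, int]]] = None
                       ) -> pd.DataFrame:
    """Mean daily ensemble prediction per unit per (season, season-year).

    Seasons are DJF/MAM/JJA/SON with December assigned to the following
    year's winter, so winters stay contiguous.  If specific (season, year)
    pairs are requested and one is absent from the panel it is rejected by
    name.
    """
    df = predictions.copy()
    dates = pd.to_datetime(df["date"])
    df["season"] = season_of(dates)
    df["season_year"] = season_year(dates)
    if season_years is not None:
        have = set(zip(df["season"], df["season_year"]))
        for want in season_years:
            if (want[0], want[1]) not in have:
                raise ValueError(f"season {want[0]!r} {want[1]} absent from predictions")
        mask = df.apply(lambda r: (r["season"], r["season_year"]) in set(map(tuple, season_years)), axis=1)
        df = df[mask]
    out = (
        df.groupby(["unit_id", "season", "season_year"], sort=True)["pred_ensemble"]
        .agg(mean_pred="mean", n_days="size")
        .reset_index()
    )
    return out
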