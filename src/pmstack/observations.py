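"""Harmonization and QC of multi-source 24-h PM2.5 monitor tables.

The pipeline is: map each source's raw columns onto the canonical schema,
concatenate, drop records repeated across sources (keeping the copy from the
highest-precedence source), and remove implausible values — anything strictly
above 850 µg/m³ and any negative reported concentration.

Canonical schema: ``monitor_id, source, lon, lat, state, date, pm25`` with
dates as datetimes, coordinates in decimal degrees and pm25 in µg/m³.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .synthetic import SOURCE_SCHEMAS

log = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["monitor_id", "source", "lon", "lat", "state", "date", "pm25"]

#: Which copy to keep when a record is repeated across sources.
DEFAULT_SOURCE_PRECEDENCE = ["airnow", "improve", "state_network", "fire_cache"]

#: Default per-source raw-column mappings (canonical name -> raw name).
DEFAULT_COLUMN_MAPS: Mapping[str, Mapping[str, str]] = SOURCE_SCHEMAS

#: Records above this 24-h concentration are treated as instrument artifacts.
EXTREME_THRESHOLD = 850.0

#: Coordinates are rounded to this many decimals to form the duplicate key
#: (~1 m), the only identifier that is stable across sources.
COORD_DECIMALS = 5


def harmonize_sources(
    tables: Mapping[str, pd.DataFrame],
    column_maps: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> pd.DataFrame:
    """Map per-source tables onto the canonical schema and concatenate.

    ``tables`` maps a source label to its raw table; ``column_maps`` maps a
    source label to a ``canonical -> raw column`` mapping (defaults to the
    known source layouts, falling back to identity).  A source whose columns
    cannot be mapped is rejected by name; an unparseable date is rejected
    with its row index.
    """
    column_maps = dict(DEFAULT_COLUMN_MAPS) | dict(column_maps or {})
    frames = []
    for source in sorted(tables):
        raw = tables[source]
        cmap = column_maps.get(source, {c: c for c in CANONICAL_COLUMNS if c != "source"})
        needed = [c for c in CANONICAL_COLUMNS if c != "source"]
        missing = [cmap.get(c, c) for c in needed if cmap.get(c, c) not in raw.columns]
        if missing:
            raise ValueError(
                f"source {source!r}: cannot map columns {missing} onto the canonical schema"
            )
        out = pd.DataFrame({c: raw[cmap.get(c, c)].to_numpy() for c in needed})
        out.insert(1, "source", source)
        parsed = pd.to_datetime(out["date"], errors="coerce", format="mixed")
        if parsed.isna().any():
            bad = int(np.flatnonzero(parsed.isna().to_numpy())[0])
            raise ValueError(f"source {source!r}: unparseable date at row {bad}")
        out["date"] = parsed
        out["lon"] = out["lon"].astype(float)
        out["lat"] = out["lat"].astype(float)
        out["pm25"] = out["pm25"].astype(float)
        frames.append(out)
    if not frames:
        return pd.DataFrame(columns=CANONICAL_COLUMNS)
    return pd.concat(frames, ignore_index=True)[CANONICAL_COLUMNS]


def deduplicate(
    table: pd.DataFrame,
    source_precedence: Optional[list[str]] = None,
) -> tuple[pd.DataFrame, int]:
    """Keep one record per (rounded lon, rounded lat, date) key.

    The retained copy comes from the highest-precedence source; within a
    source, the first occurrence wins.  Returns the table (original row order
    preserved) and the number of rows removed.
    """
    prec = list(source_precedence or DEFAULT_SOURCE_PRECEDENCE)
    present = set(table["source"].unique())
    unknown = present - set(prec)
    if unknown:
        raise ValueError(f"source_precedence is missing source label(s): {sorted(unknown)}")
    rank = {s: i for i, s in enumerate(prec)}
    key = pd.DataFrame(
        {
            "lon": table["lon"].round(COORD_DECIMALS),
            "lat": table["lat"].round(COORD_DECIMALS),
            "date": pd.to_datetime(table["date"]),
            "_rank": table["source"].map(rank),
            "_row": np.arange(len(table)),
        }
    )
    key = key.sort_values(["_rank", "_row"], kind="stable")
    keep_rows = key.drop_duplicates(subset=["lon", "lat", "date"], keep="first")["_row"]
    keep_rows = np.sort(keep_rows.to_numpy())
    out = table.iloc[keep_rows].reset_index(drop=True)
    n_removed = len(table) - len(out)
    log.info("deduplicate: removed %d repeated record(s)", n_removed)
    return out, n_removed


def filter_extremes(
    table: pd.DataFrame, threshold: float = EXTREME_THRESHOLD
) -> tuple[pd.DataFrame, int]:
    """Drop rows with pm25 strictly above ``threshold`` or below zero."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pm = table["pm25"].to_numpy(dtype=float)
    keep = (pm <= threshold) & (pm >= 0.0)
    out = table.loc[keep].reset_index(drop=True)
    n_removed = int((~keep).sum())
    log.info("filter_extremes: removed %d row(s) outside [0, %g]", n_removed, threshold)
    return out, n_removed


@dataclass
class ObservationSummary:
    n_observations: int
    n_unique_locations: int
    n_unique_days: int
    per_state: dict[str, int]
    quantiles: Optional[dict[str, float]]


def summarize(table: pd.DataFrame) -> ObservationSummary:
    """Counts and distribution quantiles of a canonical observation table."""
    if len(table) == 0:
        return ObservationSummary(0, 0, 0, {}, None)
    locs = table[["lon", "lat"]].round(COORD_DECIMALS)
    n_loc = len(locs.drop_duplicates())
    n_day = table["date"].nunique()
    per_state = table.groupby("state", sort=True).size().to_dict()
    qs = table["pm25"].quantile([0.0, 0.25, 0.5, 0.75, 0.95, 1.0])
    quantiles = {f"q{int(q * 100):02d}": float(v) for q, v in qs.items()}
    return ObservationSummary(len(table), n_loc, n_day, per_state, quantiles)


def qc_pipeline(
    tables: Mapping[str, pd.DataFrame],
    column_maps=None,
    source_precedence=None,
    threshold: float = EXTREME_THRESHOLD,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """harmonize -> deduplicate -> filter, returning the table and removal counts."""
    harmonized = harmonize_sources(tables, column_maps)
    deduped, n_dup = deduplicate(harmonized, source_precedence)
    clean, n_ext = filter_extremes(deduped, threshold)
    counts = {
        "n_input": len(harmonized),
        "n_duplicates_removed": n_dup,
        "n_extremes_removed": n_ext,
        "n_retained": len(clean),
    }
    return clean, counts
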