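"""Predictor construction for (location, day) keys.

Builds the full predictor vector the ensemble consumes: satellite AOD and CTM
PM2.5 joined by nearest grid cell and exact date, daily means of 6-hourly
meteorology, inverse-distance-weighted fire counts at lags 0–7 with a 500-km
weekly fire indicator, land-cover buffer fractions, road-length buffers,
population density, a monthly vegetation index, elevation, cosine temporal
harmonics, and a nested spatiotemporal dummy basis (period, year, season,
region, state, period×region, raw lat/lon).

All spatial linkage is nearest-neighbour on haversine distance in WGS84
degrees; there is deliberately no projection step.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .geo import EARTH_RADIUS_KM, Grid, haversine_km  # noqa: F401  (re-exported)

#: Cumulative fire-count buffer radii, km.
FIRE_RADII_KM = (25.0, 50.0, 100.0, 500.0)
#: Fire lags, days (current day plus previous seven).
FIRE_LAGS = tuple(range(8))
#: Urban land-cover buffer radii, km.
URBAN_RADII_KM = (1.0, 5.0, 10.0)
#: Road-length buffer radii, m.
ROAD_RADII_M = (100, 250, 500, 1000)
#: Road classes contributing to road-length buffers.
ROAD_CLASSES = ("arterial", "collector")

#: Region membership of the 11 western states (two-letter codes).
WESTERN_US_REGIONS = {
    "WA": "northwest",
    "OR": "northwest",
    "CA": "southwest",
    "NV": "southwest",
    "AZ": "four_corners",
    "CO": "four_corners",
    "NM": "four_corners",
    "UT": "four_corners",
    "WY": "northern_mountain",
    "MT": "northern_mountain",
    "ID": "northern_mountain",
}

#: Year groupings of the temporal nesting.  Years at or before the first
#: bound fall in the first period, etc.
PERIODS = (("2008_2012", 2012), ("2013_2016", 2016), ("2017_2018", 10_000))

KEY_COLUMNS = ["location_id", "lon", "lat", "state", "date"]


# ---------------------------------------------------------------------------
# fire proximity
# ---------------------------------------------------------------------------
def fire_proximity_features(
    lon: float,
    lat: float,
    date,
    fires: pd.DataFrame,
    radii_km=FIRE_RADII_KM,
    lags=FIRE_LAGS,
) -> dict[str, float]:
    """Fire features for one point and day.

    For each lag ℓ, count fire detections on day (date − ℓ) within each
    cumulative radius r, then average the counts with weights 1/r:
    ``idw_ℓ = Σ_r (count_{r,ℓ}/r) / Σ_r (1/r)``.  The indicator is 1 iff any
    detection fell within the largest radius over the whole lag window.
    """
    radii = np.asarray(radii_km, dtype=float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii_km must be strictly increasing")
    out = {f"fire_idw_lag{lag}": 0.0 for lag in lags}
    out["fire_within_500km_week"] = 0.0
    if fires is None or len(fires) == 0:
        return out
    date = pd.Timestamp(date)
    fdate = pd.to_datetime(fires["date"])
    d = haversine_km(lon, lat, fires["lon"].to_numpy(), fires["lat"].to_numpy())
    w = 1.0 / radii
    any_within_max = False
    for lag in lags:
        day = date - pd.Timedelta(days=int(lag))
        on_day = (fdate == day).to_numpy()
        counts = np.array([(on_day & (d <= r)).sum() for r in radii], dtype=float)
        out[f"fire_idw_lag{lag}"] = float((counts * w).sum() / w.sum())
        if counts[-1] >= 1:
            any_within_max = True
    out["fire_within_500km_week"] = 1.0 if any_within_max else 0.0
    return out


def fire_feature_arrays(
    lons, lats, dates: pd.DatetimeIndex, fires: pd.DataFrame,
    radii_km=FIRE_RADII_KM, lags=FIRE_LAGS,
):
    """Vectorized fire features for a set of points over a daily date index.

    Returns ``(idw, indicator)`` with shapes (n_points, n_days, n_lags) and
    (n_points, n_days).
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    radii = np.asarray(radii_km, dtype=float)
    n_pts, n_days, n_lags = lons.size, len(dates), len(lags)
    idw = np.zeros((n_pts, n_days, n_lags))
    indicator = np.zeros((n_pts, n_days))
    if fires is None or len(fires) == 0:
        return idw, indicator
    fday = (pd.to_datetime(fires["date"]) - dates[0]).dt.days.to_numpy()
    d = haversine_km(
        lons[:, None], lats[:, None],
        fires["lon"].to_numpy()[None, :], fires["lat"].to_numpy()[None, :],
    )
    # counts[pt, day, radius]
    counts = np.zeros((n_pts, n_days, radii.size))
    in_span = (fday >= -max(lags)) & (fday < n_days)
    lo = -max(lags)
    shifted = np.zeros((n_pts, n_days - lo, radii.size))
    for ri, r in enumerate(radii):
        within = d <= r
        # accumulate over fires into (day - lo) slots so negative days fit
        np.add.at(shifted[:, :, ri].T, fday[in_span] - lo, within[:, in_span].T.astype(float))
    w = 1.0 / radii
    wsum = w.sum()
    for li, lag in enumerate(lags):
        # counts on day - lag live at shifted slot (day - lag - lo)
        sl = shifted[:, (0 - lag - lo):(n_days - lag - lo), :]
        idw[:, :, li] = (sl * w[None, None, :]).sum(axis=2) / wsum
        indicator += sl[:, :, -1]
    indicator = (indicator >= 1).astype(float)
    return idw, indicator


# ---------------------------------------------------------------------------
# buffers
# ---------------------------------------------------------------------------
def buffer_fraction(raster: Grid, lon: float, lat: float, radius_km: float,
                    positive_codes=(22, 23, 24)) -> float:
    """Fraction of raster cells within ``radius_km`` carrying a positive code.

    Counts cells whose centre falls inside the circle; if no centre does
    (radius below the cell size), the nearest cell decides alone.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    if raster.values.size == 0:
        raise ValueError("raster is empty")
    lon2d, lat2d = raster.mesh()
    d = haversine_km(lon, lat, lon2d, lat2d)
    inside = d <= radius_km
    codes = raster.values
    positive = np.isin(codes, np.asarray(positive_codes))
    if not inside.any():
        iy, ix = np.unravel_index(np.argmin(d), d.shape)
        return float(positive[iy, ix])
    return float(positive[inside].mean())


def densify_roads(roads: pd.DataFrame, step_m: float = 25.0) -> pd.DataFrame:
    """Split road polylines into ~step_m pieces with midpoints and lengths.

    Only arterial/collector classes are kept.  Returns columns
    ``mid_lon, mid_lat, length_km``.
    """
    sub = roads[roads["road_class"].isin(ROAD_CLASSES)]
    mids_lon, mids_lat, lens = [], [], []
    for _, grp in sub.groupby("road_id", sort=True):
        grp = grp.sort_values("seq")
        lon = grp["lon"].to_numpy()
        lat = grp["lat"].to_numpy()
        for i in range(len(lon) - 1):
            seg_km = float(haversine_km(lon[i], lat[i], lon[i + 1], lat[i + 1]))
            if seg_km == 0.0:
                continue
            n = max(1, int(np.ceil(seg_km * 1000.0 / step_m)))
            t = (np.arange(n) + 0.5) / n
            mids_lon.append(lon[i] + t * (lon[i + 1] - lon[i]))
            mids_lat.append(lat[i] + t * (lat[i + 1] - lat[i]))
            lens.append(np.full(n, seg_km / n))
    if not mids_lon:
        return pd.DataFrame(columns=["mid_lon", "mid_lat", "length_km"])
    return pd.DataFrame(
        {
            "mid_lon": np.concatenate(mids_lon),
            "mid_lat": np.concatenate(mids_lat),
            "length_km": np.concatenate(lens),
        }
    )


def buffer_road_length(roads: pd.DataFrame, lon: float, lat: float,
                       radius_m: float, step_m: float = 25.0) -> float:
    """Total arterial/collector road length (km) within a radius of a point.

    Computed by densified-vertex summation: segments are split into ~step_m
    pieces and a piece counts iff its midpoint lies inside the buffer.
    """
    pieces = roads if {"mid_lon", "mid_lat", "length_km"} <= set(roads.columns) else densify_roads(roads, step_m)
    if len(pieces) == 0:
        return 0.0
    d = haversine_km(lon, lat, pieces["mid_lon"].to_numpy(), pieces["mid_lat"].to_numpy())
    return float(pieces["length_km"].to_numpy()[d <= radius_m / 1000.0].sum())


# ---------------------------------------------------------------------------
# temporal terms
# ---------------------------------------------------------------------------
def temporal_harmonics(dates) -> pd.DataFrame:
    """Cosine-of-day-of-week/-of-year/-of-month terms, aligned at boundaries.

    ``cos_dow`` uses Monday = 0; ``cos_doy`` uses a 365.25-day year so Dec 31
    and the following Jan 1 nearly coincide; ``cos_month`` peaks in January.
    """
    dates = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(dates)))
    dow = dates.dayofweek.to_numpy().astype(float)
    doy = dates.dayofyear.to_numpy().astype(float)
    month = dates.month.to_numpy().astype(float)
    return pd.DataFrame(
        {
            "cos_dow": np.cos(2.0 * np.pi * dow / 7.0),
            "cos_doy": np.cos(2.0 * np.pi * (doy - 1.0) / 365.25),
            "cos_month": np.cos(2.0 * np.pi * (month - 1.0) / 12.0),
        }
    )


def season_of(dates) -> np.ndarray:
    """Meteorological season: DJF winter, MAM spring, JJA summer, SON fall."""
    month = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(dates))).month.to_numpy()
    return np.select(
        [np.isin(month, (12, 1, 2)), np.isin(month, (3, 4, 5)), np.isin(month, (6, 7, 8))],
        ["winter", "spring", "summer"],
        default="fall",
    )


def season_year(dates) -> np.ndarray:
    """Year label of the season; December counts toward the following winter."""
    dates = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(dates)))
    year = dates.year.to_numpy()
    return np.where(dates.month.to_numpy() == 12, year + 1, year)


def period_of_year(years) -> np.ndarray:
    """Period label ('2008_2012', '2013_2016', '2017_2018') per year."""
    years = np.atleast_1d(np.asarray(years, dtype=int))
    out = np.empty(years.shape, dtype=object)
    remaining = np.ones(years.shape, dtype=bool)
    for name, upper in PERIODS:
        hit = remaining & (years <= upper)
        out[hit] = name
        remaining &= ~hit
    return out


def spatiotemporal_basis(
    states, lons, lats, dates, region_of_state=WESTERN_US_REGIONS
) -> pd.DataFrame:
    """Nested spatiotemporal dummies plus raw coordinates.

    Emits period (3), year, season (4), region, state, and period×region
    dummies; exactly one dummy is active per group per row.  An unknown state
    label is rejected.
    """
    states = np.atleast_1d(np.asarray(states, dtype=object))
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    dates = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(dates)))
    unknown = sorted(set(states) - set(region_of_state))
    if unknown:
        raise KeyError(f"state label(s) not in the region map: {unknown}")
    regions = np.array([region_of_state[s] for s in states], dtype=object)
    region_levels = sorted(set(region_of_state.values()))
    state_levels = sorted(region_of_state)
    years = dates.year.to_numpy()
    periods = period_of_year(years)
    seasons = season_of(dates)

    out = {"latitude": lats, "longitude": lons, "year": years.astype(float)}
    for name, _ in PERIODS:
        out[f"period_{name}"] = (periods == name).astype(float)
    for s in ("winter", "spring", "summer", "fall"):
        out[f"season_{s}"] = (seasons == s).astype(float)
    for r in region_levels:
        out[f"region_{r}"] = (regions == r).astype(float)
    for s in state_levels:
        out[f"state_{s}"] = (states == s).astype(float)
    for name, _ in PERIODS:
        for r in region_levels:
            out[f"period_{name}_x_region_{r}"] = out[f"period_{name}"] * out[f"region_{r}"]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# meteorology and joins
# ---------------------------------------------------------------------------
def daily_met_means(records: pd.DataFrame, variables=None) -> pd.Series:
    """24-h means of up to four 6-hourly records for one grid cell and day.

    The mean uses whatever records are present; with none present the value
    is NaN (a missingness flag downstream).
    """
    variables = list(variables) if variables is not None else [
        c for c in records.columns if c not in ("cell_id", "date", "hour")
    ]
    if len(records) > 4:
        raise ValueError("at most 4 six-hourly records per cell-day")
    return records[variables].mean(axis=0, skipna=True)


def nearest_join(targets: pd.DataFrame, source: pd.DataFrame,
                 value_col: str = "value") -> pd.DataFrame:
    """Attach to each (lon, lat, date) target the value of the spatially
    nearest source location on the exact same date.

    Ties go to the lowest source location index (row order of first
    appearance).  A source location with no value for the target's date
    yields NaN and ``missing=1``.
    """
    if len(source) == 0:
        raise ValueError("source has no locations")
    src_locs = source[["lon", "lat"]].drop_duplicates().reset_index(drop=True)
    d = haversine_km(
        targets["lon"].to_numpy()[:, None], targets["lat"].to_numpy()[:, None],
        src_locs["lon"].to_numpy()[None, :], src_locs["lat"].to_numpy()[None, :],
    )
    nearest = d.argmin(axis=1)
    dist = d[np.arange(len(targets)), nearest]
    src = source.merge(
        src_locs.reset_index(names="_loc"), on=["lon", "lat"], how="left"
    )
    lookup = {
        (int(loc), pd.Timestamp(date)): val
        for loc, date, val in zip(src["_loc"], pd.to_datetime(src["date"]), src[value_col])
    }
    tdates = pd.to_datetime(targets["date"])
    values = np.array(
        [lookup.get((int(l), pd.Timestamp(t)), np.nan) for l, t in zip(nearest, tdates)],
        dtype=float,
    )
    return pd.DataFrame(
        {
            "value": values,
            "source_index": nearest,
            "distance_km": dist,
            "missing": np.isnan(values).astype(int),
        },
        index=targets.index,
    )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------
def assemble_features(keys: pd.DataFrame, world, include_ctm: bool = True) -> pd.DataFrame:
    """One predictor row per (location, day) key, order preserved.

    ``keys`` needs columns ``location_id, lon, lat, state, date``.  Grid
    layers are linked by nearest cell and exact date; per-column missingness
    flags (``miss_*``) mark AOD/met/CTM gaps for the imputation stage.
    """
    for c in KEY_COLUMNS:
        if c not in keys.columns:
            raise ValueError(f"keys table lacks required column {c!r}")
    keys = keys.reset_index(drop=True)
    dates = pd.to_datetime(keys["date"])
    day_idx = world.day_index(dates)

    locs = keys.drop_duplicates("location_id")[["location_id", "lon", "lat", "state"]]
    locs = locs.reset_index(drop=True)
    loc_pos = {lid: i for i, lid in enumerate(locs["location_id"])}
    row_loc = keys["location_id"].map(loc_pos).to_numpy()
    llon = locs["lon"].to_numpy()
    llat = locs["lat"].to_numpy()

    # static, per unique location
    iy, ix = world.grid.nearest_cell(llon, llat)
    elev = world.elevation_raster.values[iy, ix]
    popden = world.population_raster.values[iy, ix]
    urb = {
        r: np.array([
            buffer_fraction(world.urban_raster, lo, la, r, positive_codes=(22, 23, 24))
            for lo, la in zip(llon, llat)
        ])
        for r in URBAN_RADII_KM
    }
    pieces = densify_roads(world.roads)
    road = {
        r: np.array([buffer_road_length(pieces, lo, la, r) for lo, la in zip(llon, llat)])
        for r in ROAD_RADII_M
    }

    # fire features on unique locations × world days
    idw, indicator = fire_feature_arrays(llon, llat, world.dates, world.fires)

    # dynamic grid layers per row
    r_iy, r_ix = iy[row_loc], ix[row_loc]
    aod = world.aod_daily[r_iy, r_ix, day_idx]
    ctm = world.ctm_daily[r_iy, r_ix, day_idx]
    month_idx = dates.dt.month.to_numpy() - 1
    veg = world.vegetation_monthly.values[month_idx, r_iy, r_ix]
    met_cols = {}
    for var in world.met_6h:
        met_cols[f"met_{var}"] = world.met_daily(var)[r_iy, r_ix, day_idx]

    harm = temporal_harmonics(dates)
    basis = spatiotemporal_basis(
        keys["state"].to_numpy(), keys["lon"].to_numpy(), keys["lat"].to_numpy(),
        dates, world.region_of_state,
    )

    out = keys[KEY_COLUMNS].copy()
    out["date"] = dates
    out["aod"] = aod
    for name, col in met_cols.items():
        out[name] = col
    if include_ctm:
        out["ctm_pm25"] = ctm
    for li in FIRE_LAGS:
        out[f"fire_idw_lag{li}"] = idw[row_loc, day_idx, li]
    out["fire_within_500km_week"] = indicator[row_loc, day_idx]
    out["elevation"] = elev[row_loc]
    for r in URBAN_RADII_KM:
        out[f"urban_frac_{int(r)}km"] = urb[r][row_loc]
    out["population_density"] = popden[row_loc]
    out["vegetation_index"] = veg
    for r in ROAD_RADII_M:
        out[f"road_len_{r}m"] = road[r][row_loc]
    for c in harm.columns:
        out[c] = harm[c].to_numpy()
    for c in basis.columns:
        out[c] = basis[c].to_numpy()
    out["miss_aod"] = np.isnan(aod).astype(int)
    for name in met_cols:
        out[f"miss_{name}"] = np.isnan(out[name].to_numpy()).astype(int)
    if include_ctm:
        out["miss_ctm_pm25"] = np.isnan(ctm).astype(int)
    return out


def predictor_columns(features: pd.DataFrame) -> list[str]:
    """Model design-matrix columns: everything but keys and missing flags."""
    return [
        c for c in features.columns
        if c not in KEY_COLUMNS and not c.startswith("miss_")
    ]
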