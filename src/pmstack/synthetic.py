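"""Seeded synthetic study domain for the PM2.5 exposure pipeline.

Generates a self-contained "world": a nonnegative, right-skewed daily PM2.5
truth field over a western-US-like domain, a preferentially urban monitoring
network (plus mobile fire monitors), wildfire detections with Gaussian smoke
plumes and lagged decay, and every predictor layer the feature builder
consumes — an AOD proxy with cloud-like missingness, 6-hourly meteorology
with a boundary-layer height that collapses in winter, a spatially smoothed
and biased chemical-transport-model (CTM) proxy, land-cover codes, elevation,
population density, a monthly vegetation index, road polylines, and areal
centroids at county / ZCTA / tract level.

The truth model is log-additive — concentrations are the exponential of a sum
of a spatial baseline, a winter-peaking seasonal cosine, an urban increment,
an elevation effect, a synoptic weather term, and a valley inversion term
scaled by inverse boundary-layer height — plus an additive smoke term summed
over fires with Gaussian spatial kernels and geometric lag decay.  The
exponential form makes the field nonnegative with a heavy right tail, the way
real 24-h PM2.5 distributions look in wildfire country.

Every random component draws from its own stream derived from
``(config.seed, component name)``, so regenerating with the same config is
bitwise reproducible and switching one component off (e.g. ``fire_rate=0``)
leaves all other components unchanged.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geo import Grid, haversine_km

#: 6-hourly meteorology variables (daily means of these become predictors).
MET_VARS = (
    "pbl",
    "temp_2m",
    "rh_2m",
    "dewpoint_2m",
    "wind_u",
    "wind_v",
    "pressure_sfc",
    "pressure_msl",
    "vv_850",
    "vv_700",
)

#: NLCD-style land-cover codes counted as urban development.
URBAN_CODES = (22, 23, 24)

#: Monitor source labels used by the generator.
SOURCE_DAILY = "airnow"
SOURCE_1IN3 = "improve"
SOURCE_MOBILE = "fire_cache"
SOURCE_DUPLICATE = "state_network"


@dataclass(frozen=True)
class WorldConfig:
    """All knobs of the synthetic world; defaults define the study conditions.

    Proportions are in [0, 1]; distances in km; concentrations in µg/m³.
    """

    seed: int = 0
    domain_bbox: tuple[float, float, float, float] = (-121.0, -114.0, 36.0, 42.0)
    n_days: int = 365
    start_date: str = "2013-01-01"
    n_monitors: int = 300
    urban_site_fraction: float = 0.6
    n_mobile_fire_monitors: int = 30
    fire_rate: float = 2.0
    smoke_sigma_km: float = 40.0
    smoke_decay_per_day: float = 0.65
    aod_noise_sd: float = 0.05
    aod_missing_prob: float = 0.35
    ctm_bias: float = 2.0
    ctm_smooth_km: float = 50.0
    obs_noise_sd: float = 0.10
    every_third_day_fraction: float = 0.6
    duplicate_fraction: float = 0.05
    extreme_injection_count: int = 5
    n_states: int = 8
    raster_resolution_km: float = 25.0

    def __post_init__(self) -> None:
        lon_min, lon_max, lat_min, lat_max = self.domain_bbox
        if not (lon_min < lon_max and lat_min < lat_max):
            raise ValueError("domain_bbox is empty or inverted")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not 0.0 < self.smoke_decay_per_day < 1.0:
            raise ValueError("smoke_decay_per_day must lie in (0, 1)")
        for name in (
            "urban_site_fraction",
            "aod_missing_prob",
            "every_third_day_fraction",
            "duplicate_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "n_monitors",
            "n_mobile_fire_monitors",
            "extreme_injection_count",
            "n_states",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("fire_rate", "aod_noise_sd", "obs_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.smoke_sigma_km <= 0 or self.ctm_smooth_km <= 0:
            raise ValueError("smoke_sigma_km and ctm_smooth_km must be positive")
        if self.raster_resolution_km <= 0:
            raise ValueError("raster_resolution_km must be positive")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")

    def to_dict(self) -> dict:
        out = {}
        for f in dc_fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "WorldConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown WorldConfig fields: {sorted(unknown)}")
        d = dict(d)
        if "domain_bbox" in d:
            d["domain_bbox"] = tuple(d["domain_bbox"])
        return cls(**d)


def _rng(seed: int, name: str) -> np.random.Generator:
    """Independent stream for one named component of the world."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _smooth_field(rng, shape, sigma, scale=1.0):
    """Standardized Gaussian-smoothed white noise (spatially/temporally correlated)."""
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, sigma=sigma, mode="nearest")
    sd = sm.std()
    if sd > 0:
        sm = sm / sd
    return scale * sm


class _Sinusoids:
    """A fixed small set of low-frequency 2-D sinusoids: cheap smooth fields."""

    def __init__(self, rng, n_terms, amp, freq=2.5):
        self.a = rng.normal(0.0, amp, size=n_terms)
        self.p = rng.uniform(-freq, freq, size=n_terms)
        self.q = rng.uniform(-freq, freq, size=n_terms)
        self.phi = rng.uniform(0.0, 2.0 * np.pi, size=n_terms)

    def __call__(self, u, v):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        out = np.zeros(np.broadcast(u, v).shape, dtype=float)
        for a, p, q, phi in zip(self.a, self.p, self.q, self.phi):
            out += a * np.cos(2.0 * np.pi * (p * u + q * v) + phi)
        return out


@dataclass
class World:
    """A generated world.  See :func:`generate_world` for the construction."""

    config: WorldConfig
    dates: pd.DatetimeIndex
    monitors: pd.DataFrame
    fires: pd.DataFrame
    urban_raster: Grid
    elevation_raster: Grid
    population_raster: Grid
    vegetation_monthly: Grid
    roads: pd.DataFrame
    met_6h: dict[str, np.ndarray]
    aod_daily: np.ndarray
    ctm_daily: np.ndarray
    truth_grid: np.ndarray
    smoke_grid: np.ndarray
    centroids: pd.DataFrame
    region_of_state: dict[str, str]
    state_seeds: pd.DataFrame
    _truth_point: Callable = field(repr=False, default=None)
    _truth_matrix: Callable = field(repr=False, default=None)
    _met_daily: dict[str, np.ndarray] = field(repr=False, default=None)

    # -- helpers ---------------------------------------------------------
    @property
    def grid(self) -> Grid:
        return self.elevation_raster

    def day_index(self, dates) -> np.ndarray:
        """Map dates to day offsets within the world span; reject outsiders."""
        dates = pd.DatetimeIndex(pd.to_datetime(dates))
        idx = (dates - self.dates[0]).days
        idx = np.asarray(idx, dtype=int)
        bad = (idx < 0) | (idx >= len(self.dates))
        if bad.any():
            raise ValueError(f"date outside world span: {dates[bad][0].date()}")
        return idx

    def truth(self, lons, lats, dates) -> np.ndarray:
        """True PM2.5 (µg/m³) at points and dates; deterministic.

        ``lons``/``lats``/``dates`` are aligned per element (same length).
        """
        return self._truth_point(
            np.atleast_1d(np.asarray(lons, dtype=float)),
            np.atleast_1d(np.asarray(lats, dtype=float)),
            self.day_index(np.atleast_1d(dates)),
        )

    def truth_matrix(self, lons, lats) -> np.ndarray:
        """True PM2.5 at each point for every world day, shape (n_pts, n_days)."""
        return self._truth_matrix(
            np.atleast_1d(np.asarray(lons, dtype=float)),
            np.atleast_1d(np.asarray(lats, dtype=float)),
        )

    def met_daily(self, var: str) -> np.ndarray:
        """Daily means of a 6-hourly met variable, shape (n_lat, n_lon, n_days)."""
        if self._met_daily is None:
            self._met_daily = {}
        if var not in self._met_daily:
            self._met_daily[var] = self.met_6h[var].mean(axis=3, dtype=np.float64)
        return self._met_daily[var]

    def state_of(self, lons, lats) -> np.ndarray:
        """State label of each point: nearest state seed (contiguous regions)."""
        d = haversine_km(
            np.atleast_1d(lons)[:, None],
            np.atleast_1d(lats)[:, None],
            self.state_seeds["lon"].to_numpy()[None, :],
            self.state_seeds["lat"].to_numpy()[None, :],
        )
        return self.state_seeds["state"].to_numpy()[d.argmin(axis=1)]

    def save(self, path, include_met: bool = False) -> None:
        """Serialize tables to a directory of CSV/Parquet files.

        The world is fully reconstructable from ``config.yaml`` via
        :func:`generate_world`; the tables are for external consumption.
        """
        import yaml

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "config.yaml").write_text(
            yaml.safe_dump(self.config.to_dict(), sort_keys=True)
        )
        self.monitors.to_csv(path / "monitors.csv", index=False)
        fires = self.fires.copy()
        fires["date"] = fires["date"].dt.strftime("%Y-%m-%d")
        fires.to_csv(path / "fires.csv", index=False)
        self.roads.to_csv(path / "roads.csv", index=False)
        self.centroids.to_csv(path / "centroids.csv", index=False)
        lon2d, lat2d = self.grid.mesh()
        static = pd.DataFrame(
            {
                "cell_id": np.arange(lon2d.size),
                "lon": lon2d.ravel(),
                "lat": lat2d.ravel(),
                "landcover_code": self.urban_raster.values.ravel(),
                "elevation_m": self.elevation_raster.values.ravel(),
                "population_density": self.population_raster.values.ravel(),
            }
        )
        for m in range(12):
            static[f"vegetation_m{m + 1:02d}"] = self.vegetation_monthly.values[m].ravel()
        static.to_csv(path / "grid_static.csv", index=False)
        n_cells = lon2d.size
        n_days = len(self.dates)
        daily = pd.DataFrame(
            {
                "cell_id": np.repeat(np.arange(n_cells), n_days),
                "date": np.tile(self.dates.strftime("%Y-%m-%d"), n_cells),
                "aod": self.aod_daily.reshape(n_cells, n_days).ravel(),
                "ctm_pm25": self.ctm_daily.reshape(n_cells, n_days).ravel(),
            }
        )
        daily.to_parquet(path / "grid_daily.parquet", index=False)
        if include_met:
            recs = {
                "cell_id": np.repeat(np.arange(n_cells), n_days * 4),
                "date": np.tile(np.repeat(self.dates.strftime("%Y-%m-%d"), 4), n_cells),
                "hour": np.tile([0, 6, 12, 18], n_cells * n_days),
            }
            for var in MET_VARS:
                recs[var] = self.met_6h[var].reshape(-1)
            pd.DataFrame(recs).to_parquet(path / "met_6h.parquet", index=False)


def generate_world(config: WorldConfig) -> World:
    """Build the full synthetic world from a validated config."""
    if not isinstance(config, WorldConfig):
        config = WorldConfig.from_dict(dict(config))
    lon_min, lon_max, lat_min, lat_max = config.domain_bbox
    dates = pd.date_range(config.start_date, periods=config.n_days, freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)

    # --- grid geometry ---------------------------------------------------
    lat_mid = 0.5 * (lat_min + lat_max)
    km_per_deg_lat = 111.32
    km_per_deg_lon = 111.32 * np.cos(np.radians(lat_mid))
    res = config.raster_resolution_km
    n_lon = max(2, int(round((lon_max - lon_min) * km_per_deg_lon / res)))
    n_lat = max(2, int(round((lat_max - lat_min) * km_per_deg_lat / res)))
    lon_c = lon_min + (np.arange(n_lon) + 0.5) * (lon_max - lon_min) / n_lon
    lat_c = lat_min + (np.arange(n_lat) + 0.5) * (lat_max - lat_min) / n_lat
    lon2d, lat2d = np.meshgrid(lon_c, lat_c)

    def _uv(lon, lat):
        return (
            (np.asarray(lon) - lon_min) / (lon_max - lon_min),
            (np.asarray(lat) - lat_min) / (lat_max - lat_min),
        )

    u2d, v2d = _uv(lon2d, lat2d)

    # --- smooth static fields -------------------------------------------
    base_f = _Sinusoids(_rng(config.seed, "base"), 6, 0.16)
    # short-wavelength site-scale structure (~20-30 km): the part of the field
    # a model can memorize at monitored places but not carry to new locations
    local_f = _Sinusoids(_rng(config.seed, "local"), 30, 0.09, freq=25.0)
    elev_f = _Sinusoids(_rng(config.seed, "elevation"), 5, 0.45)

    # city centres: first city is the designated inversion valley
    rng_city = _rng(config.seed, "cities")
    n_city = 4
    city_lon = rng_city.uniform(lon_min + 0.12 * (lon_max - lon_min), lon_max - 0.12 * (lon_max - lon_min), n_city)
    city_lat = rng_city.uniform(lat_min + 0.12 * (lat_max - lat_min), lat_max - 0.12 * (lat_max - lat_min), n_city)
    city_w = np.array([0.95, 0.80, 0.70, 0.60])
    city_r = np.array([25.0, 18.0, 15.0, 12.0])  # km

    def urban_intensity(lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        out = np.zeros(lon.shape, dtype=float)
        for k in range(n_city):
            d = haversine_km(lon, lat, city_lon[k], city_lat[k])
            out += city_w[k] * np.exp(-(d**2) / (2.0 * city_r[k] ** 2))
        return np.clip(out, 0.0, 1.0)

    valley_lon, valley_lat = city_lon[0], city_lat[0]

    def valley_weight(lon, lat):
        d = haversine_km(np.asarray(lon, float), np.asarray(lat, float), valley_lon, valley_lat)
        return np.exp(-(d**2) / (2.0 * 60.0**2))

    def elevation_m(lon, lat):
        u, v = _uv(lon, lat)
        e = 1400.0 + 700.0 * elev_f(u, v)
        e = e - 600.0 * valley_weight(lon, lat)
        return np.clip(e, 50.0, None)

    urb2d = urban_intensity(lon2d, lat2d)
    elev2d = elevation_m(lon2d, lat2d)
    valley2d = valley_weight(lon2d, lat2d)

    # --- land cover, population, vegetation ------------------------------
    rng_lc = _rng(config.seed, "landcover")
    dither = urb2d + 0.08 * rng_lc.standard_normal(urb2d.shape)
    codes = np.where(
        dither > 0.75, 24, np.where(dither > 0.55, 23, np.where(dither > 0.40, 22, 0))
    )
    codes = np.where(codes == 0, np.where(elev2d > 1800.0, 42, 52), codes)
    urban_raster = Grid(lon_c, lat_c, codes.astype(np.int16))
    elevation_raster = Grid(lon_c, lat_c, elev2d)
    pop2d = 10.0 + 4000.0 * urb2d**1.7
    population_raster = Grid(lon_c, lat_c, pop2d)

    veg_f = _Sinusoids(_rng(config.seed, "vegetation"), 4, 0.35)
    veg_spatial = np.clip(0.45 + veg_f(u2d, v2d) - 0.35 * urb2d, 0.05, 0.95)
    months = np.arange(1, 13, dtype=float)
    veg = np.empty((12, n_lat, n_lon))
    for m in range(12):
        seasonal = 1.0 + 0.35 * np.cos(2.0 * np.pi * (months[m] - 7.5) / 12.0)
        veg[m] = np.clip(veg_spatial * seasonal, 0.02, 0.98)
    vegetation_monthly = Grid(lon_c, lat_c, veg)

    # --- roads ------------------------------------------------------------
    roads = _make_roads(config, city_lon, city_lat, (lon_min, lon_max, lat_min, lat_max), km_per_deg_lon)

    # --- states and regions ----------------------------------------------
    rng_state = _rng(config.seed, "states")
    st_lon = rng_state.uniform(lon_min, lon_max, config.n_states)
    st_lat = rng_state.uniform(lat_min, lat_max, config.n_states)
    order = np.argsort(st_lon, kind="stable")
    state_seeds = pd.DataFrame(
        {
            "state": [f"S{i + 1}" for i in range(config.n_states)],
            "lon": st_lon[order],
            "lat": st_lat[order],
        }
    )
    n_regions = min(4, config.n_states)
    region_of_state = {
        row.state: f"R{int(i * n_regions / config.n_states) + 1}"
        for i, row in enumerate(state_seeds.itertuples())
    }

    def state_of(lon, lat):
        d = haversine_km(
            np.atleast_1d(lon)[:, None],
            np.atleast_1d(lat)[:, None],
            state_seeds["lon"].to_numpy()[None, :],
            state_seeds["lat"].to_numpy()[None, :],
        )
        return state_seeds["state"].to_numpy()[d.argmin(axis=1)]

    # --- meteorology -------------------------------------------------------
    met_6h = _make_met(config, doy, elev2d, (n_lat, n_lon))
    pbl_daily = met_6h["pbl"].mean(axis=3, dtype=np.float64)  # (n_lat, n_lon, n_days)

    # --- fires -------------------------------------------------------------
    fires = _make_fires(config, dates, doy, (lon_min, lon_max, lat_min, lat_max))

    # --- truth field --------------------------------------------------------
    seasonal_t = 0.33 * np.cos(2.0 * np.pi * (doy - 10.0) / 365.25)
    weather = _smooth_field(
        _rng(config.seed, "weather"), (n_lat, n_lon, config.n_days), sigma=(2.0, 2.0, 1.5), scale=0.25
    )

    def inversion_term(pbl):
        return 0.5 * np.clip(400.0 / np.maximum(pbl, 50.0) - 1.0, 0.0, 3.0)

    log_static2d = (
        np.log(5.0)
        + base_f(u2d, v2d)
        + local_f(u2d, v2d)
        + 0.5 * urb2d
        - 0.25 * (elev2d / 1000.0 - float(elev2d.mean()) / 1000.0)
    )
    log_grid = (
        log_static2d[:, :, None]
        + seasonal_t[None, None, :]
        + valley2d[:, :, None] * inversion_term(pbl_daily)
        + weather
    )
    base_truth_grid = np.exp(log_grid)
    smoke_grid = _smoke_on_points(
        lon2d.ravel(), lat2d.ravel(), fires, config, config.n_days
    ).reshape(n_lat, n_lon, config.n_days)
    truth_grid = base_truth_grid + smoke_grid

    grid_for_lookup = Grid(lon_c, lat_c, elev2d)

    def truth_matrix(lons, lats):
        """Truth at given points for every day, shape (n_pts, n_days)."""
        iy, ix = grid_for_lookup.nearest_cell(lons, lats)
        u, v = _uv(lons, lats)
        log_static = (
            np.log(5.0)
            + base_f(u, v)
            + local_f(u, v)
            + 0.5 * urban_intensity(lons, lats)
            - 0.25 * (elevation_m(lons, lats) / 1000.0 - float(elev2d.mean()) / 1000.0)
        )
        vals = np.exp(
            log_static[:, None]
            + seasonal_t[None, :]
            + valley_weight(lons, lats)[:, None] * inversion_term(pbl_daily[iy, ix, :])
            + weather[iy, ix, :]
        )
        return vals + _smoke_on_points(lons, lats, fires, config, config.n_days)

    def truth_point(lons, lats, day_idx):
        # evaluate unique points once, then index (row, day)
        pts, inv = np.unique(np.column_stack([lons, lats]), axis=0, return_inverse=True)
        mat = truth_matrix(pts[:, 0], pts[:, 1])
        return mat[inv, np.asarray(day_idx, dtype=int)]

    # --- AOD proxy ----------------------------------------------------------
    rng_aod = _rng(config.seed, "aod")
    aod_noise = _smooth_field(
        rng_aod, (n_lat, n_lon, config.n_days), sigma=(2.0, 2.0, 1.0), scale=config.aod_noise_sd
    )
    aod = np.clip(0.06 + 0.013 * truth_grid + aod_noise, 0.005, None)
    cloud = _smooth_field(
        _rng(config.seed, "clouds"), (n_lat, n_lon, config.n_days), sigma=(2.5, 2.5, 0.8)
    )
    if config.aod_missing_prob > 0:
        thresh = np.quantile(cloud, 1.0 - config.aod_missing_prob)
        aod = np.where(cloud > thresh, np.nan, aod)

    # --- CTM proxy: spatially smoothed truth plus a constant bias -----------
    sigma_cells = config.ctm_smooth_km / res
    ctm = np.empty_like(truth_grid)
    for t in range(config.n_days):
        ctm[:, :, t] = gaussian_filter(truth_grid[:, :, t], sigma=sigma_cells, mode="nearest")
    ctm = ctm + config.ctm_bias

    # --- monitors ------------------------------------------------------------
    monitors = _make_monitors(
        config, city_lon, city_lat, city_w, state_of,
        (lon_min, lon_max, lat_min, lat_max), km_per_deg_lon, km_per_deg_lat, fires,
    )

    # --- centroids ------------------------------------------------------------
    centroids = _make_centroids(
        config, city_lon, city_lat, state_of,
        (lon_min, lon_max, lat_min, lat_max), km_per_deg_lon, km_per_deg_lat,
    )

    return World(
        config=config,
        dates=dates,
        monitors=monitors,
        fires=fires,
        urban_raster=urban_raster,
        elevation_raster=elevation_raster,
        population_raster=population_raster,
        vegetation_monthly=vegetation_monthly,
        roads=roads,
        met_6h=met_6h,
        aod_daily=aod,
        ctm_daily=ctm,
        truth_grid=truth_grid,
        smoke_grid=smoke_grid,
        centroids=centroids,
        region_of_state=region_of_state,
        state_seeds=state_seeds,
        _truth_point=truth_point,
        _truth_matrix=truth_matrix,
        _met_daily={},
    )


def _smoke_on_points(lons, lats, fires, config, n_days):
    """Additive smoke at points × days: Σ_f size·exp(−d²/2σ²)·decay^lag, lags 0..7."""
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    out = np.zeros((lons.size, n_days))
    if len(fires) == 0:
        return out
    sigma = config.smoke_sigma_km
    d = haversine_km(
        lons[:, None], lats[:, None],
        fires["lon"].to_numpy()[None, :], fires["lat"].to_numpy()[None, :],
    )
    contrib = fires["size"].to_numpy()[None, :] * np.exp(-(d**2) / (2.0 * sigma**2))
    fire_day = fires["day_idx"].to_numpy()
    out_t = out.T  # (n_days, n_pts) view
    for lag in range(8):
        day = fire_day + lag
        ok = day < n_days
        if not ok.any():
            continue
        np.add.at(out_t, day[ok], (contrib[:, ok] * config.smoke_decay_per_day**lag).T)
    return out


def _make_fires(config, dates, doy, bbox):
    lon_min, lon_max, lat_min, lat_max = bbox
    rng = _rng(config.seed, "fires")
    weight = np.exp(2.2 * np.cos(2.0 * np.pi * (doy - 227.0) / 365.25))
    rate = config.fire_rate * weight / weight.mean() if config.fire_rate > 0 else np.zeros_like(weight)
    n_per_day = rng.poisson(rate)
    total = int(n_per_day.sum())
    day_idx = np.repeat(np.arange(config.n_days), n_per_day)
    fires = pd.DataFrame(
        {
            "lon": rng.uniform(lon_min, lon_max, total),
            "lat": rng.uniform(lat_min, lat_max, total),
            "day_idx": day_idx,
            "size": np.exp(rng.normal(np.log(25.0), 0.9, total)),
        }
    )
    fires["date"] = dates[0] + pd.to_timedelta(fires["day_idx"], unit="D")
    return fires[["lon", "lat", "date", "day_idx", "size"]]


def _make_met(config, doy, elev2d, shape):
    n_lat, n_lon = shape
    n_days = config.n_days
    seasonal = np.cos(2.0 * np.pi * (doy - 15.0) / 365.25)  # 1 in winter
    met = {}

    def smooth(name, scale, sigma=(2.0, 2.0, 1.2)):
        return _smooth_field(_rng(config.seed, name), (n_lat, n_lon, n_days), sigma, scale)

    pbl_season = np.exp(-0.7 * seasonal)  # collapses in winter
    diurnal = np.array([0.55, 0.80, 1.50, 1.15])
    pbl_noise = smooth("met_pbl", 0.35)
    pbl = (
        700.0
        * pbl_season[None, None, :, None]
        * diurnal[None, None, None, :]
        * np.exp(pbl_noise[:, :, :, None])
    )
    met["pbl"] = np.maximum(pbl, 60.0).astype(np.float32)

    t_noise = smooth("met_temp", 2.5)
    temp_daily = (
        12.0
        - 13.0 * seasonal[None, None, :]
        - 6.5 * (elev2d[:, :, None] / 1000.0 - 1.2)
        + t_noise
    )
    t_diurnal = np.array([-4.0, -1.0, 5.0, 2.0])
    met["temp_2m"] = (temp_daily[:, :, :, None] + t_diurnal[None, None, None, :]).astype(np.float32)

    rh_daily = np.clip(50.0 + 22.0 * seasonal[None, None, :] + smooth("met_rh", 9.0), 5.0, 100.0)
    rh_diurnal = np.array([8.0, 4.0, -8.0, -4.0])
    rh = np.clip(rh_daily[:, :, :, None] + rh_diurnal[None, None, None, :], 3.0, 100.0)
    met["rh_2m"] = rh.astype(np.float32)
    met["dewpoint_2m"] = (met["temp_2m"] - ((100.0 - rh) / 5.0)).astype(np.float32)

    for name, scale in (("wind_u", 3.0), ("wind_v", 3.0), ("vv_850", 0.15), ("vv_700", 0.12)):
        daily = smooth(f"met_{name}", scale)
        jitter = _rng(config.seed, f"met_{name}_6h").normal(0.0, 0.25 * scale, (n_lat, n_lon, n_days, 4))
        met[name] = (daily[:, :, :, None] + jitter).astype(np.float32)

    four = np.zeros((1, 1, 1, 4))
    sfc = 1013.25 * np.exp(-elev2d / 8400.0)
    met["pressure_sfc"] = (
        sfc[:, :, None, None] + smooth("met_psfc", 3.0)[:, :, :, None] + four
    ).astype(np.float32)
    met["pressure_msl"] = (
        1013.25 + smooth("met_pmsl", 6.0)[:, :, :, None] + four
    ).astype(np.float32)
    return met


def _make_roads(config, city_lon, city_lat, bbox, km_per_deg_lon):
    lon_min, lon_max, lat_min, lat_max = bbox
    rng = _rng(config.seed, "roads")
    rows = []
    rid = 0

    def add_line(lon0, lat0, bearing_deg, length_km, step_km, cls):
        nonlocal rid
        n = max(2, int(length_km / step_km) + 1)
        th = np.radians(bearing_deg)
        s = np.linspace(-length_km / 2.0, length_km / 2.0, n)
        lon = lon0 + s * np.sin(th) / km_per_deg_lon
        lat = lat0 + s * np.cos(th) / 111.32
        ok = (lon >= lon_min) & (lon <= lon_max) & (lat >= lat_min) & (lat <= lat_max)
        if ok.sum() < 2:
            return
        for seq, (lo, la) in enumerate(zip(lon[ok], lat[ok])):
            rows.append((f"RD{rid:04d}", cls, seq, lo, la))
        rid += 1

    for k in range(len(city_lon)):
        for _ in range(2):
            add_line(city_lon[k], city_lat[k], rng.uniform(0, 180), rng.uniform(80, 150), 4.0, "arterial")
        for _ in range(4):
            off = rng.normal(0.0, 0.12, 2)
            add_line(
                city_lon[k] + off[0], city_lat[k] + off[1],
                rng.uniform(0, 180), rng.uniform(12, 35), 2.0, "collector",
            )
    for _ in range(6):
        add_line(
            rng.uniform(lon_min, lon_max), rng.uniform(lat_min, lat_max),
            rng.uniform(0, 180), rng.uniform(20, 60), 3.0, "collector",
        )
    return pd.DataFrame(rows, columns=["road_id", "road_class", "seq", "lon", "lat"])


def _make_monitors(config, city_lon, city_lat, city_w, state_of, bbox,
                   km_per_deg_lon, km_per_deg_lat, fires):
    lon_min, lon_max, lat_min, lat_max = bbox
    rng = _rng(config.seed, "monitors")
    n = config.n_monitors
    n_urban = int(round(config.urban_site_fraction * n))
    lons = np.empty(n)
    lats = np.empty(n)
    p_city = city_w / city_w.sum()
    which = rng.choice(len(city_lon), size=n_urban, p=p_city)
    lons[:n_urban] = city_lon[which] + rng.normal(0.0, 20.0 / km_per_deg_lon, n_urban)
    lats[:n_urban] = city_lat[which] + rng.normal(0.0, 20.0 / km_per_deg_lat, n_urban)
    lons[n_urban:] = rng.uniform(lon_min, lon_max, n - n_urban)
    lats[n_urban:] = rng.uniform(lat_min, lat_max, n - n_urban)
    lons = np.clip(lons, lon_min, lon_max)
    lats = np.clip(lats, lat_min, lat_max)

    one_in_three = rng.random(n) < config.every_third_day_fraction
    offset = rng.integers(0, 3, n)
    # monitors come and go: a share runs all year, the rest over a window,
    # mirroring real networks where density is far below a full panel
    full_span = rng.random(n) < 0.30
    dur = rng.integers(60, 241, n)
    start = np.array([rng.integers(0, max(1, config.n_days - d)) for d in dur])
    start = np.where(full_span, 0, start)
    end = np.where(full_span, config.n_days - 1, np.minimum(start + dur, config.n_days - 1))

    monitors = pd.DataFrame(
        {
            "monitor_id": [f"M{i:04d}" for i in range(n)],
            "lon": lons,
            "lat": lats,
            "state": state_of(lons, lats),
            "schedule": np.where(one_in_three, "1in3", "daily"),
            "source": np.where(one_in_three, SOURCE_1IN3, SOURCE_DAILY),
            "start_day": start,
            "end_day": end,
            "offset": offset,
        }
    )

    n_mob = config.n_mobile_fire_monitors if len(fires) else 0
    if n_mob:
        fidx = rng.integers(0, len(fires), n_mob)
        mlon = np.clip(
            fires["lon"].to_numpy()[fidx] + rng.normal(0, 15.0 / km_per_deg_lon, n_mob),
            lon_min, lon_max,
        )
        mlat = np.clip(
            fires["lat"].to_numpy()[fidx] + rng.normal(0, 15.0 / km_per_deg_lat, n_mob),
            lat_min, lat_max,
        )
        mobile = pd.DataFrame(
            {
                "monitor_id": [f"F{i:04d}" for i in range(n_mob)],
                "lon": mlon,
                "lat": mlat,
                "state": state_of(mlon, mlat),
                "schedule": "mobile",
                "source": SOURCE_MOBILE,
                "start_day": 0,
                "end_day": config.n_days - 1,
                "offset": 0,
            }
        )
        monitors = pd.concat([monitors, mobile], ignore_index=True)
    return monitors


def _make_centroids(config, city_lon, city_lat, state_of, bbox,
                    km_per_deg_lon, km_per_deg_lat):
    lon_min, lon_max, lat_min, lat_max = bbox
    rng = _rng(config.seed, "centroids")

    def scatter(n, near_city_frac, sd_km):
        n_c = int(round(near_city_frac * n))
        which = rng.integers(0, len(city_lon), n_c)
        lon = np.concatenate(
            [
                city_lon[which] + rng.normal(0, sd_km / km_per_deg_lon, n_c),
                rng.uniform(lon_min, lon_max, n - n_c),
            ]
        )
        lat = np.concatenate(
            [
                city_lat[which] + rng.normal(0, sd_km / km_per_deg_lat, n_c),
                rng.uniform(lat_min, lat_max, n - n_c),
            ]
        )
        return np.clip(lon, lon_min, lon_max), np.clip(lat, lat_min, lat_max)

    frames = []
    c_lon, c_lat = scatter(18, 0.3, 60.0)
    frames.append(
        pd.DataFrame(
            {
                "level": "county",
                "county_fips": [f"{53001 + i:05d}" for i in range(18)],
                "tract_code": "",
                "zcta5_code": "",
                "lon": c_lon,
                "lat": c_lat,
            }
        )
    )
    z_lon, z_lat = scatter(45, 0.55, 35.0)
    frames.append(
        pd.DataFrame(
            {
                "level": "zip",
                "county_fips": "",
                "tract_code": "",
                "zcta5_code": [f"{84001 + i:05d}" for i in range(45)],
                "lon": z_lon,
                "lat": z_lat,
            }
        )
    )
    t_lon, t_lat = scatter(110, 0.65, 25.0)
    county_of = [f"{53001 + i % 18:05d}" for i in range(110)]
    frames.append(
        pd.DataFrame(
            {
                "level": "tract",
                "county_fips": county_of,
                "tract_code": [f"{county_of[i]}{i:06d}" for i in range(110)],
                "zcta5_code": "",
                "lon": t_lon,
                "lat": t_lat,
            }
        )
    )
    cent = pd.concat(frames, ignore_index=True)
    cent["state"] = state_of(cent["lon"].to_numpy(), cent["lat"].to_numpy())
    return cent


def sample_observations(world: World) -> pd.DataFrame:
    """Draw the raw multi-source observation table from the world.

    Stationary monitors report truth at their site times multiplicative
    lognormal noise on their schedule (daily or 1-in-3-day) within their
    operational window; mobile fire monitors report only on days when an
    active fire is within 100 km; a ``duplicate_fraction`` share of records is
    re-emitted verbatim under a second source label; and
    ``extreme_injection_count`` records are overwritten with implausible
    values above 850 µg/m³ (the QC stage is expected to remove them).
    """
    config = world.config
    rng = _rng(config.seed, "observations")
    n_days = config.n_days
    mon = world.monitors

    rows_mon = []
    rows_day = []
    for i, m in enumerate(mon.itertuples()):
        if m.schedule == "mobile":
            continue
        step = 3 if m.schedule == "1in3" else 1
        first = int(m.start_day) + (int(m.offset) % step if step > 1 else 0)
        days = np.arange(first, int(m.end_day) + 1, step)
        rows_mon.append(np.full(days.size, i))
        rows_day.append(days)

    # mobile monitors: active only within 100 km of a same-day fire
    if len(world.fires):
        fire_lon = world.fires["lon"].to_numpy()
        fire_lat = world.fires["lat"].to_numpy()
        fire_day = world.fires["day_idx"].to_numpy()
        for i, m in enumerate(mon.itertuples()):
            if m.schedule != "mobile":
                continue
            d = haversine_km(m.lon, m.lat, fire_lon, fire_lat)
            active = np.unique(fire_day[d <= 100.0])
            active = active[(active >= 0) & (active < n_days)]
            if active.size:
                rows_mon.append(np.full(active.size, i))
                rows_day.append(active)

    mon_idx = np.concatenate(rows_mon) if rows_mon else np.array([], dtype=int)
    day_idx = np.concatenate(rows_day) if rows_day else np.array([], dtype=int)
    lons = mon["lon"].to_numpy()[mon_idx]
    lats = mon["lat"].to_numpy()[mon_idx]
    truth_mat = world._truth_matrix(mon["lon"].to_numpy(), mon["lat"].to_numpy())
    truth = truth_mat[mon_idx, day_idx]
    noise = np.exp(rng.normal(0.0, config.obs_noise_sd, truth.size)) if config.obs_noise_sd > 0 else 1.0
    pm25 = truth * noise

    obs = pd.DataFrame(
        {
            "monitor_id": mon["monitor_id"].to_numpy()[mon_idx],
            "source": mon["source"].to_numpy()[mon_idx],
            "lon": lons,
            "lat": lats,
            "state": mon["state"].to_numpy()[mon_idx],
            "date": world.dates[0] + pd.to_timedelta(day_idx, unit="D"),
            "pm25": pm25,
        }
    )

    n_extreme = min(config.extreme_injection_count, len(obs))
    if n_extreme:
        pick = rng.choice(len(obs), size=n_extreme, replace=False)
        obs.loc[obs.index[pick], "pm25"] = rng.uniform(900.0, 3000.0, n_extreme)

    n_dup = int(np.floor(config.duplicate_fraction * len(obs)))
    if n_dup:
        pick = rng.choice(len(obs), size=n_dup, replace=False)
        dup = obs.iloc[np.sort(pick)].copy()
        dup["source"] = np.where(dup["source"] == SOURCE_DUPLICATE, SOURCE_DAILY, SOURCE_DUPLICATE)
        obs = pd.concat([obs, dup], ignore_index=True)
    return obs


#: Per-source raw column layouts, emulating heterogeneous upstream files.
SOURCE_SCHEMAS: dict[str, dict[str, str]] = {
    SOURCE_DAILY: {
        "monitor_id": "site_id",
        "lon": "longitude",
        "lat": "latitude",
        "state": "state_name",
        "date": "date_local",
        "pm25": "sample_value",
    },
    SOURCE_1IN3: {
        "monitor_id": "SiteCode",
        "lon": "Lon",
        "lat": "Lat",
        "state": "State",
        "date": "ObsDate",
        "pm25": "PM25_ugm3",
    },
    SOURCE_MOBILE: {
        "monitor_id": "unit",
        "lon": "lng",
        "lat": "lat",
        "state": "st",
        "date": "day",
        "pm25": "conc",
    },
    SOURCE_DUPLICATE: {
        "monitor_id": "station",
        "lon": "x_lon",
        "lat": "y_lat",
        "state": "state",
        "date": "sample_date",
        "pm25": "value",
    },
}


def raw_source_tables(observations: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a canonical observation table into per-source raw tables.

    Each table gets that source's raw column names (see ``SOURCE_SCHEMAS``)
    and ISO-8601 date strings, emulating what source harmonization ingests.
    """
    out = {}
    for source, sub in observations.groupby("source", sort=True):
        schema = SOURCE_SCHEMAS.get(source, {c: c for c in sub.columns})
        tab = sub.drop(columns=["source"]).copy()
        tab["date"] = pd.to_datetime(tab["date"]).dt.strftime("%Y-%m-%d")
        out[source] = tab.rename(columns=schema).reset_index(drop=True)
    return out
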