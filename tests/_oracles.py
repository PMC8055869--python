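"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive — O(N·M) scans, explicit loops,
spherical-law-of-cosines distances — so that agreement with the package's
vectorized implementations is meaningful.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088


def slc_distance_km(lon1, lat1, lon2, lat2) -> float:
    """Spherical law of cosines great-circle distance (scalar)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    c = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl)
    return EARTH_RADIUS_KM * np.arccos(np.clip(c, -1.0, 1.0))


def fire_idw_brute(lon, lat, date, fires, radii=(25.0, 50.0, 100.0, 500.0), n_lags=8):
    """All-pairs fire IDW features for one point/day."""
    date = pd.Timestamp(date)
    out = {}
    any500 = 0.0
    w = [1.0 / r for r in radii]
    for lag in range(n_lags):
        day = date - pd.Timedelta(days=lag)
        counts = []
        for r in radii:
            c = 0
            for f in fires.itertuples():
                if pd.Timestamp(f.date) != day:
                    continue
                if slc_distance_km(lon, lat, f.lon, f.lat) <= r:
                    c += 1
            counts.append(c)
        out[f"fire_idw_lag{lag}"] = sum(c * wi for c, wi in zip(counts, w)) / sum(w)
        if counts[-1] >= 1:
            any500 = 1.0
    out["fire_within_500km_week"] = any500
    return out


def buffer_fraction_brute(raster, lon, lat, radius_km, positive_codes) -> float:
    """Exhaustive cell enumeration of an urban buffer fraction."""
    n_in = n_pos = 0
    best, best_pos = np.inf, 0
    for iy, la in enumerate(raster.lat):
        for ix, lo in enumerate(raster.lon):
            d = slc_distance_km(lon, lat, lo, la)
            code = raster.values[iy, ix]
            pos = int(code in positive_codes)
            if d < best:
                best, best_pos = d, pos
            if d <= radius_km:
                n_in += 1
                n_pos += pos
    if n_in == 0:
        return float(best_pos)
    return n_pos / n_in


def road_length_brute(roads, lon, lat, radius_m, step_m=1.0) -> float:
    """Fine (1-m) densification road-length oracle, km.

    Independent of the implementation under test: law-of-cosines distances and
    per-segment fine densification (vectorized only for speed).
    """
    total = 0.0
    sub = roads[roads["road_class"].isin(("arterial", "collector"))]
    for _, grp in sub.groupby("road_id"):
        grp = grp.sort_values("seq")
        xs, ys = grp["lon"].to_numpy(), grp["lat"].to_numpy()
        for i in range(len(xs) - 1):
            seg_km = slc_distance_km(xs[i], ys[i], xs[i + 1], ys[i + 1])
            if seg_km == 0:
                continue
            # cheap reject: segment entirely beyond radius + segment length
            if slc_distance_km(lon, lat, xs[i], ys[i]) > radius_m / 1000.0 + seg_km:
                continue
            n = max(1, int(np.ceil(seg_km * 1000.0 / step_m)))
            t = (np.arange(n) + 0.5) / n
            mx = xs[i] + t * (xs[i + 1] - xs[i])
            my = ys[i] + t * (ys[i + 1] - ys[i])
            d = slc_distance_km(lon, lat, mx, my)
            total += seg_km / n * int((d <= radius_m / 1000.0).sum())
    return total


def nearest_scan(t_lon, t_lat, s_lon, s_lat):
    """O(N·M) nearest-source scan; returns (index, distance_km) per target."""
    idx, dist = [], []
    for lo, la in zip(np.atleast_1d(t_lon), np.atleast_1d(t_lat)):
        best_i, best_d = -1, np.inf
        for i, (slo, sla) in enumerate(zip(s_lon, s_lat)):
            d = slc_distance_km(lo, la, slo, sla)
            if d < best_d - 1e-12:
                best_i, best_d = i, d
        idx.append(best_i)
        dist.append(best_d)
    return np.array(idx), np.array(dist)


def ols_coefficients(a, b, y):
    """Normal-equations solution of y ~ 1 + a + b."""
    X = np.column_stack([np.ones_like(a), a, b])
    return np.linalg.solve(X.T @ X, X.T @ y)


def rmse(pred, obs) -> float:
    return float(np.sqrt(np.mean((np.asarray(pred) - np.asarray(obs)) ** 2)))
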