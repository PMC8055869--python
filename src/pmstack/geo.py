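"""Geodesic primitives shared across the package.

All coordinates are WGS84 decimal degrees; all distances are great-circle
(haversine) kilometres.  Gridded layers live on regular lon/lat grids and are
linked to points by nearest cell centre, which is the linkage rule used
throughout the pipeline (no reprojection step anywhere).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance between points, in km.

    Accepts scalars or broadcastable arrays.  Latitudes outside [-90, 90]
    are rejected; the distance is symmetric and zero iff the points agree.
    """
    lon1, lat1, lon2, lat2 = (np.asarray(x, dtype=float) for x in (lon1, lat1, lon2, lat2))
    for name, lat in (("lat1", lat1), ("lat2", lat2)):
        if not np.all(np.isfinite(lat)) or np.any(np.abs(lat) > 90.0):
            raise ValueError(f"{name} must be finite and within [-90, 90]")
    if not (np.all(np.isfinite(lon1)) and np.all(np.isfinite(lon2))):
        raise ValueError("longitudes must be finite")
    rlon1, rlat1, rlon2, rlat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = rlat2 - rlat1
    dlon = rlon2 - rlon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(rlat1) * np.cos(rlat2) * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(a))


@dataclass
class Grid:
    """A regular lon/lat raster.

    ``values`` has shape ``(..., n_lat, n_lon)``; leading axes hold layers
    (e.g. months) or time.  ``lon``/``lat`` are 1-D cell-centre coordinates in
    ascending order.
    """

    lon: np.ndarray
    lat: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if self.values.shape[-2:] != (self.lat.size, self.lon.size):
            raise ValueError("values trailing shape must be (n_lat, n_lon)")

    @property
    def n_lat(self) -> int:
        return self.lat.size

    @property
    def n_lon(self) -> int:
        return self.lon.size

    def nearest_cell(self, lons, lats):
        """Indices ``(iy, ix)`` of the cell centre nearest each point.

        The grid is separable in lon and lat, so the nearest centre can be
        found per axis; ties go to the lower index.
        """
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        ix = np.abs(lons[:, None] - self.lon[None, :]).argmin(axis=1)
        iy = np.abs(lats[:, None] - self.lat[None, :]).argmin(axis=1)
        return iy, ix

    def at(self, lons, lats):
        """Value(s) at the nearest cell centre for each point."""
        iy, ix = self.nearest_cell(lons, lats)
        return self.values[..., iy, ix]

    def mesh(self):
        """Dense 2-D arrays of cell-centre lon and lat, shape (n_lat, n_lon)."""
        return np.meshgrid(self.lon, self.lat)
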