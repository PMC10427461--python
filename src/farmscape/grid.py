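"""Regular lat/lon grids and spherical geodesy.

All distances are great-circle distances on a sphere of radius 6,371 km
(the conventional mean Earth radius used with the haversine formula).
Cell membership follows a half-open convention: a point belongs to the
cell whose interval is [west, east) x [south, north), so points exactly
on an eastern or northern boundary fall in the next cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridSpec:
    """A regular latitude/longitude grid.

    Parameters
    ----------
    n_lat, n_lon
        Number of rows (latitude) and columns (longitude).
    lat_min, lat_max, lon_min, lon_max
        Outer bounds of the grid in degrees. Row 0 is the southernmost
        row; column 0 is the westernmost column.
    """

    n_lat: int
    n_lon: int
    lat_min: float = -90.0
    lat_max: float = 90.0
    lon_min: float = -180.0
    lon_max: float = 180.0

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid dimensions must be positive")
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ValueError("grid bounds must be non-degenerate")

    @property
    def dlat(self) -> float:
        return (self.lat_max - self.lat_min) / self.n_lat

    @property
    def dlon(self) -> float:
        return (self.lon_max - self.lon_min) / self.n_lon

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.dlat

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.dlon

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    def cell_of(self, lat, lon):
        """Row/column indices of the cells containing the given points.

        Half-open membership: [west, east) x [south, north). Points outside
        the grid get index -1 in the offending dimension.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        i = np.floor((lat - self.lat_min) / self.dlat).astype(int)
        j = np.floor((lon - self.lon_min) / self.dlon).astype(int)
        i = np.where((lat >= self.lat_min) & (lat < self.lat_max), i, -1)
        j = np.where((lon >= self.lon_min) & (lon < self.lon_max), j, -1)
        return i, j

    def contains(self, lat, lon) -> np.ndarray:
        i, j = self.cell_of(lat, lon)
        return (np.asarray(i) >= 0) & (np.asarray(j) >= 0)

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) cell-center arrays, each of shape (n_lat, n_lon)."""
        return np.meshgrid(self.lat_centers, self.lon_centers, indexing="ij")


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points, broadcasting like numpy.

    Spherical Earth, radius 6,371 km. Symmetric; zero iff the points
    coincide (up to floating error).
    """
    lat1, lon1, lat2, lon2 = (np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2))
    for la in (lat1, lat2):
        if np.any(np.abs(la) > 90.0):
            raise ValueError("latitude outside [-90, 90]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def pairwise_haversine_km(lat, lon) -> np.ndarray:
    """Full n x n great-circle distance matrix for a set of points."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    return haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
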