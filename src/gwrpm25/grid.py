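"""Grid geometry and great-circle distance utilities shared by all stages.

Grids are cell-registered regular lon/lat rasters: the origin is the lower-left
corner of the bounding box, axes are in degrees, and a point belongs to the
half-open cell ``[edge, next_edge)``.  Arrays are indexed ``[lat, lon]`` with
latitude increasing along axis 0.  All physical distances are great-circle
(haversine) distances in km on a sphere of radius 6371 km.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0  # ~111.19 km per degree of arc


@dataclass(frozen=True)
class GridSpec:
    """Definition of a regular cell-registered lon/lat grid."""

    lon_min: float
    lat_min: float
    dlon: float
    dlat: float
    nlon: int
    nlat: int

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.nlon * self.dlon

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.nlat * self.dlat

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.nlon) + 0.5) * self.dlon

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.nlat) + 0.5) * self.dlat

    @property
    def res_km(self) -> float:
        """Nominal spacing in km (mean of meridional and zonal spacing)."""
        mid = 0.5 * (self.lat_min + self.lat_max)
        return 0.5 * (
            self.dlat * KM_PER_DEG + self.dlon * KM_PER_DEG * np.cos(np.radians(mid))
        )

    @classmethod
    def from_bbox_res(cls, bbox: tuple[float, float, float, float], res_km: float) -> "GridSpec":
        """Build a grid covering ``bbox = (lon_min, lon_max, lat_min, lat_max)``.

        Spacings are stretched slightly so an integer number of cells covers
        the box exactly; the target spacing is ``res_km``.
        """
        lon_min, lon_max, lat_min, lat_max = bbox
        if not (lon_max > lon_min and lat_max > lat_min):
            raise ValueError(f"degenerate bbox {bbox}")
        if res_km <= 0:
            raise ValueError("res_km must be positive")
        mid = 0.5 * (lat_min + lat_max)
        dlat_t = res_km / KM_PER_DEG
        dlon_t = res_km / (KM_PER_DEG * np.cos(np.radians(mid)))
        nlat = max(1, round((lat_max - lat_min) / dlat_t))
        nlon = max(1, round((lon_max - lon_min) / dlon_t))
        return cls(
            lon_min=lon_min,
            lat_min=lat_min,
            dlon=(lon_max - lon_min) / nlon,
            dlat=(lat_max - lat_min) / nlat,
            nlon=nlon,
            nlat=nlat,
        )

    def cell_of(self, lon, lat):
        """Return (row, col) of the half-open cell containing each point.

        Points outside the grid extent get index -1 in both coordinates.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.dlon).astype(int)
        row = np.floor((lat - self.lat_min) / self.dlat).astype(int)
        bad = (col < 0) | (col >= self.nlon) | (row < 0) | (row >= self.nlat)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def contains(self, lon, lat):
        row, _ = self.cell_of(lon, lat)
        return np.asarray(row) >= 0

    def mesh_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """2-D arrays of cell-center longitudes and latitudes, shape (nlat, nlon)."""
        return np.meshgrid(self.lon_centers, self.lat_centers)

    def same_geometry(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.nlon == other.nlon
            and self.nlat == other.nlat
            and abs(self.lon_min - other.lon_min) < tol
            and abs(self.lat_min - other.lat_min) < tol
            and abs(self.dlon - other.dlon) < tol
            and abs(self.dlat - other.dlat) < tol
        )


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_distances_km(lon_a, lat_a, lon_b, lat_b) -> np.ndarray:
    """Matrix of great-circle distances, shape (len(a), len(b))."""
    lon_a = np.asarray(lon_a, dtype=float)[:, None]
    lat_a = np.asarray(lat_a, dtype=float)[:, None]
    lon_b = np.asarray(lon_b, dtype=float)[None, :]
    lat_b = np.asarray(lat_b, dtype=float)[None, :]
    return haversine_km(lon_a, lat_a, lon_b, lat_b)


def local_xy_km(lon, lat, lat_ref: float) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection to km, used only for fast neighbour lookup.

    Exact distances are always recomputed with :func:`haversine_km`; this
    projection only has to preserve neighbour ordering approximately.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = lon * KM_PER_DEG * np.cos(np.radians(lat_ref))
    y = lat * KM_PER_DEG
    return x, y
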