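"""Geodesic distances and square spatial-block tiling.

Distances between records (thinning, pseudo-absence exclusion disks) use the
exact haversine great-circle formula on a sphere of radius 6371.0 km.  Block
tilings for spatial cross-validation live in a local equirectangular
projection anchored at a reference latitude, which keeps blocks metrically
close to square over a mid-latitude study extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0  # ~111.195 km per degree of arc

__all__ = ["PointLL", "BlockTiling", "haversine_km", "pairwise_haversine_km", "EARTH_RADIUS_KM", "KM_PER_DEG"]


@dataclass(frozen=True)
class PointLL:
    """A WGS84 point in decimal degrees."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lon) and np.isfinite(self.lat)):
            raise ValueError("coordinates must be finite")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of [-90, 90]")


def haversine_km(a, b) -> float | np.ndarray:
    """Great-circle distance in kilometres.

    Accepts PointLL instances or (lon, lat) array-likes; broadcasts over
    arrays of shape (..., 2).
    """
    lon1, lat1 = _lonlat(a)
    lon2, lat2 = _lonlat(b)
    if not (np.all(np.isfinite(lon1)) and np.all(np.isfinite(lat1))
            and np.all(np.isfinite(lon2)) and np.all(np.isfinite(lat2))):
        raise ValueError("non-finite coordinates")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    if np.isscalar(d) or d.shape == ():
        return float(d)
    return d


def pairwise_haversine_km(points: np.ndarray) -> np.ndarray:
    """Full n x n haversine distance matrix for an (n, 2) lon/lat array."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    lon = np.radians(pts[:, 0])
    lat = np.radians(pts[:, 1])
    dphi = lat[:, None] - lat[None, :]
    dlmb = lon[:, None] - lon[None, :]
    h = np.sin(dphi / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _lonlat(p):
    if isinstance(p, PointLL):
        return p.lon, p.lat
    arr = np.asarray(p, dtype=float)
    return arr[..., 0], arr[..., 1]


@dataclass(frozen=True)
class BlockTiling:
    """Square block tiling in a local equirectangular projection.

    x = (lon - lon0) * 111.195 * cos(lat_ref), y = (lat - lat0) * 111.195;
    block index = (floor(x / block_km), floor(y / block_km)).  The floor
    convention makes cells half-open, so a point exactly on a block edge
    belongs to the higher-index block.
    """

    origin: PointLL
    block_km: float
    lat_ref: float

    def __post_init__(self) -> None:
        if not self.block_km > 0:
            raise ValueError("block_km must be > 0")

    @classmethod
    def for_points(cls, points: np.ndarray, block_km: float) -> "BlockTiling":
        """Tiling anchored at the point cloud's south-west corner with
        lat_ref = mid-latitude of the cloud."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        origin = PointLL(float(pts[:, 0].min()), float(pts[:, 1].min()))
        lat_ref = float((pts[:, 1].min() + pts[:, 1].max()) / 2.0)
        return cls(origin=origin, block_km=block_km, lat_ref=lat_ref)

    def block_index(self, points) -> np.ndarray:
        """(n, 2) integer array of (i, j) block coordinates."""
        pts = np.asarray(
            [[p.lon, p.lat] for p in points] if _is_pointll_seq(points) else points,
            dtype=float,
        ).reshape(-1, 2)
        x = (pts[:, 0] - self.origin.lon) * KM_PER_DEG * np.cos(np.radians(self.lat_ref))
        y = (pts[:, 1] - self.origin.lat) * KM_PER_DEG
        i = np.floor(x / self.block_km).astype(int)
        j = np.floor(y / self.block_km).astype(int)
        return np.column_stack([i, j])


def _is_pointll_seq(points) -> bool:
    return hasattr(points, "__len__") and len(points) > 0 and isinstance(points[0], PointLL)
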