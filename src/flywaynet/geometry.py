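"""Spherical geometry primitives.

All distances are great-circle (haversine) on a sphere of radius 6371 km.
The thresholds used downstream (250 km merge radius, 700 km cluster
diameter) are far coarser than the <0.5% error an ellipsoid would remove,
so a sphere is used throughout. Angles follow the navigation convention:
bearings clockwise from north in [0, 360).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "EarthModel",
    "great_circle_km",
    "pairwise_great_circle_km",
    "initial_bearing_deg",
    "turning_angle_deg",
    "mean_location",
]

EARTH_RADIUS_KM = 6371.0


def _normalize_lon(lon_deg: float) -> float:
    """Wrap longitude into (-180, 180]."""
    lon = math.fmod(lon_deg, 360.0)
    if lon <= -180.0:
        lon += 360.0
    elif lon > 180.0:
        lon -= 360.0
    return lon


@dataclass(frozen=True)
class GeoPoint:
    """A location in decimal degrees, longitude normalized to (-180, 180]."""

    lat_deg: float
    lon_deg: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat_deg <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat_deg}")
        if not math.isfinite(self.lon_deg):
            raise ValueError(f"longitude not finite: {self.lon_deg}")
        object.__setattr__(self, "lon_deg", _normalize_lon(self.lon_deg))


@dataclass(frozen=True)
class EarthModel:
    radius_km: float = EARTH_RADIUS_KM

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ValueError("radius_km must be positive")


DEFAULT_EARTH = EarthModel()


def great_circle_km(a: GeoPoint, b: GeoPoint, earth: EarthModel = DEFAULT_EARTH) -> float:
    """Haversine great-circle distance in kilometers."""
    la1, lo1 = math.radians(a.lat_deg), math.radians(a.lon_deg)
    la2, lo2 = math.radians(b.lat_deg), math.radians(b.lon_deg)
    h = (
        math.sin((la2 - la1) / 2.0) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2.0) ** 2
    )
    return 2.0 * earth.radius_km * math.asin(min(1.0, math.sqrt(h)))


def pairwise_great_circle_km(
    lat_deg: np.ndarray, lon_deg: np.ndarray, earth: EarthModel = DEFAULT_EARTH
) -> np.ndarray:
    """Full n x n haversine distance matrix for coordinate arrays (degrees)."""
    la = np.radians(np.asarray(lat_deg, dtype=float))
    lo = np.radians(np.asarray(lon_deg, dtype=float))
    dla = la[:, None] - la[None, :]
    dlo = lo[:, None] - lo[None, :]
    h = np.sin(dla / 2.0) ** 2 + np.cos(la)[:, None] * np.cos(la)[None, :] * np.sin(dlo / 2.0) ** 2
    return 2.0 * earth.radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def initial_bearing_deg(a: GeoPoint, b: GeoPoint) -> float:
    """Initial great-circle bearing from a to b, degrees in [0, 360), 0 = north.

    Raises ValueError for coincident points, where the bearing is undefined.
    """
    if a.lat_deg == b.lat_deg and a.lon_deg == b.lon_deg:
        raise ValueError("bearing undefined for coincident points")
    la1, la2 = math.radians(a.lat_deg), math.radians(b.lat_deg)
    dlo = math.radians(b.lon_deg - a.lon_deg)
    y = math.sin(dlo) * math.cos(la2)
    x = math.cos(la1) * math.sin(la2) - math.sin(la1) * math.cos(la2) * math.cos(dlo)
    return math.degrees(math.atan2(y, x)) % 360.0


def turning_angle_deg(prev: GeoPoint, vertex: GeoPoint, next_: GeoPoint) -> float:
    """Interior angle at `vertex` between the directions to its neighbors.

    180 degrees means the vertex lies straight between its neighbors;
    0 degrees means an exact out-and-back reversal. Raises ValueError if
    the vertex coincides with either neighbor.
    """
    b_prev = initial_bearing_deg(vertex, prev)
    b_next = initial_bearing_deg(vertex, next_)
    diff = abs(b_prev - b_next) % 360.0
    if diff > 180.0:
        diff = 360.0 - diff
    return diff


def mean_location(
    points: Sequence[GeoPoint], weights: Sequence[float] | None = None
) -> GeoPoint:
    """Spherical centroid: normalized mean of unit vectors, projected back.

    Robust across the antimeridian (the flyway spans 180 degrees longitude,
    so naive longitude averaging is wrong). Raises ValueError on empty
    input, non-positive total weight, or a degenerate (antipodal) mean.
    """
    if len(points) == 0:
        raise ValueError("mean_location of empty sequence")
    la = np.radians([p.lat_deg for p in points])
    lo = np.radians([p.lon_deg for p in points])
    xyz = np.stack(
        [np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)], axis=1
    )
    if weights is None:
        w = np.ones(len(points))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(points):
            raise ValueError("weights length mismatch")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative and not all zero")
    v = (xyz * w[:, None]).sum(axis=0) / w.sum()
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ValueError("mean vector degenerate (antipodal inputs)")
    v = v / norm
    lat = math.degrees(math.asin(max(-1.0, min(1.0, v[2]))))
    lon = math.degrees(math.atan2(v[1], v[0]))
    return GeoPoint(lat, lon)
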