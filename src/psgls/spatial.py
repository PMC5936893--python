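"""Great-circle distances and the spatial similarity matrix W.

Pairwise distances between sample locations (capital cities in the
motivating application) come from the haversine formula on a sphere of
radius 6371 km.  Raw distances cannot act as a covariance (zero diagonal,
growing with separation), so they are mapped to a unit-diagonal similarity
matrix; the default is the linear decay w = 1 - d / d_max, with an
exponential kernel exp(-d / rho) available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeoPoints",
    "SpatialSimilarity",
    "distance_matrix",
    "haversine_distance",
    "spatial_similarity",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class GeoPoints:
    """Ordered taxa with one (lat, lon) decimal-degree pair each."""

    taxa: list[str]
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if not (len(self.taxa) == self.lat.size == self.lon.size):
            raise ValueError("taxa, lat and lon must have equal length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in coordinate table")
        _check_bounds(self.lat, self.lon)


@dataclass
class SpatialSimilarity:
    """Unit-diagonal similarity matrix derived from pairwise distances."""

    taxa: list[str]
    w: np.ndarray
    d_max: float


def _check_bounds(lat: np.ndarray, lon: np.ndarray) -> None:
    if np.any((lat < -90.0) | (lat > 90.0)):
        raise ValueError("latitude out of [-90, 90]")
    if np.any((lon <= -180.0) | (lon > 180.0)):
        raise ValueError("longitude out of (-180, 180]")


def haversine_distance(
    p1: tuple[float, float],
    p2: tuple[float, float],
    radius: float = EARTH_RADIUS_KM,
) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    lat1, lon1 = (np.asarray(x, dtype=float) for x in p1)
    lat2, lon2 = (np.asarray(x, dtype=float) for x in p2)
    _check_bounds(np.atleast_1d(lat1), np.atleast_1d(lon1))
    _check_bounds(np.atleast_1d(lat2), np.atleast_1d(lon2))
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def distance_matrix(points: GeoPoints, radius: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Symmetric zero-diagonal matrix of pairwise haversine distances (km)."""
    if len(points.taxa) < 2:
        raise ValueError("need at least 2 points")
    phi = np.radians(points.lat)
    lam = np.radians(points.lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (
        np.sin(dphi / 2.0) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    )
    d = 2.0 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)


def spatial_similarity(
    d: np.ndarray,
    taxa: list[str] | None = None,
    transform: str = "linear",
    rho: float | None = None,
) -> SpatialSimilarity:
    """Map a distance matrix to the unit-diagonal similarity W.

    linear (default): w = 1 - d / d_max, so the maximally distant pair has
    similarity 0.  exponential: w = exp(-d / rho) with rho defaulting to
    d_max / 3.  d_max is always taken from the supplied matrix.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    d_max = float(d.max())
    if d_max <= 0.0:
        raise ValueError("all-zero distance matrix: similarity undefined")
    if taxa is None:
        taxa = [f"p{i}" for i in range(n)]
    if transform == "linear":
        w = 1.0 - d / d_max
    elif transform == "exponential":
        rho = d_max / 3.0 if rho is None else float(rho)
        if rho <= 0:
            raise ValueError("rho must be positive")
        w = np.exp(-d / rho)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    np.fill_diagonal(w, 1.0)
    return SpatialSimilarity(taxa=list(taxa), w=0.5 * (w + w.T), d_max=d_max)
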