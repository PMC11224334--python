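"""Shared numerical helpers: map projection, spatial correlation, truncated normals."""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

EARTH_RADIUS_KM = 6371.0


def laea_project(lon, lat, lon0: float, lat0: float, radius: float = EARTH_RADIUS_KM):
    """Lambert azimuthal equal-area projection (spherical) to km.

    Parameters
    ----------
    lon, lat : array-like, decimal degrees
    lon0, lat0 : projection centre, decimal degrees
    radius : sphere radius in km

    Returns
    -------
    (x, y) : ndarrays in km
    """
    lam = np.deg2rad(np.asarray(lon, dtype=float))
    phi = np.deg2rad(np.asarray(lat, dtype=float))
    lam0 = np.deg2rad(lon0)
    phi0 = np.deg2rad(lat0)
    dlam = lam - lam0
    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
    # antipodal point maps to infinity; guard for safety on odd inputs
    denom = np.maximum(denom, 1e-12)
    k = np.sqrt(2.0 / denom)
    x = radius * k * np.cos(phi) * np.sin(dlam)
    y = radius * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam))
    return x, y


def cell_areas_km2(lat, res_deg: float, radius: float = EARTH_RADIUS_KM):
    """Exact spherical area of res_deg x res_deg cells centred at latitudes `lat`."""
    lat = np.asarray(lat, dtype=float)
    half = res_deg / 2.0
    dlam = np.deg2rad(res_deg)
    return radius**2 * dlam * (np.sin(np.deg2rad(lat + half)) - np.sin(np.deg2rad(lat - half)))


def exp_corr(dist: np.ndarray, alpha: float) -> np.ndarray:
    """Exponential spatial correlation exp(-d / alpha); alpha in the units of d."""
    if alpha <= 0:
        return np.where(dist == 0.0, 1.0, 0.0)
    return np.exp(-dist / alpha)


def pairwise_dist(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Euclidean distance matrix between rows of a (n,2) and b (m,2)."""
    if b is None:
        b = a
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def truncnorm_draw(rng: np.random.Generator, mean: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Draw z ~ N(mean, 1) truncated to z > 0 where positive, z <= 0 elsewhere.

    Uses the inverse-CDF method, vectorised; stable for |mean| up to ~8.
    """
    mean = np.asarray(mean, dtype=float)
    u = rng.uniform(size=mean.shape)
    lo_cdf = ndtr(-mean)  # P(z <= 0)
    eps = 1e-12
    # positive branch: sample CDF value in (P(z<=0), 1); negative branch in (0, P(z<=0)]
    p = np.where(positive, lo_cdf + u * (1.0 - lo_cdf), u * lo_cdf)
    p = np.clip(p, eps, 1.0 - eps)
    return mean + ndtri(p)


def spawn_seed(rng: np.random.Generator) -> int:
    """Derive a child seed below 2**31 from an existing generator."""
    return int(rng.integers(0, 2**31 - 1))
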