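"""Regular lon/lat study grid with equal-area coordinates and shelf bathymetry.

The study domain mirrors a continental-shelf survey grid: 0.25-degree cells,
depths capped at 500 m (the haul-depth filter applied to the survey data), and
an equal-area Lambert azimuthal projection used for all distance/area metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import cell_areas_km2, laea_project


@dataclass
class SpatialGrid:
    """Regular lon/lat raster flattened row-major (south-to-north rows).

    Attributes
    ----------
    cell_id : int array, unique per cell
    lon, lat : cell-centre coordinates, decimal degrees
    x, y : equal-area (Lambert azimuthal) coordinates, km
    cell_area : km^2
    depth : positive-down bathymetry, m
    shape : (nlat, nlon) raster shape
    res : cell size in degrees
    """

    cell_id: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    x: np.ndarray
    y: np.ndarray
    cell_area: np.ndarray
    depth: np.ndarray
    shape: tuple[int, int]
    res: float
    lon0: float = field(default=0.0)
    lat0: float = field(default=0.0)

    def __post_init__(self):
        if len(np.unique(self.cell_id)) != self.cell_id.size:
            raise ValueError("cell_id must be unique")
        if np.any(self.cell_area <= 0):
            raise ValueError("cell_area must be positive")

    @property
    def n_cells(self) -> int:
        return self.cell_id.size

    @property
    def coords_km(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def raster(self, values: np.ndarray) -> np.ndarray:
        """Reshape a per-cell vector to the (nlat, nlon) raster."""
        return np.asarray(values).reshape(self.shape)

    def cell_at(self, lon, lat) -> np.ndarray:
        """Nearest-cell index for point coordinates; -1 if outside the grid."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        nlat, nlon = self.shape
        lon_min = self.lon.min() - self.res / 2
        lat_min = self.lat.min() - self.res / 2
        i = np.floor((lat - lat_min) / self.res).astype(int)
        j = np.floor((lon - lon_min) / self.res).astype(int)
        inside = (i >= 0) & (i < nlat) & (j >= 0) & (j < nlon)
        out = np.where(inside, i * nlon + j, -1)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "lon": self.lon,
                "lat": self.lat,
                "x": self.x,
                "y": self.y,
                "cell_area": self.cell_area,
                "depth": self.depth,
            }
        )


def make_grid(
    nlon: int = 24,
    nlat: int = 20,
    lon_min: float = 10.0,
    lat_min: float = 62.0,
    res: float = 0.25,
    max_depth: float = 500.0,
    seed: int = 0,
) -> SpatialGrid:
    """Build a rectangular shelf grid with smooth synthetic bathymetry.

    Depth deepens away from an undulating coastline and is clipped to
    (10, max_depth) m so every cell obeys the <= 500 m shelf constraint.
    """
    rng = np.random.default_rng(seed)
    lon_c = lon_min + res * (np.arange(nlon) + 0.5)
    lat_c = lat_min + res * (np.arange(nlat) + 0.5)
    lon2d, lat2d = np.meshgrid(lon_c, lat_c)  # (nlat, nlon)
    lon_f = lon2d.ravel()
    lat_f = lat2d.ravel()
    lon0 = float(lon_c.mean())
    lat0 = float(lat_c.mean())
    x, y = laea_project(lon_f, lat_f, lon0, lat0)

    # shelf sloping offshore (westwards) with gentle alongshore undulation
    span = max(lon_c.max() - lon_c.min(), 1e-6)
    t = (lon_c.max() - lon_f) / span
    depth = 30.0 + 420.0 * t + 40.0 * np.sin(2 * np.pi * (lat_f - lat_min) / 5.0)
    depth += rng.normal(0.0, 5.0, size=depth.shape)
    depth = np.clip(depth, 10.0, max_depth)

    return SpatialGrid(
        cell_id=np.arange(lon_f.size),
        lon=lon_f,
        lat=lat_f,
        x=x,
        y=y,
        cell_area=cell_areas_km2(lat_f, res),
        depth=depth,
        shape=(nlat, nlon),
        res=res,
        lon0=lon0,
        lat0=lat0,
    )
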