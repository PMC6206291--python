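"""Kernel-density occurrence surface on a regular lat/lon grid.

Quartic (biweight) kernel with planar degree coordinates:
``K(d) = 3/pi * (1 - (d/h)^2)^2`` for ``d < h``, zero beyond.  The surface
value at a cell centre is ``sum_points K(distance) / h^2``, so each point
contributes unit mass to the surface integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DensitySurface:
    grid: np.ndarray
    origin_lon: float
    origin_lat: float
    resolution: float
    bandwidth: float


def kernel_density(
    lats: np.ndarray,
    lons: np.ndarray,
    origin_lon: float,
    origin_lat: float,
    n_rows: int,
    n_cols: int,
    resolution: float,
    bandwidth: float,
) -> DensitySurface:
    """Evaluate the quartic-kernel density of a point set at every cell centre.

    ``bandwidth`` is in decimal degrees; distances are planar in degree space.
    Points outside the extent still contribute to cells within one bandwidth.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("grid dimensions must be positive")
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)

    surface = np.zeros((n_rows, n_cols))
    h2 = bandwidth**2
    half = resolution / 2.0
    reach = int(np.ceil(bandwidth / resolution)) + 1

    for lat, lon in zip(lats, lons):
        # fractional cell coordinates of the point
        fc = (lon - origin_lon) / resolution
        fr = (origin_lat - lat) / resolution
        r0 = max(0, int(np.floor(fr)) - reach)
        r1 = min(n_rows, int(np.ceil(fr)) + reach + 1)
        c0 = max(0, int(np.floor(fc)) - reach)
        c1 = min(n_cols, int(np.ceil(fc)) + reach + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rows = np.arange(r0, r1)
        cols = np.arange(c0, c1)
        cy = origin_lat - rows * resolution - half
        cx = origin_lon + cols * resolution + half
        d2 = (cy[:, None] - lat) ** 2 + (cx[None, :] - lon) ** 2
        t = 1.0 - d2 / h2
        np.clip(t, 0.0, None, out=t)
        surface[r0:r1, c0:c1] += (3.0 / np.pi) * t**2 / h2

    return DensitySurface(
        grid=surface,
        origin_lon=origin_lon,
        origin_lat=origin_lat,
        resolution=resolution,
        bandwidth=bandwidth,
    )


def density_from_points(
    points: pd.DataFrame,
    resolution: float,
    bandwidth: float,
    extent: tuple[float, float, float, float] | None = None,
    lat_col: str = "lat",
    lon_col: str = "lon",
) -> DensitySurface:
    """Density surface from a table of points, auto-sizing the extent.

    ``extent`` is (min_lon, min_lat, max_lon, max_lat); when None it is the
    point bounding box padded by one bandwidth.
    """
    lats = points[lat_col].to_numpy(dtype=float)
    lons = points[lon_col].to_numpy(dtype=float)
    if extent is None:
        if lats.size == 0:
            raise ValueError("cannot auto-size extent from an empty point set")
        extent = (
            lons.min() - bandwidth,
            lats.min() - bandwidth,
            lons.max() + bandwidth,
            lats.max() + bandwidth,
        )
    min_lon, min_lat, max_lon, max_lat = extent
    n_cols = max(1, int(np.ceil((max_lon - min_lon) / resolution)))
    n_rows = max(1, int(np.ceil((max_lat - min_lat) / resolution)))
    return kernel_density(
        lats, lons, min_lon, max_lat, n_rows, n_cols, resolution, bandwidth
    )
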