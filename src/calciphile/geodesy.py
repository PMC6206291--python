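"""Gazetteer geocoding and ellipsoidal distance.

The distance routine is the iterative Vincenty inverse solution on the WGS84
ellipsoid.  Near-antipodal pairs for which the iteration does not converge
raise :class:`VincentyConvergenceError` rather than returning an approximate
value.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._types import DistanceStats, GeoPoint

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563


class VincentyConvergenceError(RuntimeError):
    """The Vincenty inverse iteration failed to converge (near-antipodal pair)."""


def vincenty_distance(
    p1: GeoPoint,
    p2: GeoPoint,
    a: float = WGS84_A,
    f: float = WGS84_F,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> float:
    """Geodesic distance in metres between two points on an ellipsoid.

    Parameters
    ----------
    p1, p2
        Points in decimal degrees (WGS84 by default).
    a
        Equatorial radius in metres.
    f
        Flattening.
    tol
        Convergence threshold on the longitude-difference iterate, radians.
    max_iter
        Iteration cap; exceeding it raises :class:`VincentyConvergenceError`.
    """
    if p1.lat == p2.lat and p1.lon == p2.lon:
        return 0.0

    b = a * (1.0 - f)
    phi1, phi2 = math.radians(p1.lat), math.radians(p2.lat)
    L = math.radians(p2.lon - p1.lon)

    U1 = math.atan((1.0 - f) * math.tan(phi1))
    U2 = math.atan((1.0 - f) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.sqrt(
            (cosU2 * sin_lam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * cos_lam) ** 2
        )
        if sin_sigma == 0.0:
            return 0.0  # coincident on the auxiliary sphere
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        if cos2_alpha == 0.0:
            cos_2sigma_m = 0.0  # equatorial geodesic
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
        C = f / 16.0 * cos2_alpha * (4.0 + f * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * f * sin_alpha * (
            sigma
            + C
            * sin_sigma
            * (cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < tol:
            break
    else:
        raise VincentyConvergenceError(
            f"no convergence after {max_iter} iterations for {p1} -> {p2}"
        )

    u2 = cos2_alpha * (a**2 - b**2) / b**2
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos_2sigma_m
            + B
            / 4.0
            * (
                cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2)
                - B
                / 6.0
                * cos_2sigma_m
                * (-3.0 + 4.0 * sin_sigma**2)
                * (-3.0 + 4.0 * cos_2sigma_m**2)
            )
        )
    )
    return b * A * (sigma - delta_sigma)


def build_gazetteer(entries: pd.DataFrame) -> dict[str, GeoPoint]:
    """Turn a (label, lat, lon) table into a lookup map.

    Raises
    ------
    ValueError
        If the table contains duplicate labels (a configuration error: exact
        matching requires unique labels).
    """
    if entries["label"].duplicated().any():
        dups = entries.loc[entries["label"].duplicated(), "label"].unique()
        raise ValueError(f"duplicate gazetteer labels: {list(dups[:5])}")
    return {
        row.label: GeoPoint(lat=float(row.lat), lon=float(row.lon))
        for row in entries.itertuples()
    }


def geocode(location_text: str, gazetteer: Mapping[str, GeoPoint]) -> tuple[GeoPoint | None, bool]:
    """Resolve a text location by exact label match.

    Returns ``(point, True)`` on a match and ``(None, False)`` otherwise.
    """
    if not gazetteer:
        raise ValueError("gazetteer is empty")
    point = gazetteer.get(location_text)
    return (point, True) if point is not None else (None, False)


def geocode_table(specimens: pd.DataFrame, gazetteer_df: pd.DataFrame) -> pd.DataFrame:
    """Geocode every specimen; adds ``lat``, ``lon``, ``matched`` columns."""
    gaz = build_gazetteer(gazetteer_df)
    out = specimens.copy()
    lats, lons, matched = [], [], []
    for text in out["location_text"]:
        point, ok = geocode(text, gaz)
        matched.append(ok)
        lats.append(point.lat if ok else np.nan)
        lons.append(point.lon if ok else np.nan)
    out["lat"] = lats
    out["lon"] = lons
    out["matched"] = matched
    return out


def accuracy_stats(pairs: Iterable[tuple[GeoPoint, GeoPoint]]) -> DistanceStats:
    """Distance summary between geocoded and reference points.

    Mean, standard error (sd/sqrt(n), sample sd) and quartiles of the per-pair
    Vincenty distances, in kilometres.  Quartiles use linear interpolation
    between order statistics, the same rule as the per-taxon quartiles.
    """
    d_km = np.array([vincenty_distance(g, r) / 1000.0 for g, r in pairs])
    if d_km.size == 0:
        raise ValueError("accuracy_stats requires at least one pair")
    n = int(d_km.size)
    se = float(d_km.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    q1, med, q3 = np.quantile(d_km, [0.25, 0.5, 0.75])
    return DistanceStats(
        n=n,
        mean_km=float(d_km.mean()),
        se_km=se,
        q1_km=float(q1),
        median_km=float(med),
        q3_km=float(q3),
    )
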