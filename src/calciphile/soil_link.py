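"""Point-to-cell lookup, attribute join, and dataset cleaning.

Cells are half-open rectangles: a point on an interior boundary belongs to the
cell with the higher row/column index, so every point inside the extent maps
to exactly one cell.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ._types import EXCLUDED_SURFACE_CODES, NODATA, GeoPoint, SoilLandscape

#: Cleaning rules in the order their counts are ledgered; a record removed by
#: an earlier rule is not re-counted under a later one.
REMOVAL_REASONS = ("out_of_region", "excluded_surface", "missing_subsoil")

ATTRIBUTE_JOIN_COLUMNS = ["su_sym90", "t_ph_h2o", "s_ph_h2o", "t_caco3", "s_caco3"]


class DataIntegrityError(RuntimeError):
    """A mapping-unit id present in the raster has no attribute record."""


def locate_cell(p: GeoPoint, landscape: SoilLandscape) -> tuple[int, int] | None:
    """Grid indices of the cell containing ``p``, or None if out of extent.

    ``col = floor((lon - origin_lon) / resolution)``;
    ``row = floor((origin_lat - lat) / resolution)``.
    """
    col = math.floor((p.lon - landscape.origin_lon) / landscape.resolution)
    row = math.floor((landscape.origin_lat - p.lat) / landscape.resolution)
    if 0 <= row < landscape.n_rows and 0 <= col < landscape.n_cols:
        return row, col
    return None


def locate_cells(
    lats: np.ndarray, lons: np.ndarray, landscape: SoilLandscape
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`locate_cell`; returns (rows, cols, in_extent mask)."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    cols = np.floor((lons - landscape.origin_lon) / landscape.resolution).astype(int)
    rows = np.floor((landscape.origin_lat - lats) / landscape.resolution).astype(int)
    inside = (
        (rows >= 0)
        & (rows < landscape.n_rows)
        & (cols >= 0)
        & (cols < landscape.n_cols)
        & np.isfinite(lats)
        & np.isfinite(lons)
    )
    return rows, cols, inside


def link_specimens(
    specimens: pd.DataFrame, landscape: SoilLandscape
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join each geocoded specimen to the soil attributes of its grid cell.

    Expects ``lat``/``lon`` columns (from geocoding).  Returns
    ``(linked, unlinked)``: linked rows gain ``row``, ``col``, ``mu_id`` and the
    attribute columns; unlinked rows (outside the extent or on a NODATA cell)
    gain a ``reason`` column instead.

    Raises
    ------
    DataIntegrityError
        If a raster mu_id has no attribute record (checked at landscape
        construction, re-checked here for defence in depth).
    """
    rows, cols, inside = locate_cells(
        specimens["lat"].to_numpy(), specimens["lon"].to_numpy(), landscape
    )
    mu = np.full(len(specimens), NODATA, dtype=int)
    mu[inside] = landscape.grid[rows[inside], cols[inside]]
    linked_mask = inside & (mu != NODATA)

    present = np.unique(mu[linked_mask])
    missing = set(present.tolist()) - set(landscape.attributes.index.tolist())
    if missing:
        raise DataIntegrityError(
            f"mu_ids in grid without attribute record: {sorted(missing)[:5]}"
        )

    linked = specimens.loc[linked_mask].copy()
    linked["row"] = rows[linked_mask]
    linked["col"] = cols[linked_mask]
    linked["mu_id"] = mu[linked_mask]
    attrs = landscape.attributes.loc[linked["mu_id"], ATTRIBUTE_JOIN_COLUMNS]
    for c in ATTRIBUTE_JOIN_COLUMNS:
        linked[c] = attrs[c].to_numpy()

    unlinked = specimens.loc[~linked_mask].copy()
    unlinked["reason"] = "out_of_region"
    return linked, unlinked


def clean_dataset(
    linked: pd.DataFrame,
    mu_id_range: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the cleaning rules and account for every removal.

    Rules, applied first-match in ledger order:

    1. ``out_of_region`` — no mapping unit (missing/NODATA ``mu_id``), or, when
       ``mu_id_range`` is given, an id outside ``[low, high]``.
    2. ``excluded_surface`` — soil-unit symbol in {WR, RK, GG, UR}.
    3. ``missing_subsoil`` — either subsoil field (``s_ph_h2o``, ``s_caco3``)
       missing.

    Returns the retained records and a ledger mapping reason -> count; the
    counts always sum to ``len(linked) - len(retained)``.
    """
    df = linked
    if "mu_id" in df.columns:
        mu = pd.to_numeric(df["mu_id"], errors="coerce")
        out_of_region = mu.isna() | (mu == NODATA)
        if mu_id_range is not None:
            low, high = mu_id_range
            out_of_region |= mu.notna() & ((mu < low) | (mu > high))
    else:
        out_of_region = pd.Series(True, index=df.index)

    if "su_sym90" in df.columns:
        excluded = df["su_sym90"].isin(EXCLUDED_SURFACE_CODES)
    else:
        excluded = pd.Series(False, index=df.index)
    excluded &= ~out_of_region

    if {"s_ph_h2o", "s_caco3"} <= set(df.columns):
        missing_sub = df["s_ph_h2o"].isna() | df["s_caco3"].isna()
    else:
        missing_sub = pd.Series(True, index=df.index)
    missing_sub &= ~out_of_region & ~excluded

    ledger = {
        "out_of_region": int(out_of_region.sum()),
        "excluded_surface": int(excluded.sum()),
        "missing_subsoil": int(missing_sub.sum()),
    }
    retained = df.loc[~(out_of_region | excluded | missing_sub)].copy()
    assert sum(ledger.values()) == len(df) - len(retained)
    return retained, ledger
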