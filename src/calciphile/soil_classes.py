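"""pH and CaCO3 class bins and the cell/specimen/taxon distribution tables.

Bin edges follow the soil database's published ranges.  Interior bins are
lower-inclusive, upper-exclusive; e.g. pH 4.5 falls in "4.5-5.5" and CaCO3
2.0 falls in "2-5".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._types import NODATA, SoilLandscape

PH_EDGES = [4.5, 5.5, 7.2, 8.5]
PH_LABELS = ["<4.5", "4.5-5.5", "5.5-7.2", "7.2-8.5", ">8.5"]

CACO3_EDGES = [2.0, 5.0, 15.0]
CACO3_LABELS = ["<2", "2-5", "5-15", ">15"]

_LAYER_PREFIX = {"topsoil": "t", "subsoil": "s"}
_ATTR_SUFFIX = {"ph": "ph_h2o", "caco3": "caco3"}


def _column(attribute: str, layer: str) -> str:
    try:
        return f"{_LAYER_PREFIX[layer]}_{_ATTR_SUFFIX[attribute]}"
    except KeyError:
        raise ValueError(f"unknown attribute/layer: {attribute!r}/{layer!r}") from None


def _edges_labels(attribute: str) -> tuple[list[float], list[str]]:
    if attribute == "ph":
        return PH_EDGES, PH_LABELS
    if attribute == "caco3":
        return CACO3_EDGES, CACO3_LABELS
    raise ValueError(f"unknown attribute: {attribute!r}")


def ph_class(v: float) -> str:
    """Class label for a pH value; raises on missing input."""
    return _classify_scalar(v, PH_EDGES, PH_LABELS)


def caco3_class(v: float) -> str:
    """Class label for a CaCO3 %-weight value; raises on missing input."""
    return _classify_scalar(v, CACO3_EDGES, CACO3_LABELS)


def _classify_scalar(v: float, edges: list[float], labels: list[str]) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        raise ValueError("cannot classify a missing value")
    return labels[int(np.searchsorted(edges, v, side="right"))]


def classify(values: np.ndarray, attribute: str) -> pd.Categorical:
    """Vectorized classification; NaN input yields NaN category."""
    edges, labels = _edges_labels(attribute)
    values = np.asarray(values, dtype=float)
    idx = np.searchsorted(edges, values, side="right")
    out = np.array(labels, dtype=object)[idx]
    out[~np.isfinite(values)] = None
    return pd.Categorical(out, categories=labels, ordered=True)


def _landscape_values(landscape: SoilLandscape, column: str) -> np.ndarray:
    """Attribute values of all non-NODATA cells (NaN where missing)."""
    vals = landscape.cell_values(column).ravel()
    return vals[landscape.grid.ravel() != NODATA]


def distribution_table(
    linked: pd.DataFrame,
    landscape: SoilLandscape,
    attribute: str = "ph",
    layer: str = "topsoil",
) -> pd.DataFrame:
    """Per-class counts and percentages of grid cells, specimens and taxa.

    Cells are tallied over the whole landscape (all non-NODATA cells);
    specimens are counted once each; a taxon is counted in every class where it
    has at least one specimen, so taxon percentages may sum past 100.
    """
    col = _column(attribute, layer)
    edges, labels = _edges_labels(attribute)

    cell_vals = _landscape_values(landscape, col)
    n_cells_total = cell_vals.size
    cell_cls = classify(cell_vals, attribute)
    n_cells = pd.Series(cell_cls).value_counts(sort=False).reindex(labels, fill_value=0)

    spec_cls = classify(linked[col].to_numpy(), attribute) if len(linked) else classify(
        np.array([]), attribute
    )
    n_spec = pd.Series(spec_cls).value_counts(sort=False).reindex(labels, fill_value=0)
    n_spec_total = len(linked)

    if len(linked):
        tx = pd.DataFrame({"taxon": linked["latin_name"].to_numpy(), "cls": spec_cls})
        n_taxa = (
            tx.dropna(subset=["cls"])
            .groupby("cls", observed=False)["taxon"]
            .nunique()
            .reindex(labels, fill_value=0)
        )
        n_taxa_total = tx["taxon"].nunique()
    else:
        n_taxa = pd.Series(0, index=labels)
        n_taxa_total = 0

    def pct(counts: pd.Series, total: int) -> pd.Series:
        return (100.0 * counts / total) if total else counts * 0.0

    table = pd.DataFrame(
        {
            "n_cells": n_cells.to_numpy(),
            "pct_cells": pct(n_cells, n_cells_total).to_numpy(),
            "n_specimens": n_spec.to_numpy(),
            "pct_specimens": pct(n_spec, n_spec_total).to_numpy(),
            "n_taxa": n_taxa.to_numpy(),
            "pct_taxa": pct(n_taxa, n_taxa_total).to_numpy(),
        },
        index=pd.Index(labels, name="class"),
    )
    table.attrs["attribute"] = attribute
    table.attrs["layer"] = layer
    table.attrs["empty_input"] = n_spec_total == 0
    return table


def value_histogram(
    linked: pd.DataFrame,
    attribute: str = "ph",
    layer: str = "topsoil",
    landscape: SoilLandscape | None = None,
) -> pd.DataFrame:
    """Per-distinct-value specimen/taxon (and optionally cell) tallies.

    One row per distinct attribute value occurring among the specimens or (when
    a landscape is given) the grid cells.  Taxa are counted in every value
    where they have at least one specimen.
    """
    col = _column(attribute, layer)
    vals = linked[col].dropna() if len(linked) else pd.Series(dtype=float)

    n_spec = vals.value_counts().sort_index()
    n_spec_total = len(linked)
    if len(linked):
        n_taxa = (
            linked.dropna(subset=[col])
            .groupby(col)["latin_name"]
            .nunique()
            .sort_index()
        )
        n_taxa_total = linked["latin_name"].nunique()
    else:
        n_taxa = pd.Series(dtype=int)
        n_taxa_total = 0

    index = n_spec.index
    if landscape is not None:
        cell_vals = pd.Series(_landscape_values(landscape, col)).dropna()
        n_cells = cell_vals.value_counts().sort_index()
        index = index.union(n_cells.index)

    out = pd.DataFrame(index=pd.Index(index, name="value"))
    out["n_specimens"] = n_spec.reindex(index, fill_value=0).astype(int)
    out["pct_specimens"] = (
        100.0 * out["n_specimens"] / n_spec_total if n_spec_total else 0.0
    )
    out["n_taxa"] = n_taxa.reindex(index, fill_value=0).astype(int)
    out["pct_taxa"] = 100.0 * out["n_taxa"] / n_taxa_total if n_taxa_total else 0.0
    if landscape is not None:
        out["n_cells"] = n_cells.reindex(index, fill_value=0).astype(int)
        out["pct_cells"] = 100.0 * out["n_cells"] / cell_vals.size
    return out
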