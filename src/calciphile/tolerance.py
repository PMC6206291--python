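"""Per-taxon topsoil quartiles, the upper-quartile tolerance rule, and its
contingency-table validation.

The tolerance rule: a taxon is predicted lime-tolerant when the upper quartile
of its specimens' topsoil pH strictly exceeds 7.2 AND the upper quartile of
topsoil CaCO3 strictly exceeds 2 % weight.  Species, botanical varieties and
subspecies are treated as separate taxa throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._types import ContingencyResult, TaxonomySummary
from .soil_classes import CACO3_LABELS, PH_LABELS, classify

PH_THRESHOLD = 7.2
CACO3_THRESHOLD = 2.0
MIN_SPECIMENS = 10


def taxon_quartiles(linked: pd.DataFrame, min_n: int = MIN_SPECIMENS) -> pd.DataFrame:
    """Quartile summary of topsoil pH and CaCO3 for each taxon with >= min_n
    specimens.

    Quartiles interpolate linearly between order statistics (the quantile of
    order statistic k of n is (k-1)/(n-1)).  Also reports, per taxon, the
    percentage of its specimens in each pH and CaCO3 class.
    """
    rows = []
    for name, grp in linked.groupby("latin_name", sort=True):
        n = len(grp)
        if n < min_n:
            continue
        ph = grp["t_ph_h2o"].to_numpy(dtype=float)
        ca = grp["t_caco3"].to_numpy(dtype=float)
        ph_q = np.quantile(ph, [0.25, 0.5, 0.75])
        ca_q = np.quantile(ca, [0.25, 0.5, 0.75])
        row = {
            "latin_name": name,
            "rank": grp["rank"].iloc[0] if "rank" in grp else "",
            "subgenus": grp["subgenus"].iloc[0] if "subgenus" in grp else "",
            "n": n,
            "ph_lq": ph_q[0],
            "ph_median": ph_q[1],
            "ph_uq": ph_q[2],
            "caco3_lq": ca_q[0],
            "caco3_median": ca_q[1],
            "caco3_uq": ca_q[2],
        }
        ph_cls = pd.Series(classify(ph, "ph")).value_counts(sort=False)
        for label in PH_LABELS:
            row[f"pct_ph_{label}"] = 100.0 * ph_cls.get(label, 0) / n
        ca_cls = pd.Series(classify(ca, "caco3")).value_counts(sort=False)
        for label in CACO3_LABELS:
            row[f"pct_caco3_{label}"] = 100.0 * ca_cls.get(label, 0) / n
        rows.append(row)
    columns = (
        ["latin_name", "rank", "subgenus", "n", "ph_lq", "ph_median", "ph_uq",
         "caco3_lq", "caco3_median", "caco3_uq"]
        + [f"pct_ph_{x}" for x in PH_LABELS]
        + [f"pct_caco3_{x}" for x in CACO3_LABELS]
    )
    return pd.DataFrame(rows, columns=columns)


def predict_tolerance(
    summaries: pd.DataFrame,
    ph_threshold: float = PH_THRESHOLD,
    caco3_threshold: float = CACO3_THRESHOLD,
) -> pd.DataFrame:
    """Apply the UQ threshold rule; strict inequalities on both attributes."""
    out = summaries[["latin_name", "rank", "subgenus", "n", "ph_uq", "caco3_uq"]].copy()
    out["tolerant"] = (out["ph_uq"] > ph_threshold) & (out["caco3_uq"] > caco3_threshold)
    out["ph_threshold"] = ph_threshold
    out["caco3_threshold"] = caco3_threshold
    return out


def lime_contingency(
    linked: pd.DataFrame,
    predictions: pd.DataFrame,
    ph_threshold: float = PH_THRESHOLD,
    caco3_threshold: float = CACO3_THRESHOLD,
    min_n: int = MIN_SPECIMENS,
    unpredicted_taxa: str = "non_tolerant",
) -> tuple[np.ndarray, int]:
    """Count specimens in lime vs non-lime topsoil by predicted tolerance.

    A specimen is in *lime* topsoil when pH > ph_threshold and CaCO3 >
    caco3_threshold, *non-lime* when pH <= ph_threshold and CaCO3 <=
    caco3_threshold; specimens meeting neither conjunction are excluded as
    mixed and returned in the second element.

    Taxa absent from ``predictions`` (those below ``min_n``) are assigned to
    the non-tolerant row by default (``unpredicted_taxa="non_tolerant"``) or
    dropped (``"exclude"``).  A missing prediction for a taxon with at least
    ``min_n`` specimens is an error.

    Returns ``(counts, n_mixed_excluded)`` with counts rows = (tolerant,
    non-tolerant) and columns = (lime, non-lime).
    """
    if unpredicted_taxa not in {"non_tolerant", "exclude"}:
        raise ValueError(f"unknown unpredicted_taxa policy: {unpredicted_taxa!r}")
    pred_map = predictions.set_index("latin_name")["tolerant"]
    sizes = linked.groupby("latin_name").size()
    unpredicted = sizes.index.difference(pred_map.index)
    too_big = sizes.loc[unpredicted]
    if (too_big >= min_n).any():
        raise ValueError(
            "prediction missing for taxa with >= min_n specimens: "
            f"{list(too_big[too_big >= min_n].index[:5])}"
        )

    ph = linked["t_ph_h2o"].to_numpy(dtype=float)
    ca = linked["t_caco3"].to_numpy(dtype=float)
    lime = (ph > ph_threshold) & (ca > caco3_threshold)
    non_lime = (ph <= ph_threshold) & (ca <= caco3_threshold)
    mixed = ~(lime | non_lime)

    tol = linked["latin_name"].map(pred_map)
    notna = tol.notna().to_numpy()
    tol_bool = np.zeros(len(linked), dtype=bool)
    tol_bool[notna] = tol[notna].astype(bool).to_numpy()
    if unpredicted_taxa == "non_tolerant":
        keep = ~mixed
    else:
        keep = notna & ~mixed

    counts = np.zeros((2, 2), dtype=int)
    tol_keep = tol_bool[keep]
    lime_keep = lime[keep]
    counts[0, 0] = int((tol_keep & lime_keep).sum())
    counts[0, 1] = int((tol_keep & ~lime_keep).sum())
    counts[1, 0] = int((~tol_keep & lime_keep).sum())
    counts[1, 1] = int((~tol_keep & ~lime_keep).sum())
    return counts, int(mixed.sum())


def chi_square_2x2(
    counts: np.ndarray, correction: bool = True, n_mixed_excluded: int = 0
) -> ContingencyResult:
    """Pearson chi-square test of a 2x2 table, Yates-corrected by default.

    With correction, each cell contributes ``max(0, |O-E| - 0.5)^2 / E``; the
    p-value is the upper tail of the chi-square distribution with 1 df.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise ValueError("zero margin: expected counts undefined")
    total = counts.sum()
    expected = np.outer(row_sums, col_sums) / total
    dev = np.abs(counts - expected)
    if correction:
        dev = np.maximum(0.0, dev - 0.5)
    statistic = float((dev**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return ContingencyResult(
        counts=counts.astype(int),
        statistic=statistic,
        df=1,
        p=p,
        correction=correction,
        n_mixed_excluded=n_mixed_excluded,
    )


def taxonomy_summary(
    specimens: pd.DataFrame,
    described_counts: pd.DataFrame | None = None,
    top_n: int = 20,
) -> TaxonomySummary:
    """Per-subgenus species counts, per-rank coverage, and the top-N table.

    ``described_counts`` carries the reference totals with columns ``kind``
    ("subgenus" or "rank"), ``name`` and ``described``.  Coverage percentages
    are dataset count / described count x 100, rounded to one decimal.
    """
    by_rank = (
        specimens.groupby("rank")["latin_name"].nunique()
        if len(specimens)
        else pd.Series(dtype=int)
    )
    n_species = int(by_rank.get("species", 0))
    n_varieties = int(by_rank.get("variety", 0))
    n_subspecies = int(by_rank.get("subspecies", 0))

    sp = specimens[specimens["rank"] == "species"] if len(specimens) else specimens
    species_by_subgenus = (
        sp.groupby("subgenus")["latin_name"].nunique()
        if len(sp)
        else pd.Series(dtype=int)
    )

    coverage: dict[str, float] = {}
    if described_counts is not None:
        ref_sub = described_counts[described_counts["kind"] == "subgenus"]
        known = set(ref_sub["name"])
        unknown = set(species_by_subgenus.index) - known
        if unknown:
            raise KeyError(f"subgenus absent from reference table: {sorted(unknown)}")
        ref_rank = (
            described_counts[described_counts["kind"] == "rank"]
            .set_index("name")["described"]
        )
        for rank, n in (
            ("species", n_species),
            ("variety", n_varieties),
            ("subspecies", n_subspecies),
        ):
            if rank in ref_rank.index and ref_rank[rank] > 0:
                coverage[rank] = round(100.0 * n / ref_rank[rank], 1)
            else:
                coverage[rank] = 0.0

    total = len(specimens)
    counts = (
        specimens.groupby("latin_name").size().sort_values(ascending=False)
        if total
        else pd.Series(dtype=int)
    )
    top = counts.head(top_n).rename("n_specimens").reset_index()
    top_share = round(100.0 * top["n_specimens"].sum() / total, 1) if total else 0.0

    return TaxonomySummary(
        n_specimens=total,
        n_species=n_species,
        n_varieties=n_varieties,
        n_subspecies=n_subspecies,
        species_by_subgenus=species_by_subgenus,
        coverage_pct=coverage,
        top_taxa=top,
        top_share_pct=top_share,
    )
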