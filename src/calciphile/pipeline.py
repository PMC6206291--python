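"""End-to-end orchestration: simulate -> geocode -> link -> clean ->
summarize -> predict -> validate, with a reconciling run manifest.

Every intermediate is written as plain text (TSV / ASCII grid / JSON) so each
stage can be re-run and audited in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from ._types import GeoPoint
from .density import density_from_points
from .geodesy import accuracy_stats, geocode_table
from .soil_classes import distribution_table, value_histogram
from .soil_link import clean_dataset, link_specimens
from .synthetic import (
    STAGE_SEED_OFFSETS,
    LandscapeConfig,
    corrupt_location_texts,
    generate_gazetteer,
    generate_landscape,
    generate_specimens,
    generate_taxa,
)
from .tolerance import (
    chi_square_2x2,
    lime_contingency,
    predict_tolerance,
    taxon_quartiles,
)

log = logging.getLogger("calciphile")


@dataclass
class RunConfig:
    """Flat configuration of a full synthetic pipeline run."""

    out_dir: str = "run_out"
    seed: int = 0
    # landscape
    n_rows: int = 80
    n_cols: int = 80
    origin_lon: float = 98.0
    origin_lat: float = 30.0
    resolution: float = 0.0083
    frac_excluded_surface: float = 0.02
    frac_missing_subsoil: float = 0.05
    n_units: int = 400
    # taxa / specimens
    n_taxa: int = 40
    tolerant_fraction: float = 0.5
    n_specimens_per_taxon: int = 50
    ph_sd: float = 0.5
    # geocoding
    noise_km: float = 1.0
    corrupt_fraction: float = 0.0
    # analysis
    ph_threshold: float = 7.2
    caco3_threshold: float = 2.0
    min_n: int = 10
    correction: bool = True
    # density
    density_resolution: float = 0.05
    density_bandwidth: float = 0.2

    def __post_init__(self) -> None:
        if self.ph_threshold <= 0 or self.caco3_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_n < 1:
            raise ValueError("min_n must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunManifest:
    version: str = __version__
    seed: int = 0
    parameters: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    removal_ledger: dict = field(default_factory=dict)
    chi_square: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage in order, writing all intermediates to
    ``config.out_dir`` and returning a manifest whose counts reconcile."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, parameters=asdict(config))
    t_stage = time.perf_counter()

    def tick(stage: str) -> None:
        nonlocal t_stage
        now = time.perf_counter()
        manifest.stage_seconds[stage] = round(now - t_stage, 3)
        log.info("stage %-10s %.3fs", stage, now - t_stage)
        t_stage = now

    # --- simulate -----------------------------------------------------------
    seed = config.seed
    landscape = generate_landscape(
        LandscapeConfig(
            n_rows=config.n_rows,
            n_cols=config.n_cols,
            origin_lon=config.origin_lon,
            origin_lat=config.origin_lat,
            resolution=config.resolution,
            frac_excluded_surface=config.frac_excluded_surface,
            frac_missing_subsoil=config.frac_missing_subsoil,
            n_units=config.n_units,
            seed=seed + STAGE_SEED_OFFSETS["landscape"],
        )
    )
    taxa = generate_taxa(
        config.n_taxa,
        config.tolerant_fraction,
        seed + STAGE_SEED_OFFSETS["taxa"],
        ph_sd=config.ph_sd,
        n_specimens=config.n_specimens_per_taxon,
    )
    specimens = generate_specimens(
        taxa, landscape, seed + STAGE_SEED_OFFSETS["specimens"]
    )
    gazetteer, specimens = generate_gazetteer(
        specimens, config.noise_km, seed + STAGE_SEED_OFFSETS["gazetteer"]
    )
    if config.corrupt_fraction:
        specimens = corrupt_location_texts(
            specimens, config.corrupt_fraction, seed + 5
        )
    io.write_landscape(out / "landscape.asc", out / "attributes.tsv", landscape)
    io.write_table(out / "specimens.tsv", specimens)
    io.write_table(out / "gazetteer.tsv", gazetteer)
    truth = pd.DataFrame(
        {
            "latin_name": [t.taxon_name for t in taxa],
            "ground_truth_tolerant": [t.ground_truth_tolerant for t in taxa],
        }
    )
    io.write_table(out / "ground_truth.tsv", truth)
    manifest.stage_counts["simulated"] = len(specimens)
    tick("simulate")

    # --- geocode ------------------------------------------------------------
    geocoded = geocode_table(specimens, gazetteer)
    io.write_table(out / "geocoded.tsv", geocoded)
    matched = geocoded[geocoded["matched"]].copy()
    manifest.stage_counts["geocoded"] = int(len(matched))
    pairs = [
        (GeoPoint(r.lat, r.lon), GeoPoint(r.true_lat, r.true_lon))
        for r in matched.itertuples()
    ]
    if pairs:
        acc = accuracy_stats(pairs)
        io.write_table(out / "geocoding_accuracy.tsv", pd.DataFrame([asdict(acc)]))
    tick("geocode")

    # --- link + clean -------------------------------------------------------
    linked, unlinked = link_specimens(matched, landscape)
    all_linked = pd.concat([linked, unlinked], ignore_index=True)
    retained, ledger = clean_dataset(all_linked)
    retained = retained.drop(columns=["reason"], errors="ignore")
    io.write_table(out / "linked.tsv", retained)
    io.write_table(
        out / "removal_ledger.tsv",
        pd.DataFrame(ledger.items(), columns=["reason", "n_removed"]),
    )
    manifest.removal_ledger = ledger
    manifest.stage_counts["linked"] = int(len(all_linked))
    manifest.stage_counts["retained"] = int(len(retained))
    if len(retained) + sum(ledger.values()) != len(all_linked):
        raise RuntimeError("cleaning ledger does not reconcile")
    tick("link")

    # --- summarize ----------------------------------------------------------
    for attribute in ("ph", "caco3"):
        for layer in ("topsoil", "subsoil"):
            table = distribution_table(retained, landscape, attribute, layer)
            io.write_table(out / f"distribution_{attribute}_{layer}.tsv", table, index=True)
        hist = value_histogram(retained, attribute, "topsoil", landscape)
        io.write_table(out / f"histogram_{attribute}_topsoil.tsv", hist, index=True)
    tick("summarize")

    # --- predict ------------------------------------------------------------
    summaries = taxon_quartiles(retained, min_n=config.min_n)
    predictions = predict_tolerance(
        summaries, config.ph_threshold, config.caco3_threshold
    )
    io.write_table(out / "taxon_quartiles.tsv", summaries)
    io.write_table(out / "predictions.tsv", predictions)
    manifest.stage_counts["taxa_summarized"] = int(len(summaries))
    manifest.stage_counts["taxa_predicted_tolerant"] = int(predictions["tolerant"].sum())
    tick("predict")

    # --- validate -----------------------------------------------------------
    counts, n_mixed = lime_contingency(
        retained,
        predictions,
        config.ph_threshold,
        config.caco3_threshold,
        config.min_n,
    )
    result = chi_square_2x2(counts, correction=config.correction, n_mixed_excluded=n_mixed)
    manifest.chi_square = {
        "counts": counts.tolist(),
        "n_mixed_excluded": n_mixed,
        "statistic": result.statistic,
        "df": result.df,
        "p": result.p,
        "p_text": result.p_text(),
        "correction": result.correction,
    }
    with open(out / "contingency.json", "w") as fh:
        json.dump(manifest.chi_square, fh, indent=2)
    if int(counts.sum()) + n_mixed != len(retained):
        raise RuntimeError("contingency counts do not reconcile with retained records")
    tick("validate")

    # --- density ------------------------------------------------------------
    if len(retained):
        surface = density_from_points(
            retained, config.density_resolution, config.density_bandwidth
        )
        io.write_ascii_grid(
            out / "density.asc",
            surface.grid,
            surface.origin_lon,
            surface.origin_lat,
            surface.resolution,
        )
    tick("density")

    with open(out / "manifest.json", "w") as fh:
        json.dump(asdict(manifest), fh, indent=2)
    return manifest
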