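"""Synthetic soil landscapes, taxa, specimen records and gazetteers.

These generators emulate the statistical structure the downstream analysis
assumes — a mapping-unit raster joined to one attribute record per unit, a
multimodal topsoil-pH landscape with CaCO3 coupled to pH, non-soil surface
classes, units missing subsoil data, and taxa occupying distinct pH niches —
so every stage can be tested against known ground truth without external data.

All randomness flows through explicit seeds; per-stage seeds are derived from
one top-level seed by fixed offsets (see :data:`STAGE_SEED_OFFSETS`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._types import SPECIMEN_COLUMNS, SoilLandscape

#: Fixed offsets deriving per-stage seeds from one top-level seed.
STAGE_SEED_OFFSETS = {
    "landscape": 1,
    "taxa": 2,
    "specimens": 3,
    "gazetteer": 4,
}

#: Mixture humps of the synthetic topsoil-pH distribution: (center, weight, sd).
#: Centers and relative weights mirror the four humps of the real soil grid
#: (6.7 : 7.9 : 12.5 : 11, normalized).
DEFAULT_PH_MODES = (
    (4.8, 6.7 / 38.1, 0.25),
    (5.7, 7.9 / 38.1, 0.25),
    (6.5, 12.5 / 38.1, 0.25),
    (8.0, 11.0 / 38.1, 0.25),
)

#: Non-soil surface classes (inland water, rock debris, glaciers/snow, urban).
EXCLUDED_SYMBOLS = ("WR", "RK", "GG", "UR")

#: Ordinary soil-unit symbols assigned to non-excluded units.
SOIL_SYMBOLS = ("I", "ACu", "ACh", "CMd", "LVh", "RGc", "PLd", "FLc")

SUBGENERA = (
    "Rhododendron",
    "Pseudazalea",
    "Pseudorhodorastrum",
    "Rhodorastrum",
    "Hymenanthes",
    "Azaleastrum",
    "Pentanthera",
    "Tsutsusi",
    "Therorhodion",
)

#: First mapping-unit id issued by the generator.
MU_ID_START = 11000

_EARTH_RADIUS_KM = 6371.0088


def default_caco3_rule(ph: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """CaCO3 % weight given pH: zero in acid soils, positive above pH 6.5.

    Alkaline units draw from the 2-5 and 5-15 %-weight ranges with
    probabilities 0.25 / 0.75 (the relative cell frequencies of those two
    classes in the real soil grid).
    """
    ph = np.asarray(ph, dtype=float)
    out = np.zeros_like(ph)
    alk = ph >= 6.5
    n = int(alk.sum())
    if n:
        pick_low = rng.random(n) < 0.25
        vals = np.where(
            pick_low, rng.uniform(2.0, 5.0, n), rng.uniform(5.0, 15.0, n)
        )
        out[alk] = vals
    return out


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic soil landscape."""

    n_rows: int = 60
    n_cols: int = 60
    origin_lon: float = 98.0
    origin_lat: float = 30.0
    resolution: float = 0.0083
    ph_modes: Sequence[tuple[float, float, float]] = DEFAULT_PH_MODES
    caco3_given_ph: Callable[[np.ndarray, np.random.Generator], np.ndarray] = (
        default_caco3_rule
    )
    frac_excluded_surface: float = 0.02
    frac_missing_subsoil: float = 0.05
    n_units: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for frac in (self.frac_excluded_surface, self.frac_missing_subsoil):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        weights = sum(w for _, w, _ in self.ph_modes)
        if not math.isclose(weights, 1.0, abs_tol=1e-9):
            raise ValueError(f"pH mixture weights must sum to 1, got {weights}")
        if self.n_units <= 0:
            raise ValueError("n_units must be positive")


@dataclass
class NicheParams:
    """Ground-truth soil niche of one synthetic taxon."""

    taxon_name: str
    ground_truth_tolerant: bool
    ph_mean: float
    ph_sd: float
    n_specimens: int
    rank: str = "species"
    subgenus: str = "Rhododendron"

    def __post_init__(self) -> None:
        if self.ph_sd <= 0:
            raise ValueError("ph_sd must be positive")
        if self.n_specimens < 0:
            raise ValueError("n_specimens must be non-negative")


def generate_landscape(config: LandscapeConfig) -> SoilLandscape:
    """Build a mapping-unit raster with one attribute record per unit.

    Attribute values live on the mapping units; the raster assigns each cell
    one unit uniformly at random, so the per-cell pH distribution follows the
    configured mixture.  pH values are drawn from the mixture of normals,
    clipped to [3.5, 9.5] and rounded to one decimal (the granularity of the
    real attribute data); CaCO3 follows ``caco3_given_ph``.  Excluded-surface
    units still carry attributes — exclusion happens at cleaning.
    """
    rng = np.random.default_rng(config.seed)
    n_units = config.n_units

    centers, weights, sds = (np.array(x, dtype=float) for x in zip(*config.ph_modes))
    comp = rng.choice(len(centers), size=n_units, p=weights)
    t_ph = rng.normal(centers[comp], sds[comp])
    t_ph = np.round(np.clip(t_ph, 3.5, 9.5), 1)
    s_ph = np.round(np.clip(t_ph + rng.normal(0.0, 0.15, n_units), 3.5, 9.5), 1)

    t_caco3 = np.round(config.caco3_given_ph(t_ph, rng), 1)
    s_caco3 = np.round(config.caco3_given_ph(s_ph, rng), 1)

    symbols = rng.choice(SOIL_SYMBOLS, size=n_units).astype(object)
    excluded = rng.random(n_units) < config.frac_excluded_surface
    symbols[excluded] = rng.choice(EXCLUDED_SYMBOLS, size=int(excluded.sum()))

    missing = rng.random(n_units) < config.frac_missing_subsoil
    s_ph = s_ph.astype(float)
    s_caco3 = s_caco3.astype(float)
    s_ph[missing] = np.nan
    s_caco3[missing] = np.nan

    mu_ids = np.arange(MU_ID_START, MU_ID_START + n_units)
    attributes = pd.DataFrame(
        {
            "mu_id": mu_ids,
            "su_sym90": symbols,
            "t_ph_h2o": t_ph,
            "s_ph_h2o": s_ph,
            "t_caco3": t_caco3,
            "s_caco3": s_caco3,
        }
    ).set_index("mu_id")

    # Mapping units are contiguous patches, as in a real soil map: each cell
    # takes the unit of the nearest of n_units random seed points (Voronoi).
    seeds = rng.uniform(
        [0.0, 0.0], [config.n_rows, config.n_cols], size=(n_units, 2)
    )
    tree = cKDTree(seeds)
    rr, cc = np.meshgrid(
        np.arange(config.n_rows) + 0.5,
        np.arange(config.n_cols) + 0.5,
        indexing="ij",
    )
    _, nearest = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    grid = mu_ids[nearest].reshape(config.n_rows, config.n_cols)
    return SoilLandscape(
        grid=grid,
        origin_lon=config.origin_lon,
        origin_lat=config.origin_lat,
        resolution=config.resolution,
        attributes=attributes,
    )


def generate_taxa(
    n_taxa: int,
    tolerant_fraction: float,
    seed: int,
    tolerant_ph_mean: float = 8.0,
    intolerant_ph_mean: float = 5.0,
    ph_mean_jitter: float = 0.3,
    ph_sd: float = 0.5,
    n_specimens: int = 50,
) -> list[NicheParams]:
    """Taxa with separated ground-truth niches.

    ``round(n_taxa * tolerant_fraction)`` taxa are flagged tolerant and receive
    ph_mean near ``tolerant_ph_mean`` (jittered, always >= 7.2); the rest
    receive ph_mean near ``intolerant_ph_mean`` (always <= 5.5).
    """
    if n_taxa <= 0:
        raise ValueError("n_taxa must be positive")
    if not 0.0 <= tolerant_fraction <= 1.0:
        raise ValueError("tolerant_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_tol = round(n_taxa * tolerant_fraction)
    ranks = ("species", "variety", "subspecies")
    taxa = []
    for i in range(n_taxa):
        tolerant = i < n_tol
        base = tolerant_ph_mean if tolerant else intolerant_ph_mean
        mean = base + rng.uniform(-ph_mean_jitter, ph_mean_jitter)
        mean = max(mean, 7.2) if tolerant else min(mean, 5.5)
        taxa.append(
            NicheParams(
                taxon_name=f"Taxon_{i + 1:03d}",
                ground_truth_tolerant=tolerant,
                ph_mean=mean,
                ph_sd=ph_sd,
                n_specimens=n_specimens,
                rank=ranks[rng.choice(3, p=[0.8, 0.1, 0.1])],
                subgenus=SUBGENERA[rng.integers(len(SUBGENERA))],
            )
        )
    return taxa


def generate_specimens(
    taxa: Sequence[NicheParams], landscape: SoilLandscape, seed: int
) -> pd.DataFrame:
    """Place specimens on the landscape according to each taxon's pH niche.

    Each specimen lands in a cell with probability proportional to a Gaussian
    kernel of that cell's topsoil pH around the taxon's ph_mean, then takes a
    uniform position inside the cell.  Placement uses the cell-level attribute,
    mirroring the analysis's cell-level soil lookup.
    """
    rng = np.random.default_rng(seed)
    cell_ph = landscape.cell_values("t_ph_h2o").ravel()
    valid = np.isfinite(cell_ph)
    if not valid.any():
        raise ValueError("landscape has no cell with topsoil pH")
    valid_idx = np.flatnonzero(valid)
    ph_valid = cell_ph[valid_idx]

    records = []
    counter = 1
    for taxon in taxa:
        if taxon.n_specimens == 0:
            continue
        logw = -0.5 * ((ph_valid - taxon.ph_mean) / taxon.ph_sd) ** 2
        logw -= logw.max()
        w = np.exp(logw)
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError(
                f"taxon {taxon.taxon_name!r} has zero niche weight over the landscape"
            )
        chosen = rng.choice(valid_idx, size=taxon.n_specimens, p=w / total)
        rows, cols = np.unravel_index(chosen, landscape.grid.shape)
        u = rng.random(taxon.n_specimens)
        v = rng.random(taxon.n_specimens)
        lats = landscape.origin_lat - (rows + u) * landscape.resolution
        lons = landscape.origin_lon + (cols + v) * landscape.resolution
        for lat, lon in zip(lats, lons):
            records.append(
                {
                    "specimen_id": f"S{counter:06d}",
                    "latin_name": taxon.taxon_name,
                    "rank": taxon.rank,
                    "subgenus": taxon.subgenus,
                    "location_text": f"LOC_{counter:06d}",
                    "true_lat": lat,
                    "true_lon": lon,
                }
            )
            counter += 1
    return pd.DataFrame(records, columns=SPECIMEN_COLUMNS)


def _displace(
    lats: np.ndarray, lons: np.ndarray, dist_km: np.ndarray, bearing: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Spherical destination points at given distances/bearings."""
    phi = np.radians(lats)
    lam = np.radians(lons)
    delta = dist_km / _EARTH_RADIUS_KM
    phi2 = np.arcsin(
        np.sin(phi) * np.cos(delta) + np.cos(phi) * np.sin(delta) * np.cos(bearing)
    )
    lam2 = lam + np.arctan2(
        np.sin(bearing) * np.sin(delta) * np.cos(phi),
        np.cos(delta) - np.sin(phi) * np.sin(phi2),
    )
    return np.degrees(phi2), np.degrees(lam2)


def generate_gazetteer(
    specimens: pd.DataFrame,
    noise_km: float,
    seed: int,
    n_extra_entries: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A gazetteer resolving each specimen's location text, with positional noise.

    Every specimen's ``location_text`` matches exactly one gazetteer label
    whose coordinates are displaced from the specimen's true position by a
    half-normal distance with mean ``noise_km`` (in a uniform random bearing).
    ``n_extra_entries`` decoy labels at random positions within the specimen
    bounding box can be appended to model gazetteer entries no specimen uses.

    Returns ``(gazetteer, specimens)``; the specimen table is returned
    unchanged apart from a defensive copy, its location texts already being
    the labels resolved here.
    """
    if noise_km < 0:
        raise ValueError("noise_km must be non-negative")
    if n_extra_entries < 0:
        raise ValueError("n_extra_entries must be non-negative")
    if len(specimens) + n_extra_entries < 1:
        raise ValueError("gazetteer must have at least one entry")
    rng = np.random.default_rng(seed)
    n = len(specimens)

    lats = specimens["true_lat"].to_numpy(dtype=float)
    lons = specimens["true_lon"].to_numpy(dtype=float)
    if noise_km > 0 and n:
        # half-normal with mean m has scale m * sqrt(pi/2)
        sigma = noise_km * math.sqrt(math.pi / 2.0)
        dist = np.abs(rng.normal(0.0, sigma, n))
        bearing = rng.uniform(0.0, 2.0 * math.pi, n)
        glats, glons = _displace(lats, lons, dist, bearing)
    else:
        glats, glons = lats.copy(), lons.copy()

    gaz = pd.DataFrame(
        {
            "label": specimens["location_text"].to_numpy(),
            "lat": glats,
            "lon": glons,
        }
    )
    if n_extra_entries:
        lo_lat, hi_lat = (lats.min(), lats.max()) if n else (-1.0, 1.0)
        lo_lon, hi_lon = (lons.min(), lons.max()) if n else (-1.0, 1.0)
        extra = pd.DataFrame(
            {
                "label": [f"DECOY_{i + 1:06d}" for i in range(n_extra_entries)],
                "lat": rng.uniform(lo_lat, hi_lat, n_extra_entries),
                "lon": rng.uniform(lo_lon, hi_lon, n_extra_entries),
            }
        )
        gaz = pd.concat([gaz, extra], ignore_index=True)
    return gaz, specimens.copy()


def corrupt_location_texts(
    specimens: pd.DataFrame, fraction: float, seed: int
) -> pd.DataFrame:
    """Corrupt an exact share of location texts so they miss the gazetteer.

    ``round(n * fraction)`` rows, chosen at random, get a suffix appended that
    no gazetteer label carries — the stand-in for unresolvable free-text
    locations.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = specimens.copy()
    n_bad = round(len(out) * fraction)
    idx = rng.choice(len(out), size=n_bad, replace=False)
    col = out.columns.get_loc("location_text")
    out.iloc[idx, col] = out.iloc[idx, col] + "_unresolvable"
    return out


def make_cleaning_fixture(
    n_total: int = 35574,
    n_out_of_region: int = 382,
    n_excluded_surface: int = 458,
    n_missing_subsoil: int = 3588,
    seed: int = 0,
) -> tuple[pd.DataFrame, SoilLandscape]:
    """A landscape plus geocoded specimens realizing an exact removal structure.

    Builds a small landscape whose mapping units are partitioned into ordinary,
    excluded-surface and missing-subsoil groups, then places specimens so that
    exactly the requested numbers fall outside the grid, on excluded-surface
    cells, and on cells lacking subsoil data (disjoint categories).  Running
    ``link_specimens`` then ``clean_dataset`` on the result must retain
    ``n_total - n_out - n_excluded - n_missing`` records.

    Returns ``(specimens, landscape)`` where specimens carry ``lat``/``lon``
    columns ready for linking.
    """
    n_clean = n_total - n_out_of_region - n_excluded_surface - n_missing_subsoil
    if n_clean < 0:
        raise ValueError("removal counts exceed n_total")
    rng = np.random.default_rng(seed)

    config = LandscapeConfig(
        n_rows=30,
        n_cols=30,
        frac_excluded_surface=0.0,
        frac_missing_subsoil=0.0,
        n_units=90,
        seed=seed,
    )
    landscape = generate_landscape(config)
    attrs = landscape.attributes
    # carve out dedicated excluded-surface and missing-subsoil unit groups,
    # drawn from units that actually own cells in the raster
    mu_ids = np.unique(landscape.grid)
    excl_units = mu_ids[:10]
    miss_units = mu_ids[10:20]
    attrs.loc[excl_units, "su_sym90"] = np.resize(EXCLUDED_SYMBOLS, len(excl_units))
    attrs.loc[miss_units, ["s_ph_h2o", "s_caco3"]] = np.nan

    def cells_of(units: np.ndarray) -> np.ndarray:
        mask = np.isin(landscape.grid.ravel(), units)
        return np.flatnonzero(mask)

    clean_units = mu_ids[20:]
    groups = [
        (cells_of(clean_units), n_clean),
        (cells_of(excl_units), n_excluded_surface),
        (cells_of(miss_units), n_missing_subsoil),
    ]
    lats, lons = [], []
    for cells, count in groups:
        if count and cells.size == 0:
            raise RuntimeError("fixture landscape lacks cells for a removal group")
        chosen = rng.choice(cells, size=count, replace=True)
        rows, cols = np.unravel_index(chosen, landscape.grid.shape)
        lats.append(landscape.origin_lat - (rows + rng.random(count)) * landscape.resolution)
        lons.append(landscape.origin_lon + (cols + rng.random(count)) * landscape.resolution)
    # out-of-region points: south of the grid
    south = landscape.origin_lat - (landscape.n_rows + 5) * landscape.resolution
    lats.append(np.full(n_out_of_region, south))
    lons.append(
        landscape.origin_lon
        + rng.random(n_out_of_region) * landscape.n_cols * landscape.resolution
    )

    lat = np.concatenate(lats)
    lon = np.concatenate(lons)
    n = lat.size
    specimens = pd.DataFrame(
        {
            "specimen_id": [f"S{i + 1:06d}" for i in range(n)],
            "latin_name": "Taxon_fixture",
            "rank": "species",
            "subgenus": SUBGENERA[0],
            "location_text": [f"LOC_{i + 1:06d}" for i in range(n)],
            "true_lat": lat,
            "true_lon": lon,
            "lat": lat,
            "lon": lon,
        }
    )
    return specimens, landscape
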