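"""Core value types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Soil-unit symbols marking non-soil surface classes that are removed at
#: cleaning: inland water, rock debris, glaciers/permanent snow, urban area.
EXCLUDED_SURFACE_CODES = frozenset({"WR", "RK", "GG", "UR"})

#: Sentinel used for missing mapping-unit ids in integer rasters.
NODATA = -9999

#: Columns every specimen table carries.
SPECIMEN_COLUMNS = [
    "specimen_id",
    "latin_name",
    "rank",
    "subgenus",
    "location_text",
    "true_lat",
    "true_lon",
]

#: Columns of a mapping-unit attribute table.
ATTRIBUTE_COLUMNS = ["mu_id", "su_sym90", "t_ph_h2o", "s_ph_h2o", "t_caco3", "s_caco3"]


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 coordinate in decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range [-90, 90]: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range [-180, 180]: {self.lon}")


@dataclass
class SoilLandscape:
    """A mapping-unit raster joined to one attribute record per unit.

    ``grid`` holds integer mapping-unit ids (``NODATA`` allowed); cell (0, 0)
    has its top-left corner at (``origin_lon``, ``origin_lat``) and cells are
    square with side ``resolution`` decimal degrees.  ``attributes`` is indexed
    by ``mu_id`` with columns ``su_sym90, t_ph_h2o, s_ph_h2o, t_caco3, s_caco3``.
    """

    grid: np.ndarray
    origin_lon: float
    origin_lat: float
    resolution: float
    attributes: pd.DataFrame

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.attributes.index.name != "mu_id":
            if "mu_id" in self.attributes.columns:
                self.attributes = self.attributes.set_index("mu_id")
            else:
                raise ValueError("attributes must be indexed by mu_id")
        present = np.unique(self.grid[self.grid != NODATA])
        missing = set(present.tolist()) - set(self.attributes.index.tolist())
        if missing:
            raise ValueError(
                f"{len(missing)} mapping-unit ids in grid lack attribute records"
            )

    @property
    def n_rows(self) -> int:
        return int(self.grid.shape[0])

    @property
    def n_cols(self) -> int:
        return int(self.grid.shape[1])

    def cell_center(self, row: int, col: int) -> GeoPoint:
        return GeoPoint(
            lat=self.origin_lat - (row + 0.5) * self.resolution,
            lon=self.origin_lon + (col + 0.5) * self.resolution,
        )

    def cell_values(self, column: str) -> np.ndarray:
        """Per-cell attribute values (NaN for NODATA cells), same shape as grid."""
        lookup = self.attributes[column]
        flat = pd.Series(self.grid.ravel())
        vals = flat.map(lookup).to_numpy(dtype=float)
        vals[self.grid.ravel() == NODATA] = np.nan
        return vals.reshape(self.grid.shape)


@dataclass(frozen=True)
class DistanceStats:
    """Summary of a sample of geodesic distances, in kilometres."""

    n: int
    mean_km: float
    se_km: float
    q1_km: float
    median_km: float
    q3_km: float


@dataclass
class ContingencyResult:
    """A 2x2 contingency table with its (optionally corrected) chi-square test.

    Rows: predicted tolerant / non-tolerant taxa.
    Columns: specimens in lime / non-lime topsoil.
    """

    counts: np.ndarray
    statistic: float
    df: int
    p: float
    correction: bool
    n_mixed_excluded: int = 0

    def p_text(self, floor: float = 2.2e-16) -> str:
        """R-style p-value rendering: values below ``floor`` print as '< floor'."""
        if self.p < floor:
            return f"< {floor:g}"
        return f"{self.p:g}"


@dataclass
class TaxonomySummary:
    """Per-subgenus and per-rank bookkeeping of a cleaned specimen table."""

    n_specimens: int
    n_species: int
    n_varieties: int
    n_subspecies: int
    species_by_subgenus: pd.Series
    coverage_pct: dict = field(default_factory=dict)
    top_taxa: pd.DataFrame | None = None
    top_share_pct: float = 0.0

    @property
    def n_taxa(self) -> int:
        return self.n_species + self.n_varieties + self.n_subspecies
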