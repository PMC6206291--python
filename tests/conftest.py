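import numpy as np
import pandas as pd
import pytest

from calciphile import LandscapeConfig, SoilLandscape, generate_landscape


@pytest.fixture
def tiny_landscape() -> SoilLandscape:
    """A hand-built 3x4 landscape with one attribute record per unit."""
    grid = np.array(
        [
            [11001, 11001, 11002, 11002],
            [11001, 11003, 11003, 11002],
            [11004, 11004, 11005, 11005],
        ]
    )
    attributes = pd.DataFrame(
        {
            "mu_id": [11001, 11002, 11003, 11004, 11005],
            "su_sym90": ["I", "ACu", "UR", "CMd", "LVh"],
            "t_ph_h2o": [4.8, 6.5, 7.0, 8.0, 5.7],
            "s_ph_h2o": [4.9, 6.6, 7.1, np.nan, 5.8],
            "t_caco3": [0.0, 3.0, 5.0, 9.3, 0.0],
            "s_caco3": [0.0, 3.5, 5.5, np.nan, 0.0],
        }
    )
    return SoilLandscape(
        grid=grid,
        origin_lon=100.0,
        origin_lat=30.0,
        resolution=0.5,
        attributes=attributes,
    )


@pytest.fixture(scope="session")
def default_landscape() -> SoilLandscape:
    return generate_landscape(LandscapeConfig(seed=42))


def make_linked(records: list[dict]) -> pd.DataFrame:
    """Build a minimal linked-specimen frame; missing keys get defaults."""
    defaults = {
        "specimen_id": None,
        "latin_name": "Taxon_A",
        "rank": "species",
        "subgenus": "Rhododendron",
        "mu_id": 11001,
        "su_sym90": "I",
        "t_ph_h2o": 5.0,
        "s_ph_h2o": 5.0,
        "t_caco3": 0.0,
        "s_caco3": 0.0,
    }
    rows = []
    for i, rec in enumerate(records):
        row = dict(defaults, specimen_id=f"S{i + 1:06d}")
        row.update(rec)
        rows.append(row)
    return pd.DataFrame(rows)
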