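"""Plain-text readers and writers: ESRI ASCII grids and TSV tables.

Everything the pipeline touches is text so that each stage can be inspected,
diffed, and re-run independently.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._types import ATTRIBUTE_COLUMNS, NODATA, SPECIMEN_COLUMNS, SoilLandscape


def write_ascii_grid(
    path: str | Path,
    grid: np.ndarray,
    origin_lon: float,
    origin_lat: float,
    resolution: float,
    nodata: float = NODATA,
) -> None:
    """Write a 2-D array as an ESRI ASCII grid.

    ``origin_lat`` is the latitude of the *top-left* corner; the format stores
    the lower-left corner, so the header converts between the two conventions.
    """
    grid = np.asarray(grid)
    n_rows, n_cols = grid.shape
    yll = origin_lat - n_rows * resolution
    is_int = np.issubdtype(grid.dtype, np.integer)
    fmt = "%d" if is_int else "%.10g"
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {origin_lon:.10g}\n"
        f"yllcorner {yll:.10g}\n"
        f"cellsize {resolution:.10g}\n"
        f"NODATA_value {nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt=fmt)


def read_ascii_grid(path: str | Path, dtype=int) -> tuple[np.ndarray, float, float, float, float]:
    """Read an ESRI ASCII grid.

    Returns ``(grid, origin_lon, origin_lat, resolution, nodata)`` where
    ``origin_lat`` is the top-left corner latitude.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, value = line.split()
            key = key.lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(value)
                pos = fh.tell()
            else:  # optional NODATA line absent
                fh.seek(pos)
                break
        grid = np.loadtxt(fh, dtype=dtype, ndmin=2)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    if grid.shape != (n_rows, n_cols):
        raise ValueError(f"grid shape {grid.shape} does not match header ({n_rows}, {n_cols})")
    resolution = header["cellsize"]
    origin_lat = header["yllcorner"] + n_rows * resolution
    return grid, header["xllcorner"], origin_lat, resolution, header.get("nodata_value", NODATA)


def write_attribute_table(path: str | Path, attributes: pd.DataFrame) -> None:
    """Write a mapping-unit attribute table as TSV (empty field = missing)."""
    df = attributes.reset_index() if attributes.index.name == "mu_id" else attributes.copy()
    df = df[ATTRIBUTE_COLUMNS]
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_attribute_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"mu_id": int, "su_sym90": str})
    missing = set(ATTRIBUTE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"attribute table missing columns: {sorted(missing)}")
    return df.set_index("mu_id")


def write_landscape(
    grid_path: str | Path, attr_path: str | Path, landscape: SoilLandscape
) -> None:
    write_ascii_grid(
        grid_path,
        landscape.grid.astype(int),
        landscape.origin_lon,
        landscape.origin_lat,
        landscape.resolution,
    )
    write_attribute_table(attr_path, landscape.attributes)


def read_landscape(grid_path: str | Path, attr_path: str | Path) -> SoilLandscape:
    grid, origin_lon, origin_lat, resolution, _ = read_ascii_grid(grid_path, dtype=int)
    attributes = read_attribute_table(attr_path)
    return SoilLandscape(
        grid=grid,
        origin_lon=origin_lon,
        origin_lat=origin_lat,
        resolution=resolution,
        attributes=attributes,
    )


def write_table(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="")


def read_specimens(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SPECIMEN_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"specimen table missing columns: {sorted(missing)}")
    return df


def read_gazetteer(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("label", "lat", "lon"):
        if col not in df.columns:
            raise ValueError(f"gazetteer missing column: {col}")
    return df
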