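"""Plot-table and raster file formats, plus YAML pipeline configuration.

Plot tables are CSV (UTF-8, '.' decimal, mandatory header) with columns
``plot_id``, ``x``, ``y`` and one column per service or driver.  Rasters
use the ESRI ASCII grid format (ncols/nrows/xllcorner/yllcorner/cellsize/
NODATA_value header, rows north-to-south).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kriging import RasterSurface

__all__ = [
    "read_plot_table",
    "write_plot_table",
    "write_raster_ascii",
    "read_raster_ascii",
    "load_config",
]

REQUIRED_COLUMNS = ("plot_id", "x", "y")


class SchemaError(ValueError):
    """Raised when a plot table violates the expected schema."""


def validate_plot_table(
    table: pd.DataFrame, service_columns: list[str] | None = None
) -> pd.DataFrame:
    """Validate plot-table invariants; returns the table unchanged on success."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    dup = table["plot_id"][table["plot_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate plot_id values: {sorted(set(dup))[:5]}")
    for c in ("x", "y"):
        col = pd.to_numeric(table[c], errors="coerce")
        bad = table.index[~np.isfinite(col)]
        if len(bad):
            raise SchemaError(f"non-numeric or non-finite {c!r} at rows {list(bad[:5])}")
    if service_columns is None:
        service_columns = [
            c for c in table.columns if c not in REQUIRED_COLUMNS
            and pd.api.types.is_float_dtype(table[c])
        ]
    for c in service_columns:
        if c not in table.columns:
            raise SchemaError(f"missing service column {c!r}")
        col = pd.to_numeric(table[c], errors="coerce")
        bad = table.index[~np.isfinite(col)]
        if len(bad):
            raise SchemaError(
                f"non-numeric or non-finite value in column {c!r} at rows {list(bad[:5])}"
            )
        neg = table.index[col < 0]
        if len(neg):
            raise SchemaError(
                f"negative service value in column {c!r} at row {neg[0]} "
                f"(value {col[neg[0]]})"
            )
    return table


def read_plot_table(path, service_columns: list[str] | None = None) -> pd.DataFrame:
    """Read and validate a plot table CSV; row order is preserved."""
    table = pd.read_csv(path)
    return validate_plot_table(table, service_columns=service_columns)


def write_plot_table(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def write_raster_ascii(surface: RasterSurface, path, fmt: str = "%.8g") -> None:
    """Write a surface as an ESRI ASCII grid (rows north-to-south)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vals = np.where(np.isfinite(surface.values), surface.values, surface.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {surface.n_cols}\n")
        fh.write(f"nrows {surface.n_rows}\n")
        fh.write(f"xllcorner {surface.origin_x:.8g}\n")
        fh.write(f"yllcorner {surface.origin_y:.8g}\n")
        fh.write(f"cellsize {surface.cell_size_m:.8g}\n")
        fh.write(f"NODATA_value {surface.nodata:.8g}\n")
        np.savetxt(fh, vals, fmt=fmt)


def read_raster_ascii(path, transform: str = "log") -> RasterSurface:
    """Read an ESRI ASCII grid back into a :class:`RasterSurface`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    return RasterSurface(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size_m=header["cellsize"],
        values=values,
        nodata=nodata,
        transform=transform,
    )


def load_config(path) -> dict:
    """Load a YAML pipeline configuration into a plain mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg
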