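"""Delimited-text readers/writers with schema validation, config and provenance.

All tables are comma-delimited UTF-8 with a header row; columns carry unit
suffixes (µm coordinates, day ages, cm³ volumes, per-mm² densities).  Writes
use a fixed float format so write -> read -> write round-trips byte-stably.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from .simulate import SimConfig

FLOAT_FORMAT = "%.10g"

__version__ = "0.1.0"


class SchemaError(ValueError):
    """A table failed schema validation (missing column, bad dtype, NaN)."""


MEASUREMENT_SCHEMA: Dict[str, str] = {
    "age_days": "integer",
    "sex": "string",
    "length_cm": "float",
    "width_cm": "float",
    "dermis_depth_cm": "float",
}
DENSITY_SCHEMA: Dict[str, str] = {
    "age_days": "integer",
    "layer": "string",
    "rho_per_mm2": "float",
    "n_regions": "integer",
}
CELL_SCHEMA: Dict[str, str] = {
    "cell_id": "integer",
    "x_um": "float",
    "y_um": "float",
    "z_um": "float",
    "layer": "string",
    "labelled": "boolean",
    "clone_id": "integer",
}
WOUND_SCHEMA: Dict[str, str] = {
    "wound_id": "integer",
    "section_id": "integer",
    "section_thickness_um": "float",
    "n_new_hfs": "integer",
}


def _coerce(series: pd.Series, kind: str, column: str) -> pd.Series:
    if series.isna().any():
        row = int(series.index[series.isna()][0])
        raise SchemaError(f"column {column!r} has missing value at row {row}")
    try:
        if kind == "integer":
            out = pd.to_numeric(series)
            if not np.allclose(out, np.round(out)):
                raise ValueError("non-integer values")
            return out.astype(np.int64)
        if kind == "float":
            return pd.to_numeric(series).astype(float)
        if kind == "boolean":
            if series.dtype == bool:
                return series
            mapped = series.astype(str).str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            )
            if mapped.isna().any():
                raise ValueError("non-boolean values")
            return mapped.astype(bool)
        if kind == "string":
            return series.astype(str)
    except SchemaError:
        raise
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"column {column!r} has wrong dtype: {exc}") from exc
    raise SchemaError(f"unknown schema kind {kind!r} for column {column!r}")


def read_table(
    path: Union[str, Path], schema: Dict[str, str], allow_extra: bool = True
) -> pd.DataFrame:
    """Read and validate a delimited table; errors name the offending column/row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"table {path.name} missing column(s): {missing}")
    for column, kind in schema.items():
        if len(df):
            df[column] = _coerce(df[column], kind, column)
    if not allow_extra:
        extra = [c for c in df.columns if c not in schema]
        if extra:
            raise SchemaError(f"table {path.name} has unexpected column(s): {extra}")
    return df


def write_table(df: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write a table with fixed float formatting (byte-stable round trips)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_measurements(path: Union[str, Path]) -> pd.DataFrame:
    return read_table(path, MEASUREMENT_SCHEMA)


def read_densities(path: Union[str, Path]) -> pd.DataFrame:
    return read_table(path, DENSITY_SCHEMA)


def read_cells(path: Union[str, Path]) -> pd.DataFrame:
    return read_table(path, CELL_SCHEMA)


def read_wound_sections(path: Union[str, Path]) -> pd.DataFrame:
    return read_table(path, WOUND_SCHEMA)


def read_sim_config(path: Union[str, Path]) -> SimConfig:
    with open(path, encoding="utf-8") as fh:
        return SimConfig.from_dict(json.load(fh))


def write_sim_config(config: SimConfig, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True), "utf-8")
    return path


def provenance_record(config: Optional[dict], seed: int) -> dict:
    """Run provenance: config hash, seed, package version."""
    payload = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(payload).hexdigest(),
        "seed": int(seed),
        "version": __version__,
    }
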