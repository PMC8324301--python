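"""Schema-validated CSV readers and writers for the four data streams.

Files are UTF-8 CSV with a header row; writers prepend a ``# symbiofit
schema=<name> v1`` comment line that readers tolerate (and any other
``#``-prefixed line). Validation errors carry file and row context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["SCHEMAS", "read_table", "write_table"]

SCHEMA_VERSION = 1


@dataclass
class ColumnSpec:
    name: str
    dtype: str  # "str" | "int" | "float"
    required: bool = True


@dataclass
class Schema:
    name: str
    columns: list[ColumnSpec]
    row_checks: list[tuple[str, Callable[[pd.DataFrame], pd.Series]]] = field(default_factory=list)


def _prob_ok(col: pd.Series) -> pd.Series:
    return col.isna() | ((col >= 0) & (col <= 1))


SCHEMAS: dict[str, Schema] = {
    "bioassay": Schema(
        "bioassay",
        [
            ColumnSpec("strain", "str"),
            ColumnSpec("hadv2", "str"),
            ColumnSpec("dose_ug_ml", "float"),
            ColumnSpec("n_tested", "int"),
            ColumnSpec("n_dead", "int"),
        ],
        [
            ("dose_ug_ml must be >= 0", lambda df: df["dose_ug_ml"] >= 0),
            ("n_tested must be >= 1", lambda df: df["n_tested"] >= 1),
            ("n_dead must lie in [0, n_tested]", lambda df: (df["n_dead"] >= 0) & (df["n_dead"] <= df["n_tested"])),
            ("hadv2 must be positive/negative", lambda df: df["hadv2"].isin(["positive", "negative"])),
        ],
    ),
    "lifetable": Schema(
        "lifetable",
        [
            ColumnSpec("strain", "str"),
            ColumnSpec("hadv2", "str"),
            ColumnSpec("replicate", "int"),
            ColumnSpec("individual_id", "int"),
            ColumnSpec("surv_l1_l5", "int"),
            ColumnSpec("surv_l5_pupa", "int"),
            ColumnSpec("larval_duration", "float"),
            ColumnSpec("pupal_weight", "float"),
            ColumnSpec("female", "int"),
            ColumnSpec("female_pupal_duration", "float"),
            ColumnSpec("male_pupal_duration", "float"),
            ColumnSpec("emerged", "int"),
            ColumnSpec("copulated", "int"),
            ColumnSpec("female_longevity", "float"),
            ColumnSpec("male_longevity", "float"),
            ColumnSpec("fecundity", "float"),
            ColumnSpec("hatch_rate", "float"),
        ],
        [
            ("survival flags must be 0/1", lambda df: df["surv_l1_l5"].isin([0, 1]) & df["surv_l5_pupa"].isin([0, 1])),
            ("emerged/copulated/female must be 0/1", lambda df: df["emerged"].isin([0, 1]) & df["copulated"].isin([0, 1]) & df["female"].isin([0, 1])),
            ("hatch_rate must lie in [0, 1]", lambda df: _prob_ok(df["hatch_rate"])),
            ("fecundity must be >= 0", lambda df: df["fecundity"].isna() | (df["fecundity"] >= 0)),
        ],
    ),
    "ratings": Schema(
        "ratings",
        [
            ColumnSpec("line_id", "str"),
            ColumnSpec("hadv2", "str"),
            ColumnSpec("population", "str", required=False),
            ColumnSpec("year", "int", required=False),
            ColumnSpec("diet", "str"),
            ColumnSpec("rating", "float"),
        ],
        [
            ("rating must be >= 0", lambda df: df["rating"] >= 0),
            ("diet must be bt/non_bt", lambda df: df["diet"].isin(["bt", "non_bt"])),
        ],
    ),
    "prevalence": Schema(
        "prevalence",
        [
            ColumnSpec("location", "str"),
            ColumnSpec("province", "str"),
            ColumnSpec("year", "int"),
            ColumnSpec("n_tested", "int"),
            ColumnSpec("n_positive", "int"),
            ColumnSpec("bt_crop", "str"),
            ColumnSpec("bt_intro_year", "float", required=False),
            ColumnSpec("bt_proportion", "float", required=False),
            ColumnSpec("rainfall_mm", "float", required=False),
            ColumnSpec("temp_c", "float", required=False),
            ColumnSpec("altitude_m", "float", required=False),
        ],
        [
            ("n_tested must be >= 1", lambda df: df["n_tested"] >= 1),
            ("n_positive must lie in [0, n_tested]", lambda df: (df["n_positive"] >= 0) & (df["n_positive"] <= df["n_tested"])),
            ("bt_crop must be Bt/non-Bt", lambda df: df["bt_crop"].isin(["Bt", "non-Bt"])),
        ],
    ),
}

_DTYPES = {"str": str, "int": "int64", "float": float}


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against one of the stream schemas."""
    if schema_name not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    df = pd.read_csv(path, comment="#")
    missing = [c.name for c in schema.columns if c.required and c.name not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    for col in schema.columns:
        if col.name not in df.columns:
            continue
        try:
            if col.dtype == "int" and df[col.name].isna().any():
                df[col.name] = df[col.name].astype(float)
            else:
                df[col.name] = df[col.name].astype(_DTYPES[col.dtype])
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: column {col.name!r} is not of type {col.dtype}: {exc}") from exc
    for message, check in schema.row_checks:
        cols_needed = True
        try:
            ok = check(df)
        except KeyError:
            cols_needed = False
        if cols_needed and not ok.all():
            bad = int(np.nonzero(~ok.to_numpy())[0][0])
            # +2: header line and 1-based numbering (comment lines shift this
            # further, but the row index is the stable handle)
            raise ValidationError(f"{path}:row {bad + 2}: {message}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema_name: str) -> None:
    """Write a stream table as CSV with a schema-version comment header."""
    if schema_name not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema_name!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# symbiofit schema={schema_name} v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)
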