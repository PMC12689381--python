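"""Cohort file I/O and record/country-level quality-control exclusions.

Exclusion rules (strict boundaries, equality survives):

* ``SPEEDER`` — time to completion under 7 minutes;
* ``FLATLINE`` — standard deviation of the 47 item ratings under 0.2
  (population SD, divisor n, recomputed from the ratings);
* ``NOT_UNDERSTOOD`` — respondent answered that the assessment was not easy
  to understand;
* ``SMALL_COUNTRY`` — country with fewer than 1,000 post-QC responses.

Record-level rules are applied before the country-count rule, so country
counts reflect clean records. Every exclusion is recorded in an auditable log
that satisfies the conservation identity kept + excluded = input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .synthetic import ITEM_COLUMNS, QC_COLUMNS

REQUIRED_COLUMNS = (
    ["id", "country", "age_group", "sex", "upf_freq", "exercise_freq", "income_band"]
    + ITEM_COLUMNS
    + QC_COLUMNS
)

MIN_COMPLETION_MINUTES = 7.0
MIN_RATING_SD = 0.2
MIN_COUNTRY_N = 1000

_BOOL_COLUMNS = {"comprehension_ok"}


@dataclass
class ExclusionLog:
    """Audit log of one exclusion pass.

    ``reasons`` maps each excluded record id to all reason codes it carries; a
    record is counted once in the kept/excluded arithmetic regardless of how
    many reasons apply.
    """

    input_count: int
    kept_count: int
    reasons: dict[str, list[str]] = field(default_factory=dict)

    @property
    def excluded_count(self) -> int:
        return len(self.reasons)

    @property
    def counts_per_reason(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for codes in self.reasons.values():
            for c in codes:
                out[c] = out.get(c, 0) + 1
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "input_count": self.input_count,
            "kept_count": self.kept_count,
            "excluded_count": self.excluded_count,
            "counts_per_reason": self.counts_per_reason,
            "reasons": self.reasons,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _schema_path(path: Path) -> Path:
    return path.with_name(path.stem + ".schema.json")


def build_schema(df: pd.DataFrame, extra: dict | None = None) -> dict:
    """Describe a cohort table: column order, storage dtype and (for object /
    string columns) observed category levels. ``extra`` entries (e.g. the
    feature dictionary or item polarities) are merged in verbatim."""
    columns = {}
    for col in df.columns:
        s = df[col]
        if col in _BOOL_COLUMNS or s.dtype == bool:
            kind = "bool"
        elif pd.api.types.is_integer_dtype(s):
            kind = "int"
        elif pd.api.types.is_float_dtype(s):
            kind = "float"
        else:
            kind = "string"
        entry: dict = {"dtype": kind}
        if kind == "string":
            entry["levels"] = sorted(x for x in s.dropna().unique())
        columns[col] = entry
    schema = {"columns": columns}
    if extra:
        schema.update(extra)
    return schema


def write_cohort(df: pd.DataFrame, path: str | Path, schema_extra: dict | None = None) -> Path:
    """Write a cohort to CSV or Parquet (by extension) with a JSON schema sidecar.

    Round-trips losslessly through :func:`read_cohort` for both formats.
    """
    path = Path(path)
    schema = build_schema(df, schema_extra)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    elif path.suffix == ".csv":
        df.to_csv(path, index=False)
    else:
        raise SchemaError(f"unsupported cohort format: {path.suffix!r} (use .csv or .parquet)")
    _schema_path(path).write_text(json.dumps(schema, indent=1))
    return path


def read_cohort(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a cohort written by :func:`write_cohort`, validating against its
    schema sidecar. Returns ``(dataframe, schema)``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spath = _schema_path(path)
    if not spath.exists():
        raise SchemaError(f"schema sidecar not found: {spath}")
    schema = json.loads(spath.read_text())

    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    elif path.suffix == ".csv":
        dtypes = {}
        for col, entry in schema["columns"].items():
            dtypes[col] = {
                "string": "string",
                "int": "int64",
                "float": "float64",
                "bool": "boolean",
            }[entry["dtype"]]
        df = pd.read_csv(path, dtype=dtypes)
        bool_cols = [c for c, e in schema["columns"].items() if e["dtype"] == "bool"]
        for c in bool_cols:
            df[c] = df[c].astype(bool)
    else:
        raise SchemaError(f"unsupported cohort format: {path.suffix!r}")

    for col in schema["columns"]:
        if col not in df.columns:
            raise SchemaError(f"cohort file is missing required column {col!r}")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file is missing required column(s): {missing}")
    # normalise string columns to pandas string dtype for format parity
    for col, entry in schema["columns"].items():
        if entry["dtype"] == "string":
            df[col] = df[col].astype("string")
    return df, schema


def apply_record_exclusions(
    df: pd.DataFrame, recompute_sd: bool = True
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the record-level QC rules, returning kept records and the log.

    ``recompute_sd``: recompute the flat-response SD from the 47 item ratings
    (population SD) rather than trusting the stored ``rating_sd`` column.
    """
    for col in QC_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"QC field {col!r} missing; refusing to silently keep records")
    if recompute_sd:
        sd = df[ITEM_COLUMNS].to_numpy(float).std(axis=1)
    else:
        sd = df["rating_sd"].to_numpy(float)

    speeder = df["completion_minutes"].to_numpy(float) < MIN_COMPLETION_MINUTES
    flatline = sd < MIN_RATING_SD
    confused = ~df["comprehension_ok"].to_numpy(bool)
    excluded = speeder | flatline | confused

    reasons: dict[str, list[str]] = {}
    ids = df["id"].astype(str).to_numpy()
    for mask, code in ((speeder, "SPEEDER"), (flatline, "FLATLINE"), (confused, "NOT_UNDERSTOOD")):
        for rid in ids[mask]:
            reasons.setdefault(rid, []).append(code)

    kept = df.loc[~excluded].reset_index(drop=True)
    log = ExclusionLog(input_count=len(df), kept_count=len(kept), reasons=reasons)
    return kept, log


def apply_country_exclusions(
    df: pd.DataFrame, min_n: int = MIN_COUNTRY_N
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop all records from countries with fewer than ``min_n`` responses
    (strict: a country with exactly ``min_n`` survives). Apply after
    record-level exclusions so counts reflect clean records."""
    counts = df["country"].value_counts()
    small = set(counts.index[counts < min_n])
    mask = df["country"].isin(small).to_numpy()
    reasons = {str(rid): ["SMALL_COUNTRY"] for rid in df.loc[mask, "id"]}
    kept = df.loc[~mask].reset_index(drop=True)
    return kept, ExclusionLog(input_count=len(df), kept_count=len(kept), reasons=reasons)
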