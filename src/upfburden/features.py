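"""One-hot feature matrix construction for the distress classifier.

Every categorical life-context answer becomes a block of 0/1 indicator
columns; checklist items (traumas, medical conditions, substances) are single
0/1 columns. Demographics (country, age group, sex) are included as
predictors, which lets a tree model account for the hierarchical survey
structure without explicit random effects. The default dictionary yields 108
feature columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .synthetic import (
    EXTRA_CATEGORICALS,
    EXERCISE_LEVELS,
    INCOME_LEVELS,
    INCOME_MISSING,
    MEDICAL_ITEMS,
    SUBSTANCE_ITEMS,
    TRAUMA_ITEMS,
    UPF_LEVELS,
    GenerativeConfig,
)

UPF_FEATURE_PREFIX = "upf_freq="


@dataclass
class FeatureMatrix:
    """Design matrix plus labels and the metadata needed for stratified
    reporting. One-hot groups sum to 1 per record per categorical."""

    X: np.ndarray
    feature_names: list[str]
    y: np.ndarray | None = None
    meta: pd.DataFrame | None = None  # id, country, age_group, sex per record

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def upf_columns(self) -> list[int]:
        cols = [i for i, n in enumerate(self.feature_names) if n.startswith(UPF_FEATURE_PREFIX)]
        if not cols:
            raise ValidationError("feature matrix has no UPF exposure block")
        return cols

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X.copy(),
            feature_names=list(self.feature_names),
            y=None if self.y is None else self.y.copy(),
            meta=None if self.meta is None else self.meta.copy(),
        )


def default_feature_dictionary(config: GenerativeConfig | None = None) -> dict:
    """Feature dictionary matching the synthetic generator's schema: an ordered
    mapping of categorical columns to their level lists plus the binary
    checklist columns. With the default config this yields 108 features."""
    cfg = config or GenerativeConfig(n_respondents=1)
    categorical: dict[str, list[str]] = {
        "age_group": list(cfg.age_groups),
        "sex": list(cfg.sex_labels),
        "country": list(cfg.countries),
        "upf_freq": list(UPF_LEVELS),
        "exercise_freq": list(EXERCISE_LEVELS),
        "income_band": list(INCOME_LEVELS) + [INCOME_MISSING],
    }
    for col, (levels, _) in EXTRA_CATEGORICALS.items():
        categorical[col] = list(levels)
    binary = list(TRAUMA_ITEMS) + list(MEDICAL_ITEMS) + list(SUBSTANCE_ITEMS)
    return {"categorical": categorical, "binary": binary}


def feature_names_from_dictionary(feature_dictionary: dict) -> list[str]:
    names: list[str] = []
    for col, levels in feature_dictionary["categorical"].items():
        names.extend(f"{col}={level}" for level in levels)
    names.extend(feature_dictionary["binary"])
    return names


def build_feature_matrix(
    df: pd.DataFrame,
    feature_dictionary: dict | None = None,
    label_col: str = "distressed",
) -> FeatureMatrix:
    """One-hot encode a (scored) cohort into a deterministic column order.

    Missing income is encoded as its own 'Not available' level. An unseen
    category level raises an error naming the record and column.
    """
    fd = feature_dictionary or default_feature_dictionary()
    names = feature_names_from_dictionary(fd)
    n = len(df)
    X = np.zeros((n, len(names)), dtype=np.float64)

    col_offset = 0
    ids = df["id"].astype(str).to_numpy() if "id" in df.columns else np.arange(n).astype(str)
    for col, levels in fd["categorical"].items():
        if col not in df.columns:
            raise SchemaError(f"cohort is missing categorical column {col!r}")
        values = df[col]
        if col == "income_band":
            values = values.fillna(INCOME_MISSING)
        codes = values.map({level: i for i, level in enumerate(levels)})
        if codes.isna().any():
            bad = int(np.flatnonzero(codes.isna().to_numpy())[0])
            raise SchemaError(
                f"record {ids[bad]!r}: unseen level {values.iloc[bad]!r} in column {col!r}"
            )
        X[np.arange(n), col_offset + codes.to_numpy(int)] = 1.0
        col_offset += len(levels)
    for col in fd["binary"]:
        if col not in df.columns:
            raise SchemaError(f"cohort is missing binary column {col!r}")
        v = df[col].to_numpy()
        if not np.isin(v, (0, 1)).all():
            raise SchemaError(f"binary column {col!r} contains non-0/1 values")
        X[:, col_offset] = v
        col_offset += 1

    y = df[label_col].to_numpy(bool) if label_col in df.columns else None
    meta_cols = [c for c in ("id", "country", "age_group", "sex") if c in df.columns]
    meta = df[meta_cols].reset_index(drop=True) if meta_cols else None
    return FeatureMatrix(X=X, feature_names=names, y=y, meta=meta)
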