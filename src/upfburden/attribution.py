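"""Per-record, per-feature additive attributions for the fitted classifier.

Attributions are exact TreeSHAP values computed natively by XGBoost
(``pred_contribs=True``) in margin (log-odds) space, which is sign-stable and
standard for tree ensembles. The sign convention follows the reporting
orientation: positive values push the classification toward POSITIVE wellbeing
(away from distress), so the raw contributions toward the distress margin are
negated. Per record, ``base_value + sum(attributions)`` equals the negated
model margin — the defining additivity identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .classifier import ModelBundle
from .errors import ValidationError
from .features import FeatureMatrix


@dataclass
class ShapSummary:
    """Attribution matrix (n_records x n_features, positive = toward positive
    wellbeing), the shared base value, and features ordered by mean |value|."""

    values: np.ndarray
    base_value: float
    feature_names: list[str]

    @property
    def mean_abs(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)

    @property
    def feature_order(self) -> list[str]:
        order = np.argsort(-self.mean_abs)
        return [self.feature_names[i] for i in order]


def compute_attributions(bundle: ModelBundle, fm: FeatureMatrix) -> ShapSummary:
    """Exact tree-path attributions for a gradient-boosted-trees bundle.

    Raises for non-tree algorithms (use a tree model, or a model-agnostic
    explainer outside this package).
    """
    if bundle.algorithm != "gradient_boosted_trees":
        raise ValidationError(
            f"attributions require a tree model; got {bundle.algorithm!r} "
            "(refit with algorithm='gradient_boosted_trees' or use a "
            "model-agnostic explainer)"
        )
    if list(fm.feature_names) != list(bundle.feature_names):
        raise ValidationError("feature names differ between bundle and matrix")
    import xgboost as xgb

    booster = bundle.model.model_.get_booster()
    contribs = booster.predict(
        xgb.DMatrix(np.asarray(fm.X, dtype=np.float64)), pred_contribs=True
    )
    # contribs[:, :-1] push toward the distress margin; flip so positive means
    # toward positive wellbeing. Last column is the shared bias.
    values = -contribs[:, :-1].astype(np.float64)
    base_value = -float(contribs[0, -1])
    return ShapSummary(values=values, base_value=base_value, feature_names=list(fm.feature_names))


def rank_stability(fold_bundles: list[ModelBundle], fm: FeatureMatrix) -> float:
    """Mean Spearman rank correlation of mean-|attribution| feature rankings
    across all pairwise fold-model combinations."""
    if len(fold_bundles) < 2:
        raise ValidationError("need at least two fold models")
    names = fold_bundles[0].feature_names
    for b in fold_bundles[1:]:
        if list(b.feature_names) != list(names):
            raise ValidationError("fold models have mismatched feature spaces")
    importances = [compute_attributions(b, fm).mean_abs for b in fold_bundles]
    rhos = [
        spearmanr(importances[i], importances[j]).statistic
        for i, j in combinations(range(len(importances)), 2)
    ]
    return float(np.mean(rhos))


def beeswarm_export(
    shap_summary: ShapSummary, fm: FeatureMatrix, features_of_interest: list[str]
) -> pd.DataFrame:
    """Tidy per-(record, feature) attribution table with a selected flag (the
    one-hot column value), i.e. the data behind a beeswarm summary plot."""
    missing = [f for f in features_of_interest if f not in shap_summary.feature_names]
    if missing:
        raise ValidationError(f"unknown features: {missing}")
    rows = []
    for feat in features_of_interest:
        j = shap_summary.feature_names.index(feat)
        rows.append(
            pd.DataFrame(
                {
                    "record": np.arange(fm.n_records),
                    "feature": feat,
                    "attribution": shap_summary.values[:, j],
                    "selected": fm.X[:, j].astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
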