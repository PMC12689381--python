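"""Binary clinical-distress classifier with evaluation and sensitivity analyses.

The core estimator is gradient-boosted trees (XGBoost), which captures
nonlinearities and cross-level interactions among the one-hot life-context
features; logistic regression, Bernoulli naive Bayes and random forest run
through the identical contract for comparison. Evaluation uses stratified
k-fold cross-validation (k in {3, 5, 10}) and repeated stratified random
train/test splits; precision/recall/F1 are macro-averaged over the two classes
("average performance across positive and negative prediction models").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.naive_bayes import BernoulliNB
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .errors import ValidationError
from .features import FeatureMatrix

ALGORITHMS = ("gradient_boosted_trees", "logistic_regression", "naive_bayes", "random_forest")


class DistressClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn estimator predicting clinical mental distress (negative
    composite score) from one-hot life-context features.

    Parameters
    ----------
    algorithm : one of ``gradient_boosted_trees`` (default), ``logistic_regression``,
        ``naive_bayes``, ``random_forest``.
    n_estimators, max_depth, learning_rate : tree-model hyperparameters
        (moderate depth and shrinkage, no early stopping); ignored by the
        non-tree algorithms.
    random_state : seed for all internal randomness; fits are deterministic
        given the seed (single-threaded).
    """

    def __init__(
        self,
        algorithm: str = "gradient_boosted_trees",
        n_estimators: int = 150,
        max_depth: int = 4,
        learning_rate: float = 0.1,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _make_model(self):
        if self.algorithm == "gradient_boosted_trees":
            return XGBClassifier(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                learning_rate=self.learning_rate,
                random_state=self.random_state,
                n_jobs=1,
                tree_method="hist",
                eval_metric="logloss",
            )
        if self.algorithm == "logistic_regression":
            return LogisticRegression(max_iter=2000, random_state=self.random_state)
        if self.algorithm == "naive_bayes":
            return BernoulliNB()
        if self.algorithm == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_depth=None,
                random_state=self.random_state,
                n_jobs=1,
            )
        raise ValidationError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValidationError("both classes must be present to fit the classifier")
        self.model_ = self._make_model()
        self.model_.fit(X, y)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=np.float64))

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_margin(self, X):
        """Raw margin (log-odds of distress) for tree models; logit of the
        predicted probability otherwise."""
        check_is_fitted(self, "model_")
        if self.algorithm == "gradient_boosted_trees":
            import xgboost as xgb

            booster = self.model_.get_booster()
            return booster.predict(
                xgb.DMatrix(np.asarray(X, dtype=np.float64)), output_margin=True
            )
        p = np.clip(self.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
        return logit(p)


@dataclass
class EvalMetrics:
    """Mean evaluation metrics with per-fold (or per-repeat) detail."""

    auc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_fold: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class ModelBundle:
    """A fitted classifier plus everything needed to score new records."""

    model: DistressClassifier
    algorithm: str
    feature_names: list[str]
    seed: int
    metrics: EvalMetrics | None = None

    def save(self, path: str | Path) -> None:
        """Persist a gradient-boosted-trees bundle as booster JSON plus a
        metadata sidecar (text formats only)."""
        path = Path(path)
        if self.algorithm != "gradient_boosted_trees":
            raise ValidationError("only gradient_boosted_trees bundles support JSON persistence")
        self.model.model_.get_booster().save_model(str(path))
        meta = {
            "algorithm": self.algorithm,
            "feature_names": self.feature_names,
            "seed": self.seed,
            "params": self.model.get_params(),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        clf = DistressClassifier(**meta["params"])
        model = clf._make_model()
        model.load_model(str(path))
        clf.model_ = model
        clf.classes_ = np.array([0, 1])
        clf.n_features_in_ = len(meta["feature_names"])
        return cls(
            model=clf,
            algorithm=meta["algorithm"],
            feature_names=meta["feature_names"],
            seed=meta["seed"],
        )


def _macro_metrics(y_true, y_pred, proba) -> dict[str, float]:
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="macro", zero_division=0
    )
    return {
        "auc": float(roc_auc_score(y_true, proba)),
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
    }


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Accuracy/precision/recall/F1 from pooled confusion counts (positive
    class); F1 is the harmonic mean of precision and recall."""
    total = tp + fp + fn + tn
    if total == 0:
        raise ValidationError("empty confusion matrix")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "accuracy": (tp + tn) / total,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def fit_classifier(fm: FeatureMatrix, algorithm: str = "gradient_boosted_trees", seed: int = 0,
                   **params) -> ModelBundle:
    """Fit a classifier on the full feature matrix and wrap it in a bundle."""
    if fm.y is None:
        raise ValidationError("feature matrix has no labels")
    clf = DistressClassifier(algorithm=algorithm, random_state=seed, **params)
    clf.fit(fm.X, fm.y)
    return ModelBundle(model=clf, algorithm=algorithm, feature_names=list(fm.feature_names), seed=seed)


def _evaluate_splits(fm: FeatureMatrix, algorithm: str, splits, seed: int, **params) -> EvalMetrics:
    rows = []
    for train_idx, test_idx in splits:
        clf = DistressClassifier(algorithm=algorithm, random_state=seed, **params)
        clf.fit(fm.X[train_idx], fm.y[train_idx])
        proba = clf.predict_proba(fm.X[test_idx])[:, 1]
        pred = (proba >= 0.5).astype(int)
        rows.append(_macro_metrics(fm.y[test_idx].astype(int), pred, proba))
    per_fold = pd.DataFrame(rows)
    means = per_fold.mean()
    return EvalMetrics(
        auc=float(means["auc"]),
        accuracy=float(means["accuracy"]),
        precision=float(means["precision"]),
        recall=float(means["recall"]),
        f1=float(means["f1"]),
        per_fold=per_fold,
    )


def cross_validate(fm: FeatureMatrix, algorithm: str = "gradient_boosted_trees",
                   k: int = 5, seed: int = 0, **params) -> EvalMetrics:
    """Stratified k-fold cross-validation; metrics averaged across folds."""
    if k < 2:
        raise ValidationError("k must be at least 2")
    if fm.y is None:
        raise ValidationError("feature matrix has no labels")
    minority = int(min(np.bincount(fm.y.astype(int))))
    if k > minority:
        raise ValidationError(f"k={k} exceeds minority class size {minority}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return _evaluate_splits(fm, algorithm, skf.split(fm.X, fm.y), seed, **params)


def repeated_split_eval(fm: FeatureMatrix, algorithm: str = "gradient_boosted_trees",
                        train_frac: float = 0.65, n_repeats: int = 5, seed: int = 0,
                        **params) -> EvalMetrics:
    """Repeated stratified random train/test splits (default 65/35); the
    reported metric is the mean over repeats of the per-class (macro) metric."""
    if not 0 < train_frac < 1:
        raise ValidationError("train_frac must be in (0, 1)")
    if fm.y is None:
        raise ValidationError("feature matrix has no labels")
    sss = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=train_frac, random_state=seed
    )
    return _evaluate_splits(fm, algorithm, sss.split(fm.X, fm.y), seed, **params)


@dataclass
class SensitivityResult:
    delta_auc: float  # AUC(full) - AUC(reduced)
    dropped_features: list[str]
    auc_full: float
    auc_reduced: float


def _single_split_auc(X, y, algorithm, seed, **params) -> float:
    sss = StratifiedShuffleSplit(n_splits=1, train_size=0.65, random_state=seed)
    (train_idx, test_idx), = sss.split(X, y)
    clf = DistressClassifier(algorithm=algorithm, random_state=seed, **params)
    clf.fit(X[train_idx], y[train_idx])
    return float(roc_auc_score(y[test_idx].astype(int), clf.predict_proba(X[test_idx])[:, 1]))


def drop_correlated_sensitivity(fm: FeatureMatrix, algorithm: str = "gradient_boosted_trees",
                                r_threshold: float = 0.80, seed: int = 0,
                                **params) -> SensitivityResult:
    """Drop the later-ordered member of every feature pair with pairwise
    |r| > r_threshold, refit, and report the AUC change (full - reduced)."""
    if fm.n_features < 2:
        raise ValidationError("need at least 2 features")
    X = fm.X
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[~np.isfinite(corr)] = 0.0  # constant columns correlate with nothing
    drop: set[int] = set()
    n = fm.n_features
    for i in range(n):
        if i in drop or sd[i] == 0:
            continue
        for j in range(i + 1, n):
            if j in drop or sd[j] == 0:
                continue
            if abs(corr[i, j]) > r_threshold:
                drop.add(j)
    keep = [i for i in range(n) if i not in drop]
    if not keep:
        raise ValidationError("all features would be dropped")
    auc_full = _single_split_auc(X, fm.y, algorithm, seed, **params)
    auc_reduced = _single_split_auc(X[:, keep], fm.y, algorithm, seed, **params)
    return SensitivityResult(
        delta_auc=auc_full - auc_reduced,
        dropped_features=[fm.feature_names[j] for j in sorted(drop)],
        auc_full=auc_full,
        auc_reduced=auc_reduced,
    )


def exclude_exposure_sensitivity(fm: FeatureMatrix, algorithm: str = "gradient_boosted_trees",
                                 exposure_columns: list[str] | None = None, seed: int = 0,
                                 **params) -> SensitivityResult:
    """Refit without the exposure block (default: the five UPF indicator
    columns) and report the AUC change (full - excluded)."""
    if exposure_columns is None:
        exposure_columns = [fm.feature_names[i] for i in fm.upf_columns()]
    missing = [c for c in exposure_columns if c not in fm.feature_names]
    if missing:
        raise ValidationError(f"exposure columns absent from feature matrix: {missing}")
    drop_idx = [fm.feature_names.index(c) for c in exposure_columns]
    keep = [i for i in range(fm.n_features) if i not in set(drop_idx)]
    auc_full = _single_split_auc(fm.X, fm.y, algorithm, seed, **params)
    auc_reduced = _single_split_auc(fm.X[:, keep], fm.y, algorithm, seed, **params)
    return SensitivityResult(
        delta_auc=auc_full - auc_reduced,
        dropped_features=list(exposure_columns),
        auc_full=auc_full,
        auc_reduced=auc_reduced,
    )


def calibration_curve(model: DistressClassifier, X_test, y_test, n_bins: int = 10) -> pd.DataFrame:
    """Reliability table over equal-width probability bins: mean predicted
    probability, observed distress rate and count per bin (empty bins keep an
    n=0 row with undefined rates)."""
    proba = model.predict_proba(X_test)[:, 1]
    y = np.asarray(y_test).astype(int)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(proba, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = which == b
        n = int(m.sum())
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "mean_predicted": float(proba[m].mean()) if n else np.nan,
                "observed_rate": float(y[m].mean()) if n else np.nan,
                "n": n,
            }
        )
    return pd.DataFrame(rows)
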