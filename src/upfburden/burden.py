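"""Counterfactual burden estimators — the headline quantities.

Two routes to the fraction of distress linked to the exposure:

* **data** — arithmetic on observed prevalences: the linked percentage is the
  overall distressed percentage minus the distressed percentage among the
  reference-exposure ('Rarely/Never') group, and the burden is the linked
  percentage divided by the baseline distressed percentage. No confound
  control.
* **simulation** (g-computation / model-based standardization) — through the
  fitted classifier: predict distress on a test set, force every record's
  exposure block to the reference category leaving all other features
  untouched, re-predict, and take the drop in the predicted-distressed
  percentage. Averaged over iterations of randomly drawn test data (model
  refit per iteration by default), reported per demographic stratum.

The simulation denominator is the MODEL-PREDICTED distressed percentage on the
unmanipulated test set (the observed prevalence is available via
``denominator='observed'``). The class decision is a 0.5 probability
threshold; ``decision='expected'`` switches to the mean predicted probability,
the standard g-computation estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from .classifier import DistressClassifier, ModelBundle
from .errors import ValidationError
from .features import UPF_FEATURE_PREFIX, FeatureMatrix
from .synthetic import UPF_REFERENCE


@dataclass
class BurdenEstimate:
    """Linked-percentage / burden pair for one stratum and method.

    ``linked_pct`` is in percentage points of the (stratum) sample;
    ``burden_pct = linked_pct / baseline_pct * 100``.
    """

    method: str  # "data" | "simulation"
    stratum: str
    linked_pct: float
    baseline_pct: float
    burden_pct: float
    n_iterations: int = 1
    per_iteration: pd.DataFrame = field(default_factory=pd.DataFrame)


def set_reference_exposure(fm: FeatureMatrix) -> FeatureMatrix:
    """Force every record's UPF one-hot block to the reference category
    ('Rarely/Never'); all other columns are bit-identical."""
    cols = fm.upf_columns()
    ref_col = next(
        i for i in cols if fm.feature_names[i] == f"{UPF_FEATURE_PREFIX}{UPF_REFERENCE}"
    )
    out = fm.copy()
    out.X[:, cols] = 0.0
    out.X[:, ref_col] = 1.0
    return out


def linked_percentage_data(overall_prev_pct: float, reference_prev_pct: float) -> float:
    """Percentage points of the sample with distress linked to the exposure:
    overall minus reference-group prevalence (both in percent). A negative
    result (possible in strata) is returned signed with a warning."""
    if not (0 <= overall_prev_pct <= 100 and 0 <= reference_prev_pct <= 100):
        raise ValidationError("prevalences must be percentages in [0, 100]")
    linked = overall_prev_pct - reference_prev_pct
    if linked < 0:
        warnings.warn(
            "reference-group prevalence exceeds overall prevalence; "
            "linked percentage is negative", stacklevel=2,
        )
    return linked


def burden_ratio(linked_pct: float, baseline_pct: float) -> float:
    """Burden as a percentage of baseline distress: linked / baseline * 100."""
    if baseline_pct == 0:
        raise ValidationError("baseline prevalence is zero; burden undefined")
    return linked_pct / baseline_pct * 100.0


def data_burden_estimate(
    overall_prev_pct: float, reference_prev_pct: float, stratum: str = "All"
) -> BurdenEstimate:
    linked = linked_percentage_data(overall_prev_pct, reference_prev_pct)
    return BurdenEstimate(
        method="data",
        stratum=stratum,
        linked_pct=linked,
        baseline_pct=overall_prev_pct,
        burden_pct=burden_ratio(linked, overall_prev_pct),
    )


def _predicted_distress_pct(proba: np.ndarray, decision: str) -> float:
    if decision == "threshold":
        return float((proba >= 0.5).mean() * 100.0)
    if decision == "expected":
        return float(proba.mean() * 100.0)
    raise ValidationError(f"unknown decision rule {decision!r}")


def simulation_burden(
    fm: FeatureMatrix,
    algorithm: str = "gradient_boosted_trees",
    strata: dict[str, np.ndarray] | None = None,
    n_iterations: int = 10,
    test_frac: float = 0.35,
    seed: int = 0,
    refit: bool = True,
    model_bundle: ModelBundle | None = None,
    denominator: str = "model",
    decision: str = "threshold",
    **params,
) -> list[BurdenEstimate]:
    """Simulation-based (g-computation) burden estimates.

    Per iteration a stratified random test set of ``test_frac`` of the records
    is drawn; with ``refit=True`` (default) the classifier is refit on the
    complementary training records, otherwise ``model_bundle`` scores every
    test draw. Baseline = predicted distressed %, counterfactual = predicted
    distressed % after forcing the exposure to 'Rarely/Never', linked =
    baseline - counterfactual, burden = linked / baseline. Reported values are
    per-stratum means over iterations; strata with no test records in an
    iteration are skipped with a warning.

    ``strata`` maps a stratum name to a boolean record mask; the "All" stratum
    is always included.
    """
    if fm.y is None:
        raise ValidationError("feature matrix has no labels")
    if not refit and model_bundle is None:
        raise ValidationError("refit=False requires a fitted model_bundle")
    if denominator not in ("model", "observed"):
        raise ValidationError(f"unknown denominator {denominator!r}")
    strata = dict(strata or {})
    masks: dict[str, np.ndarray] = {"All": np.ones(fm.n_records, dtype=bool)}
    for name, m in strata.items():
        m = np.asarray(m, dtype=bool)
        if m.shape != (fm.n_records,):
            raise ValidationError(f"stratum {name!r} mask has wrong shape")
        masks[name] = m

    sss = StratifiedShuffleSplit(
        n_splits=n_iterations, test_size=test_frac, random_state=seed
    )
    rows: list[dict] = []
    for it, (train_idx, test_idx) in enumerate(sss.split(fm.X, fm.y)):
        if refit:
            clf = DistressClassifier(algorithm=algorithm, random_state=seed, **params)
            clf.fit(fm.X[train_idx], fm.y[train_idx])
        else:
            clf = model_bundle.model
        X_test = fm.X[test_idx]
        test_fm = FeatureMatrix(X=X_test, feature_names=list(fm.feature_names))
        proba_obs = clf.predict_proba(X_test)[:, 1]
        proba_cf = clf.predict_proba(set_reference_exposure(test_fm).X)[:, 1]
        for name, mask in masks.items():
            sel = mask[test_idx]
            if not sel.any():
                warnings.warn(
                    f"stratum {name!r} has no test records in iteration {it}; skipped",
                    stacklevel=2,
                )
                continue
            baseline = (
                _predicted_distress_pct(proba_obs[sel], decision)
                if denominator == "model"
                else float(fm.y[test_idx][sel].mean() * 100.0)
            )
            counterfactual = _predicted_distress_pct(proba_cf[sel], decision)
            linked = _predicted_distress_pct(proba_obs[sel], decision) - counterfactual
            rows.append(
                {
                    "iteration": it,
                    "stratum": name,
                    "baseline_pct": baseline,
                    "counterfactual_pct": counterfactual,
                    "linked_pct": linked,
                    "n_test": int(sel.sum()),
                }
            )

    detail = pd.DataFrame(rows)
    estimates: list[BurdenEstimate] = []
    for name in masks:
        sub = detail[detail["stratum"] == name]
        if sub.empty:
            continue
        linked = float(sub["linked_pct"].mean())
        baseline = float(sub["baseline_pct"].mean())
        estimates.append(
            BurdenEstimate(
                method="simulation",
                stratum=name,
                linked_pct=linked,
                baseline_pct=baseline,
                burden_pct=burden_ratio(linked, baseline),
                n_iterations=int(sub["iteration"].nunique()),
                per_iteration=sub.reset_index(drop=True),
            )
        )
    return estimates


def age_sex_strata(fm: FeatureMatrix, age_bands: dict[str, list[str]] | None = None,
                   by_sex: bool = False) -> dict[str, np.ndarray]:
    """Build demographic stratum masks from the feature-matrix metadata.

    Default age bands group the survey's age groups into 18-34 / 35-64 / 65+.
    """
    if fm.meta is None or "age_group" not in fm.meta.columns:
        raise ValidationError("feature matrix metadata lacks age_group")
    if age_bands is None:
        age_bands = {
            "18-34": ["18-24", "25-34"],
            "35-64": ["35-44", "45-54", "55-64"],
            "65+": ["65-74", "75+"],
        }
    ages = fm.meta["age_group"].to_numpy()
    out: dict[str, np.ndarray] = {}
    for band, groups in age_bands.items():
        band_mask = np.isin(ages, groups)
        if by_sex and "sex" in fm.meta.columns:
            for sx in pd.unique(fm.meta["sex"]):
                out[f"{band}|{sx}"] = band_mask & (fm.meta["sex"].to_numpy() == sx)
        else:
            out[band] = band_mask
    return out


def burden_report(
    data_estimates: list[BurdenEstimate], simulation_estimates: list[BurdenEstimate]
) -> pd.DataFrame:
    """Combine data- and simulation-based estimates into one tidy table
    (rows = stratum x method; columns = linked %, baseline %, burden %)."""
    rows = []
    for est in list(data_estimates) + list(simulation_estimates):
        rows.append(
            {
                "stratum": est.stratum,
                "method": est.method,
                "linked_pct": est.linked_pct,
                "baseline_pct": est.baseline_pct,
                "burden_pct": est.burden_pct,
                "n_iterations": est.n_iterations,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values(["stratum", "method"]).reset_index(drop=True)
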