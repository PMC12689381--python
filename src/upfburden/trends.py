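"""Dose-response and confound-stratified descriptive statistics.

UPF consumption frequency is encoded ordinally (Rarely/Never = 1 ... Several
times a day = 5) and the declining composite-score trend is characterised by
ordinary least squares on the numeric codes. Group contrasts use Welch's
two-sided t-test with no multiple-testing correction (the 47 items measure one
underlying construct, so independence-based corrections do not apply).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .synthetic import UPF_LEVELS

UPF_ORDINAL = {level: i + 1 for i, level in enumerate(UPF_LEVELS)}


@dataclass
class TrendResult:
    slope: float  # score points per UPF level
    intercept: float
    p_value: float
    n: int


@dataclass
class GroupContrast:
    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    difference: float
    t_stat: float
    p_value: float
    n_a: int
    n_b: int


def encode_upf_ordinal(upf_freq):
    """Map UPF frequency labels to 1..5 (Rarely/Never = 1, ..., Several times a
    day = 5). Accepts a single label or a sequence."""
    if isinstance(upf_freq, str):
        try:
            return UPF_ORDINAL[upf_freq]
        except KeyError:
            raise ValidationError(f"unknown UPF frequency category: {upf_freq!r}") from None
    codes = pd.Series(upf_freq).map(UPF_ORDINAL)
    if codes.isna().any():
        bad = pd.Series(upf_freq)[codes.isna()].unique()
        raise ValidationError(f"unknown UPF frequency categories: {list(bad)}")
    return codes.to_numpy(int)


def fit_linear_trend(scores, upf_codes) -> TrendResult:
    """OLS of composite score on the ordinal UPF code, with the two-sided
    p-value for slope = 0."""
    y = np.asarray(scores, dtype=float)
    x = np.asarray(upf_codes, dtype=float)
    if y.shape != x.shape:
        raise ValidationError("scores and codes must have equal length")
    if len(np.unique(x)) < 2:
        raise ValidationError("at least two distinct UPF code levels are required for a trend")
    if len(x) < 3:
        raise ValidationError("at least 3 observations are required")
    res = stats.linregress(x, y)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 0.0
    return TrendResult(slope=float(res.slope), intercept=float(res.intercept), p_value=p, n=len(x))


def group_ttest(scores_a, scores_b, label_a: str = "a", label_b: str = "b") -> GroupContrast:
    """Welch (unequal-variance) two-sided t-test between two groups; no
    multiple-testing correction. Degenerate zero-variance groups with equal
    means return p = 1 by convention (and p = 0 with unequal means)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 observations")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if a.std() == 0.0 and b.std() == 0.0:
        t, p = (0.0, 1.0) if mean_a == mean_b else (np.inf if mean_a > mean_b else -np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        t, p = float(t), float(p)
    return GroupContrast(
        label_a=label_a, label_b=label_b, mean_a=mean_a, mean_b=mean_b,
        difference=mean_a - mean_b, t_stat=t, p_value=p, n_a=len(a), n_b=len(b),
    )


@dataclass
class StratumTrend:
    stratum: str
    means_by_upf: pd.Series  # indexed by UPF level label, ordered
    extreme_difference: float  # mean(Rarely/Never) - mean(Several times a day)
    trend: TrendResult
    n: int


def stratified_contrast(
    df: pd.DataFrame,
    stratifier: str,
    strata_defs: dict[str, list],
    score_col: str = "mhq_score",
) -> list[StratumTrend]:
    """Composite-score-by-UPF profiles within confound strata.

    ``stratifier`` is a cohort column (e.g. ``exercise_freq``, ``trauma_count``,
    ``income_band``); ``strata_defs`` maps a stratum name (e.g. ``high``/``low``)
    to the list of stratifier values it groups. Returns, per stratum, the mean
    score at each UPF level, the extreme-category difference and the linear
    trend. Empty strata are omitted with a warning.
    """
    if stratifier not in df.columns:
        raise ValidationError(f"stratifier column {stratifier!r} not in cohort")
    out: list[StratumTrend] = []
    for name, values in strata_defs.items():
        sub = df[df[stratifier].isin(values)]
        if len(sub) == 0:
            warnings.warn(f"stratum {name!r} is empty; omitted", stacklevel=2)
            continue
        means = sub.groupby("upf_freq")[score_col].mean().reindex(UPF_LEVELS)
        codes = encode_upf_ordinal(sub["upf_freq"])
        trend = fit_linear_trend(sub[score_col].to_numpy(), codes)
        extreme = float(means.iloc[0] - means.iloc[-1]) if means.notna().iloc[[0, -1]].all() else np.nan
        out.append(StratumTrend(stratum=name, means_by_upf=means,
                                extreme_difference=extreme, trend=trend, n=len(sub)))
    return out


def between_strata_offsets(results: list[StratumTrend]) -> pd.DataFrame:
    """Vertical offsets between the first stratum and each other stratum at
    every UPF level — the additivity diagnostic (near-constant offsets mean the
    confounder shifts the curve without changing the dose-response)."""
    if len(results) < 2:
        raise ValidationError("need at least two strata to compare")
    base = results[0]
    rows = {}
    for other in results[1:]:
        rows[f"{base.stratum}-{other.stratum}"] = base.means_by_upf - other.means_by_upf
    return pd.DataFrame(rows)
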