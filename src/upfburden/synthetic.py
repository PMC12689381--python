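"""Synthetic survey-cohort generator with a known generative model.

Every downstream stage of the pipeline (QC, composite scoring, weighting,
classification, counterfactual burden estimation) is exercised against cohorts
drawn from a Gaussian-additive latent-wellbeing model: each respondent carries a
latent wellbeing value

    W = intercept + b_upf[u] + b_ex[e] + b_trauma * t + b_inc[i]
        + b_age[a] + b_sex[s] + eps,        eps ~ Normal(0, noise_sd)

where u is the 5-level ultra-processed-food (UPF) consumption frequency, e the
exercise frequency, t the number of reported traumas/adversities, i the income
band, and a, s demographics. A respondent is truly distressed when W falls
below a latent threshold; the 47 Likert item ratings are monotone noisy
discretisations of W, so the composite wellbeing score computed downstream
recovers the same threshold approximately.

Confounding between exposure and lifestyle covariates is induced by exponential
tilting of the covariate distributions conditional on the UPF category, which
keeps the joint distribution fully enumerable: the true attributable fraction
under a forced "Rarely/Never" exposure is available both in closed form
(mixture-of-normals CDF) and by brute-force Monte-Carlo, independent of any
fitted model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import ConfigurationError, ValidationError

# Category level sets ------------------------------------------------------

UPF_LEVELS = [
    "Rarely/Never",
    "A few times a month",
    "A few times a week",
    "Once a day",
    "Several times a day",
]
UPF_REFERENCE = UPF_LEVELS[0]

EXERCISE_LEVELS = [
    "Rarely/Never",
    "Less than once a week",
    "Once a week",
    "Several times a week",
    "Every day",
]

INCOME_LEVELS = ["<40k", "40k-70k", "70k-100k", ">100k"]
INCOME_MISSING = "Not available"

N_ITEMS = 47
ITEM_COLUMNS = [f"item_{j:02d}" for j in range(1, N_ITEMS + 1)]

TRAUMA_ITEMS = [
    "trauma_severe_illness_injury",
    "trauma_homelessness",
    "trauma_job_loss",
    "trauma_divorce_separation",
    "trauma_death_of_loved_one",
    "trauma_physical_abuse",
    "trauma_emotional_abuse",
    "trauma_sexual_assault",
    "trauma_bullying",
    "trauma_natural_disaster",
    "trauma_violent_crime",
    "trauma_war_conflict",
]

MEDICAL_ITEMS = [
    "med_chronic_pain",
    "med_diabetes",
    "med_heart_condition",
    "med_asthma",
    "med_cancer",
    "med_autoimmune",
    "med_migraine",
    "med_gi_disorder",
    "med_thyroid",
    "med_none",
]

SUBSTANCE_ITEMS = [
    "sub_cannabis",
    "sub_stimulants",
    "sub_opioids",
    "sub_sedatives",
    "sub_hallucinogens",
    "sub_none",
]

# Extra life-context questions: pure context in the default generator (no
# latent effect) but part of the one-hot feature set. Levels and sampling
# probabilities are fixed module-wide so that the feature dictionary is stable.
EXTRA_CATEGORICALS: dict[str, tuple[list[str], list[float]]] = {
    "sleep_quality": (["Poor", "Fair", "Good", "Excellent"], [0.15, 0.3, 0.4, 0.15]),
    "socializing_freq": (
        ["Rarely/Never", "1-3 times a month", "Weekly", "Most days"],
        [0.2, 0.3, 0.3, 0.2],
    ),
    "education": (
        ["Primary", "Secondary", "Vocational", "Bachelor", "Postgraduate"],
        [0.05, 0.3, 0.2, 0.3, 0.15],
    ),
    "employment": (
        ["Employed", "Self-employed", "Studying", "Homemaker/Retired", "Not employed"],
        [0.45, 0.12, 0.12, 0.19, 0.12],
    ),
    "urbanicity": (["Urban", "Suburban", "Rural"], [0.45, 0.3, 0.25]),
    "fresh_food_freq": (
        ["Rarely/Never", "A few times a week", "Once a day", "Several times a day"],
        [0.1, 0.35, 0.3, 0.25],
    ),
    "alcohol_freq": (
        ["Never", "Monthly or less", "Weekly", "Most days"],
        [0.35, 0.3, 0.25, 0.1],
    ),
    "smoking_status": (["Never", "Former", "Current"], [0.6, 0.2, 0.2]),
    "relationship_status": (
        ["Single", "Partnered", "Married", "Separated/Widowed"],
        [0.3, 0.2, 0.38, 0.12],
    ),
    "sense_of_purpose": (["Low", "Moderate", "High", "Very high"], [0.15, 0.35, 0.35, 0.15]),
    "device_hours": (["<2h", "2-4h", "4-8h", ">8h"], [0.15, 0.3, 0.35, 0.2]),
    "caffeine_freq": (["Never", "Sometimes", "Daily"], [0.2, 0.3, 0.5]),
    "financial_security": (["Struggling", "Getting by", "Comfortable"], [0.25, 0.45, 0.3]),
}

CHECKLIST_PROBS = {
    "medical": [0.12, 0.08, 0.06, 0.08, 0.02, 0.04, 0.1, 0.07, 0.05, 0.55],
    "substance": [0.12, 0.05, 0.02, 0.04, 0.03, 0.78],
}

QC_COLUMNS = ["completion_minutes", "rating_sd", "comprehension_ok"]


def _as_prob(vec, name: str, length: int | None = None) -> np.ndarray:
    p = np.asarray(vec, dtype=float)
    if length is not None and p.shape != (length,):
        raise ConfigurationError(f"{name} must have length {length}, got shape {p.shape}")
    if np.any(p < 0) or not math.isclose(float(p.sum()), 1.0, abs_tol=1e-9):
        raise ConfigurationError(f"{name} must be a probability vector summing to 1 (got sum={p.sum()!r})")
    return p


def _tilt(p: np.ndarray, s: float) -> np.ndarray:
    """Exponentially tilt a categorical distribution along its (centred) level index."""
    k = np.arange(len(p), dtype=float)
    w = p * np.exp(s * (k - k.mean()))
    return w / w.sum()


@dataclass
class GenerativeConfig:
    """Parameters of the synthetic latent-wellbeing survey model.

    Effects (``beta_*``) are in latent-wellbeing units; the latent noise is
    ``noise_sd``. Probability vectors must sum to 1. ``confound_*`` tilt the
    exercise / trauma-count / income distributions conditional on the UPF
    category, inducing observational confounding with a still-enumerable joint.
    """

    n_respondents: int = 10_000
    countries: dict[str, int] = field(
        default_factory=lambda: {
            "C01": 250_000_000,
            "C02": 60_000_000,
            "C03": 120_000_000,
            "C04": 300_000_000,
            "C05": 70_000_000,
            "C06": 90_000_000,
        }
    )
    country_sample_probs: list[float] = field(
        default_factory=lambda: [0.30, 0.15, 0.20, 0.15, 0.10, 0.10]
    )
    region_map: dict[str, str] = field(
        default_factory=lambda: {
            "C01": "RegionA",
            "C02": "RegionA",
            "C03": "RegionB",
            "C04": "RegionB",
            "C05": "RegionC",
            "C06": "RegionC",
        }
    )
    age_groups: list[str] = field(
        default_factory=lambda: ["18-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75+"]
    )
    age_probs: list[float] = field(
        default_factory=lambda: [0.20, 0.22, 0.18, 0.15, 0.12, 0.08, 0.05]
    )
    sex_labels: list[str] = field(default_factory=lambda: ["Male", "Female"])
    sex_probs: list[float] = field(default_factory=lambda: [0.46, 0.54])
    upf_probs: list[float] = field(
        default_factory=lambda: [0.381, 0.308, 0.180, 0.080, 0.051]
    )
    exercise_probs: list[float] = field(
        default_factory=lambda: [0.15, 0.15, 0.20, 0.30, 0.20]
    )
    trauma_count_probs: list[float] = field(
        default_factory=lambda: [0.35, 0.25, 0.15, 0.10, 0.08, 0.05, 0.02]
    )
    income_band_probs: list[float] = field(default_factory=lambda: [0.30, 0.30, 0.20, 0.20])
    income_countries: tuple[str, ...] = ("C01", "C03", "C04")

    beta_upf: list[float] = field(default_factory=lambda: [0.0, -0.15, -0.35, -0.55, -0.75])
    beta_exercise: list[float] = field(default_factory=lambda: [0.0, 0.10, 0.40, 0.75, 0.90])
    beta_trauma_per_event: float = -0.18
    beta_income: list[float] = field(default_factory=lambda: [0.0, 0.15, 0.30, 0.45])
    beta_age: list[float] = field(
        default_factory=lambda: [0.0, 0.05, 0.10, 0.20, 0.30, 0.45, 0.50]
    )
    beta_sex: list[float] = field(default_factory=lambda: [0.0, -0.10])

    confound_exercise: float = 0.08
    confound_trauma: float = 0.10
    confound_income: float = 0.06

    intercept: float = -1.0
    noise_sd: float = 1.0
    distress_threshold_latent: float = 0.0

    item_loadings: list[float] | None = None  # default built in __post_init__
    item_is_problem: list[bool] | None = None
    item_noise_sd: float = 1.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ConfigurationError("n_respondents must be >= 1 (empty cohort)")
        ncat = {
            "country_sample_probs": len(self.countries),
            "age_probs": len(self.age_groups),
            "sex_probs": len(self.sex_labels),
            "upf_probs": 5,
            "exercise_probs": 5,
            "income_band_probs": len(INCOME_LEVELS),
        }
        for name, n in ncat.items():
            _as_prob(getattr(self, name), name, n)
        _as_prob(self.trauma_count_probs, "trauma_count_probs")
        if len(self.trauma_count_probs) - 1 > len(TRAUMA_ITEMS):
            raise ConfigurationError("trauma_count_probs allows more events than checklist items")
        if len(self.sex_labels) != 2:
            raise ConfigurationError("exactly two sex labels are required")
        if self.beta_upf[0] != 0.0:
            raise ConfigurationError("beta_upf reference category ('Rarely/Never') must be 0")
        if len(self.beta_upf) != 5 or len(self.beta_exercise) != 5:
            raise ConfigurationError("beta_upf and beta_exercise must have length 5")
        if self.item_loadings is None:
            # reproducible default loadings, mean ~1, all positive
            rng = np.random.default_rng(2023)
            self.item_loadings = list(np.clip(rng.normal(1.0, 0.2, N_ITEMS), 0.4, None))
        if len(self.item_loadings) != N_ITEMS:
            raise ConfigurationError(f"item_loadings must have length {N_ITEMS}")
        if self.item_is_problem is None:
            # first 27 items behave as symptom ("problem") items, the rest as
            # spectrum items; fixed so polarity handling is exercised.
            self.item_is_problem = [j < 27 for j in range(N_ITEMS)]
        if len(self.item_is_problem) != N_ITEMS:
            raise ConfigurationError(f"item_is_problem must have length {N_ITEMS}")
        if len(self.beta_age) != len(self.age_groups):
            raise ConfigurationError("beta_age must match age_groups in length")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")

    # -- conditional covariate distributions (shared by sampler and oracle) --

    def _zu(self, u_idx: int) -> float:
        return float(u_idx) - 2.0

    def exercise_probs_given_upf(self, u_idx: int) -> np.ndarray:
        return _tilt(np.asarray(self.exercise_probs, float), -self.confound_exercise * self._zu(u_idx))

    def trauma_probs_given_upf(self, u_idx: int) -> np.ndarray:
        return _tilt(np.asarray(self.trauma_count_probs, float), self.confound_trauma * self._zu(u_idx))

    def income_probs_given_upf(self, u_idx: int) -> np.ndarray:
        return _tilt(np.asarray(self.income_band_probs, float), -self.confound_income * self._zu(u_idx))


@dataclass
class GroundTruth:
    """Per-record latent state of a generated cohort plus the generating config."""

    latent_wellbeing: np.ndarray
    true_distress: np.ndarray
    config_echo: GenerativeConfig


def _mu_components(config: GenerativeConfig):
    """Return (beta arrays) as numpy for vectorised lookups."""
    return (
        np.asarray(config.beta_upf, float),
        np.asarray(config.beta_exercise, float),
        np.asarray(config.beta_income, float),
        np.asarray(config.beta_age, float),
        np.asarray(config.beta_sex, float),
    )


def generate_cohort(config: GenerativeConfig, seed: int | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a full synthetic cohort.

    Returns the cohort as a DataFrame (one row per respondent, columns for
    demographics, exposure, covariates, the 47 item ratings and QC fields) and
    the per-record ground truth. Deterministic given ``seed`` (defaults to
    ``config.seed``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_respondents
    country_codes = list(config.countries)
    b_upf, b_ex, b_inc, b_age, b_sex = _mu_components(config)

    country = rng.choice(len(country_codes), size=n, p=np.asarray(config.country_sample_probs))
    age = rng.choice(len(config.age_groups), size=n, p=np.asarray(config.age_probs))
    sex = rng.choice(2, size=n, p=np.asarray(config.sex_probs))
    upf = rng.choice(5, size=n, p=_as_prob(config.upf_probs, "upf_probs", 5))

    # covariates conditional on UPF category (exponential tilting)
    exercise = np.empty(n, dtype=int)
    trauma_count = np.empty(n, dtype=int)
    income = np.full(n, -1, dtype=int)  # -1 = missing
    has_income = np.isin(country, [country_codes.index(c) for c in config.income_countries
                                   if c in country_codes])
    for u in range(5):
        m = upf == u
        k = int(m.sum())
        if k == 0:
            continue
        exercise[m] = rng.choice(5, size=k, p=config.exercise_probs_given_upf(u))
        trauma_count[m] = rng.choice(
            len(config.trauma_count_probs), size=k, p=config.trauma_probs_given_upf(u)
        )
        mi = m & has_income
        ki = int(mi.sum())
        if ki:
            income[mi] = rng.choice(len(INCOME_LEVELS), size=ki, p=config.income_probs_given_upf(u))

    # trauma checklist flags: uniformly random subset of size trauma_count
    ranks = rng.random((n, len(TRAUMA_ITEMS))).argsort(axis=1).argsort(axis=1)
    trauma_flags = ranks < trauma_count[:, None]

    income_effect = np.where(income >= 0, b_inc[np.clip(income, 0, None)], 0.0)
    mu = (
        config.intercept
        + b_upf[upf]
        + b_ex[exercise]
        + config.beta_trauma_per_event * trauma_count
        + income_effect
        + b_age[age]
        + b_sex[sex]
    )
    latent = mu + rng.normal(0.0, config.noise_sd, n)
    true_distress = latent < config.distress_threshold_latent

    # 47 item ratings: monotone noisy discretisation of the latent value.
    # Polarity-aligned raw value is centred so that the composite-score
    # distress boundary (aligned mean = 11/3 on the 1..9 scale, i.e. score 0
    # on the -100..+200 scale) coincides with the latent threshold.
    loadings = np.asarray(config.item_loadings, float)
    aligned_center = 11.0 / 3.0
    raw = (
        aligned_center
        + (latent - config.distress_threshold_latent)[:, None] * loadings[None, :]
        + rng.normal(0.0, config.item_noise_sd, (n, N_ITEMS))
    )
    aligned = np.clip(np.rint(raw), 1, 9).astype(int)
    is_problem = np.asarray(config.item_is_problem, bool)
    ratings = np.where(is_problem[None, :], 10 - aligned, aligned)

    data = {
        "id": [f"r{i:07d}" for i in range(n)],
        "country": [country_codes[c] for c in country],
        "age_group": [config.age_groups[a] for a in age],
        "sex": [config.sex_labels[s] for s in sex],
        "upf_freq": [UPF_LEVELS[u] for u in upf],
        "exercise_freq": [EXERCISE_LEVELS[e] for e in exercise],
        "trauma_count": trauma_count,
        "income_band": [INCOME_LEVELS[i] if i >= 0 else pd.NA for i in income],
    }
    for j, name in enumerate(TRAUMA_ITEMS):
        data[name] = trauma_flags[:, j].astype(int)
    for col, (levels, probs) in EXTRA_CATEGORICALS.items():
        data[col] = [levels[i] for i in rng.choice(len(levels), size=n, p=np.asarray(probs))]
    for group, items in (("medical", MEDICAL_ITEMS), ("substance", SUBSTANCE_ITEMS)):
        probs = CHECKLIST_PROBS[group]
        for j, name in enumerate(items):
            data[name] = (rng.random(n) < probs[j]).astype(int)
    for j, col in enumerate(ITEM_COLUMNS):
        data[col] = ratings[:, j]
    data["completion_minutes"] = 7.0 + rng.gamma(2.0, 3.0, n)
    data["rating_sd"] = ratings.std(axis=1)  # population SD, divisor n
    data["comprehension_ok"] = np.ones(n, dtype=bool)

    df = pd.DataFrame(data)
    df["income_band"] = df["income_band"].astype("string")
    return df, GroundTruth(latent, true_distress, config)


# ---------------------------------------------------------------------------
# Oracles for the true attributable fraction
# ---------------------------------------------------------------------------


def _enumerate_joint(config: GenerativeConfig):
    """Enumerate the joint distribution over (country, age, sex, upf, exercise,
    trauma count, income band) with probabilities and latent means, both under
    the observed exposure and with exposure forced to the reference category."""
    b_upf, b_ex, b_inc, b_age, b_sex = _mu_components(config)
    country_codes = list(config.countries)
    nc, na, ns = len(country_codes), len(config.age_groups), 2
    nt = len(config.trauma_count_probs)
    ninc = len(INCOME_LEVELS) + 1  # last index = missing

    p_country = np.asarray(config.country_sample_probs)
    p_age = np.asarray(config.age_probs)
    p_sex = np.asarray(config.sex_probs)
    p_upf = _as_prob(config.upf_probs, "upf_probs", 5)
    p_ex_u = np.stack([config.exercise_probs_given_upf(u) for u in range(5)])  # (5,5)
    p_tr_u = np.stack([config.trauma_probs_given_upf(u) for u in range(5)])  # (5,nt)
    p_in_u = np.stack([config.income_probs_given_upf(u) for u in range(5)])  # (5,4)

    has_income = np.array([c in config.income_countries for c in country_codes])

    idx = np.stack(
        np.meshgrid(
            np.arange(nc), np.arange(na), np.arange(ns), np.arange(5),
            np.arange(5), np.arange(nt), np.arange(ninc), indexing="ij",
        ),
        axis=-1,
    ).reshape(-1, 7)
    c, a, s, u, e, t, i = idx.T

    # income probability: real band i<4 only in income countries; missing (i=4)
    # with prob 1 elsewhere
    p_income = np.where(
        has_income[c],
        np.where(i < 4, p_in_u[u, np.clip(i, 0, 3)], 0.0),
        np.where(i == 4, 1.0, 0.0),
    )
    prob = p_country[c] * p_age[a] * p_sex[s] * p_upf[u] * p_ex_u[u, e] * p_tr_u[u, t] * p_income

    inc_eff = np.where(i < 4, b_inc[np.clip(i, 0, 3)], 0.0)
    base = (
        config.intercept
        + b_ex[e]
        + config.beta_trauma_per_event * t
        + inc_eff
        + b_age[a]
        + b_sex[s]
    )
    mu_obs = base + b_upf[u]
    mu_ref = base + b_upf[0]
    keep = prob > 0
    return prob[keep], mu_obs[keep], mu_ref[keep]


def closed_form_prevalences(config: GenerativeConfig) -> tuple[float, float]:
    """Exact P(distress) under the observed exposure distribution and with the
    exposure forced to 'Rarely/Never', from the mixture-of-normals latent model."""
    prob, mu_obs, mu_ref = _enumerate_joint(config)
    thr = config.distress_threshold_latent
    p_obs = float(np.sum(prob * norm.cdf((thr - mu_obs) / config.noise_sd)))
    p_ref = float(np.sum(prob * norm.cdf((thr - mu_ref) / config.noise_sd)))
    return p_obs, p_ref


def closed_form_attributable_fraction(config: GenerativeConfig) -> float:
    """Exact attributable fraction (P_obs - P_ref) / P_obs from the latent model."""
    p_obs, p_ref = closed_form_prevalences(config)
    if p_obs <= 0:
        raise ValidationError("baseline distress prevalence is zero; attributable fraction undefined")
    return (p_obs - p_ref) / p_obs


def oracle_attributable_fraction(
    config: GenerativeConfig, n_mc: int, seed: int | None = None
) -> float:
    """Brute-force Monte-Carlo oracle for the true attributable fraction.

    Simulates latent wellbeing directly from the generative model (never via a
    fitted classifier), once under the observed exposure distribution and once
    with exposure forced to the reference category while keeping each
    respondent's other covariates fixed.
    """
    if n_mc < 1000:
        raise ValidationError("n_mc must be >= 1000")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    b_upf, b_ex, b_inc, b_age, b_sex = _mu_components(config)
    country_codes = list(config.countries)

    country = rng.choice(len(country_codes), size=n_mc, p=np.asarray(config.country_sample_probs))
    age = rng.choice(len(config.age_groups), size=n_mc, p=np.asarray(config.age_probs))
    sex = rng.choice(2, size=n_mc, p=np.asarray(config.sex_probs))
    upf = rng.choice(5, size=n_mc, p=_as_prob(config.upf_probs, "upf_probs", 5))
    exercise = np.empty(n_mc, dtype=int)
    trauma = np.empty(n_mc, dtype=int)
    income = np.full(n_mc, -1, dtype=int)
    has_income = np.isin(
        country, [country_codes.index(c) for c in config.income_countries if c in country_codes]
    )
    for u in range(5):
        m = upf == u
        k = int(m.sum())
        if k == 0:
            continue
        exercise[m] = rng.choice(5, size=k, p=config.exercise_probs_given_upf(u))
        trauma[m] = rng.choice(len(config.trauma_count_probs), size=k, p=config.trauma_probs_given_upf(u))
        mi = m & has_income
        if mi.any():
            income[mi] = rng.choice(len(INCOME_LEVELS), size=int(mi.sum()), p=config.income_probs_given_upf(u))

    base = (
        config.intercept
        + b_ex[exercise]
        + config.beta_trauma_per_event * trauma
        + np.where(income >= 0, b_inc[np.clip(income, 0, None)], 0.0)
        + b_age[age]
        + b_sex[sex]
    )
    eps = rng.normal(0.0, config.noise_sd, n_mc)
    thr = config.distress_threshold_latent
    p_obs = float(np.mean(base + b_upf[upf] + eps < thr))
    p_ref = float(np.mean(base + b_upf[0] + eps < thr))
    if p_obs <= 0:
        raise ValidationError("baseline distress prevalence is zero; attributable fraction undefined")
    return (p_obs - p_ref) / p_obs


# ---------------------------------------------------------------------------
# Preset configurations
# ---------------------------------------------------------------------------


def paper_like_config(n_respondents: int = 20_000, seed: int = 0, **overrides) -> GenerativeConfig:
    """Default study-condition config: marginals and effect sizes chosen to
    emulate the reported survey structure (38.1% 'Rarely/Never' UPF consumers,
    overall distress prevalence 27.7%, a strong monotone UPF dose-response and
    lifestyle confounding). The latent intercept is solved exactly so the
    closed-form overall distress prevalence equals the target."""
    cfg = GenerativeConfig(n_respondents=n_respondents, seed=seed, **overrides)
    return calibrate_intercept(cfg, target_prevalence=0.277)


def null_config(n_respondents: int = 10_000, seed: int = 0) -> GenerativeConfig:
    """Config with the UPF effect and all UPF confounding removed; used for
    null-safety checks of the burden estimators."""
    cfg = GenerativeConfig(
        n_respondents=n_respondents,
        seed=seed,
        beta_upf=[0.0] * 5,
        confound_exercise=0.0,
        confound_trauma=0.0,
        confound_income=0.0,
    )
    return calibrate_intercept(cfg, target_prevalence=0.277)


def calibrate_intercept(config: GenerativeConfig, target_prevalence: float) -> GenerativeConfig:
    """Solve the latent intercept so the closed-form overall distress
    prevalence equals ``target_prevalence``. Deterministic (Brent's method on
    the exact mixture-normal CDF)."""
    if not 0 < target_prevalence < 1:
        raise ConfigurationError("target_prevalence must be in (0, 1)")

    def f(mu0: float) -> float:
        return closed_form_prevalences(replace(config, intercept=mu0))[0] - target_prevalence

    mu0 = brentq(f, -10.0, 10.0, xtol=1e-10)
    return replace(config, intercept=float(mu0))


# ---------------------------------------------------------------------------
# QC-failure injection (fixture support for the exclusion rules)
# ---------------------------------------------------------------------------


def inject_qc_failures(
    df: pd.DataFrame,
    speeder_rate: float = 0.0,
    flatliner_rate: float = 0.0,
    confused_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Plant QC failures into a cohort: speeders (completion < 7 min),
    flat-liners (constant item ratings, SD < 0.2) and respondents flagging the
    assessment as not understood.

    Counts are exact: ``floor(rate * n + 0.5)`` per category, drawn as disjoint
    record sets so planted failures never overlap. Returns a modified copy.
    """
    rates = (speeder_rate, flatliner_rate, confused_rate)
    if any(r < 0 or r > 1 for r in rates):
        raise ConfigurationError("QC failure rates must lie in [0, 1]")
    if sum(rates) > 1:
        raise ConfigurationError("QC failure rates must not sum to more than 1")
    n = len(df)
    counts = [int(math.floor(r * n + 0.5)) for r in rates]
    if sum(counts) > n:
        raise ConfigurationError("requested QC failures exceed cohort size")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=sum(counts), replace=False)
    speeders = chosen[: counts[0]]
    flatliners = chosen[counts[0] : counts[0] + counts[1]]
    confused = chosen[counts[0] + counts[1] :]

    out = df.copy()
    if len(speeders):
        out.iloc[speeders, out.columns.get_loc("completion_minutes")] = rng.uniform(1.0, 6.9, len(speeders))
    if len(flatliners):
        flat_vals = rng.integers(1, 10, len(flatliners))
        item_locs = [out.columns.get_loc(c) for c in ITEM_COLUMNS]
        for row, v in zip(flatliners, flat_vals):
            out.iloc[row, item_locs] = int(v)
        out.iloc[flatliners, out.columns.get_loc("rating_sd")] = 0.0
    if len(confused):
        out.iloc[confused, out.columns.get_loc("comprehension_ok")] = False
    return out
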