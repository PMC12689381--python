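"""Two-step post-stratification weighting.

Step 1: within each country, respondents are weighted so the weighted age-sex
composition matches national demographics (cell weight proportional to
population share over sample share, which calibrates the weighted cell totals
to the country sample size — weights have sample-weighted mean 1). Sparse
cells are pooled with adjacent age bands within the same country-sex stratum
before weighting.

Step 2: country-level estimates are combined into a global estimate with each
country weighted by its internet-enabled population share, preventing
overrepresentation of high-response countries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

CELL_KEYS = ["country", "age_group", "sex"]


@dataclass
class PopulationTable:
    """Reference demographics: per-(country, age_group, sex) population counts
    and per-country internet-enabled population."""

    cells: pd.DataFrame  # columns: country, age_group, sex, population
    internet_population: dict[str, int]
    age_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = {c for c in CELL_KEYS + ["population"] if c not in self.cells.columns}
        if missing:
            raise ValidationError(f"population table missing columns: {sorted(missing)}")
        if (self.cells["population"] < 0).any():
            raise ValidationError("population counts must be nonnegative")
        if not self.age_order:
            self.age_order = list(dict.fromkeys(self.cells["age_group"]))


@dataclass
class WeightTable:
    """Calibrated cell weights plus country weights and a record of pooling."""

    cell_weights: pd.DataFrame  # columns: country, age_group, sex, weight
    country_weights: dict[str, float]
    pooled_cells: list[list[tuple[str, str, str]]] = field(default_factory=list)


def population_table_from_config(config) -> PopulationTable:
    """Build a synthetic national demographics table consistent with a
    generative config (population cells proportional to the config's age/sex
    sampling margins, scaled by internet population)."""
    rows = []
    age_p = np.asarray(config.age_probs)
    sex_p = np.asarray(config.sex_probs)
    for country, pop in config.countries.items():
        for a, ag in enumerate(config.age_groups):
            for s, sx in enumerate(config.sex_labels):
                rows.append({"country": country, "age_group": ag, "sex": sx,
                             "population": pop * age_p[a] * sex_p[s]})
    return PopulationTable(
        cells=pd.DataFrame(rows),
        internet_population=dict(config.countries),
        age_order=list(config.age_groups),
    )


def _pool_country_sex(sub: pd.DataFrame, age_order: list[str], min_cell_n: int):
    """Greedy adjacent-age pooling within one country-sex stratum: scan age
    bands in order accumulating cells until the pooled sample reaches
    min_cell_n; a deficient tail group is merged into its predecessor."""
    sub = sub.set_index("age_group").reindex([a for a in age_order if a in set(sub["age_group"])])
    groups: list[list[str]] = []
    current: list[str] = []
    current_n = 0
    for age in sub.index:
        current.append(age)
        current_n += int(sub.loc[age, "n"])
        if current_n >= min_cell_n:
            groups.append(current)
            current, current_n = [], 0
    if current:
        if groups:
            groups[-1].extend(current)
        else:
            groups.append(current)
    return sub, groups


def compute_cell_weights(
    sample_counts: pd.DataFrame,
    population_table: PopulationTable,
    min_cell_n: int = 30,
) -> WeightTable:
    """Compute calibrated post-stratification cell weights.

    ``sample_counts``: columns country, age_group, sex, n (post-QC counts).
    Cell weight = (population share within country) / (sample share within
    country); cells below ``min_cell_n`` are pooled with adjacent age bands in
    the same country-sex stratum and share the pooled weight. Country weights
    are internet-population shares over the countries present.
    """
    sc = sample_counts.copy()
    if sc.empty:
        raise ValidationError("sample_counts is empty")
    pop = population_table.cells.set_index(CELL_KEYS)["population"]
    merged = sc.set_index(CELL_KEYS)
    missing_pop = merged.index.difference(pop.index)
    if len(missing_pop):
        raise ValidationError(f"population table lacks cells present in the sample: {list(missing_pop)[:5]}")
    zero_pop = [ix for ix in merged.index if pop.loc[ix] == 0 and merged.loc[ix, "n"] > 0]
    if zero_pop:
        raise ValidationError(f"population cell is zero but sample is non-empty: {zero_pop[:5]}")

    out_rows = []
    pooled_record: list[list[tuple[str, str, str]]] = []
    for country, c_sub in sc.groupby("country", sort=False):
        n_country = float(c_sub["n"].sum())
        if n_country == 0:
            raise ValidationError(f"country {country!r} has no sampled records")
        pop_country = float(
            pop.loc[country].loc[
                [(r.age_group, r.sex) for r in c_sub.itertuples()]
            ].sum()
        )
        for sex, s_sub in c_sub.groupby("sex", sort=False):
            sub, groups = _pool_country_sex(
                s_sub[["age_group", "n"]], population_table.age_order, min_cell_n
            )
            for grp in groups:
                grp_n = float(sub.loc[grp, "n"].sum())
                grp_pop = float(sum(pop.loc[(country, a, sex)] for a in grp))
                weight = (grp_pop / pop_country) / (grp_n / n_country)
                for a in grp:
                    out_rows.append(
                        {"country": country, "age_group": a, "sex": sex, "weight": weight}
                    )
                if len(grp) > 1:
                    pooled_record.append([(country, a, sex) for a in grp])

    pops = {
        c: population_table.internet_population[c] for c in sc["country"].unique()
    }
    total = float(sum(pops.values()))
    country_weights = {c: p / total for c, p in pops.items()}
    return WeightTable(
        cell_weights=pd.DataFrame(out_rows),
        country_weights=country_weights,
        pooled_cells=pooled_record,
    )


def record_weights(df: pd.DataFrame, weight_table: WeightTable) -> np.ndarray:
    """Look up each record's post-stratification cell weight."""
    wt = weight_table.cell_weights.set_index(CELL_KEYS)["weight"]
    idx = pd.MultiIndex.from_frame(df[CELL_KEYS])
    missing = idx.difference(wt.index)
    if len(missing):
        raise ValidationError(f"no weight for cells: {list(missing)[:5]}")
    return wt.loc[idx].to_numpy()


def weighted_statistic(values, weights, kind: str = "mean") -> float:
    """Weighted mean or proportion: sum(w*x)/sum(w); for ``proportion`` the
    values must be 0/1 indicators."""
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValidationError("values and weights must have equal length")
    if np.any(w < 0):
        raise ValidationError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ValidationError("weights must not all be zero")
    if kind == "proportion" and not np.isin(x, (0.0, 1.0)).all():
        raise ValidationError("proportion requires a 0/1 indicator")
    if kind not in ("mean", "proportion"):
        raise ValidationError(f"unknown statistic kind {kind!r}")
    return float(x @ w / w.sum())


def two_step_aggregate(
    per_country_estimates: dict[str, float], population_table: PopulationTable
) -> float:
    """Combine per-country estimates into a global estimate weighted by
    internet-enabled population share (second weighting step)."""
    missing = [
        c for c in per_country_estimates if c not in population_table.internet_population
    ]
    if missing:
        raise ValidationError(f"internet population unknown for countries: {missing}")
    pops = {c: population_table.internet_population[c] for c in per_country_estimates}
    total = float(sum(pops.values()))
    if total <= 0:
        raise ValidationError("total internet population is zero")
    return float(
        sum(per_country_estimates[c] * pops[c] / total for c in per_country_estimates)
    )


def weighted_global_estimate(
    df: pd.DataFrame,
    column: str,
    weight_table: WeightTable,
    population_table: PopulationTable,
    kind: str = "mean",
) -> float:
    """Convenience wrapper for the full two-step procedure on a scored cohort:
    weighted per-country statistic, then internet-population aggregation."""
    per_country = {}
    for country, sub in df.groupby("country", sort=False):
        w = record_weights(sub, weight_table)
        per_country[country] = weighted_statistic(sub[column].to_numpy(float), w, kind)
    return two_step_aggregate(per_country, population_table)
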