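# upfburden

Estimating the **clinical mental-distress burden associated with
ultra-processed food (UPF) consumption frequency** from large cross-sectional
wellbeing surveys — for epidemiologists and biostatisticians who want the full
estimation pipeline as tested, reusable code with verifiable ground truth.

## What it computes

Respondents rate 47 symptom/function items on a 9-point scale; a composite
wellbeing score maps the polarity-aligned weighted item mean onto a
−100..+200 scale, and **clinical mental distress** is a strictly negative
score. With a 5-level ordered exposure (UPF consumption frequency, reference
category 'Rarely/Never'), two estimators quantify the exposure's footprint:

* **data-based**: `linked = P(distress) − P(distress | reference exposure)`
  (percentage points), `burden = linked / P(distress) × 100` — an
  attributable-fraction-among-distressed analogue with no confound control;
* **simulation-based (g-computation)**: fit a gradient-boosted classifier of
  distress on ~108 one-hot life-context features, force every test record's
  exposure block to the reference category, re-predict, and average the drop in
  predicted distress over repeated random test draws — controlling for all
  measured covariates at once.

Around the estimators the package provides the complete pipeline: a synthetic
cohort generator with a fully known Gaussian-additive latent model (plus
closed-form and Monte-Carlo oracles for the true attributable fraction), QC
exclusion rules with an auditable log, two-step post-stratification weighting
(age–sex cells within country, internet-population across countries),
dose-response trend statistics, cross-validated model evaluation with
sensitivity analyses and calibration, and exact TreeSHAP attributions with
fold-rank stability and beeswarm export.

## Worked example

```python
import upfburden as ub
from upfburden.features import build_feature_matrix, default_feature_dictionary

# the published worked-example arithmetic
ub.linked_percentage_data(27.7, 19.9)   # -> 7.8  (percentage points)
round(ub.burden_ratio(7.8, 27.7), 1)    # -> 28.2 (% of baseline distress)

# end-to-end on a synthetic cohort with known ground truth
cfg = ub.paper_like_config(n_respondents=20_000, seed=1)
df, truth = ub.generate_cohort(cfg)
scored = ub.score_cohort(df, cfg.item_is_problem)

overall = scored["distressed"].mean() * 100                    # 27.9
reference = scored.loc[scored.upf_freq == ub.UPF_REFERENCE,
                       "distressed"].mean() * 100              # 19.5
data = ub.data_burden_estimate(overall, reference)
(data.linked_pct, data.burden_pct)                             # (8.4, 30.0)

fm = build_feature_matrix(scored, default_feature_dictionary(cfg))
sim, = ub.simulation_burden(fm, n_iterations=10, seed=2, decision="expected")
(sim.linked_pct, sim.burden_pct)                               # (5.9, 21.1)

ub.oracle_attributable_fraction(cfg, 1_000_000, seed=3) * 100  # 21.3
```

Reading the numbers: the raw prevalence difference attributes 8.4 points /
30.0% of distress to the exposure, but the generator deliberately confounds
exposure with exercise, trauma and income, so the causal truth (oracle, 21.3%)
is lower; the g-computation estimate (21.1%) recovers it by controlling for
the measured covariates. The data-based > simulation-based ordering is exactly
the behaviour expected on confounded observational data.

A `upfburden` CLI covers the pipeline stages
(`simulate`, `qc`, `score`, `trend`, `fit`, `attribute`, `burden`); each
subcommand is a thin wrapper over the functions above, e.g.

```bash
upfburden simulate --n 20000 --seed 17 --out work/
upfburden qc --in work/cohort.parquet --out work/clean.parquet --log work/qc.json
```

## Documentation

`docs/methods.md` describes the generative model and its calibration, every
estimator's assumptions and conventions, the deliberate design decisions
(weighting pooling rule, Welch t-test, 65/35 splits, macro metrics, margin-
space attributions, the g-computation decision rule and denominator), and what
passing tests on synthetic data do and do not demonstrate about real surveys.
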