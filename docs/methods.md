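# Methods

## The problem this package addresses

Large cross-sectional survey programmes measure mental wellbeing with a
composite score over many Likert-rated symptom and function items, together
with lifestyle context including how often respondents eat ultra-processed
food (UPF). Two quantities summarise the exposure's footprint on the
population:

* the **linked percentage** — the share of the sample (in percentage points)
  whose clinical mental distress is attributable to the exposure, and
* the **burden** — the linked percentage divided by the baseline distressed
  percentage, an attributable-fraction-among-distressed analogue.

The linked percentage can be read directly off the data as
`overall prevalence − prevalence among reference-exposure respondents`
(no confound control), or estimated by **g-computation** (model-based
standardization): fit a classifier of distress on the full life-context
feature set, force every record's exposure to the reference category
('Rarely/Never') without touching any other feature, re-predict, and take the
drop in the predicted-distressed percentage. The data-based route bounds the
association from above; the simulation route controls for every measured
covariate simultaneously and assumes no indirect exposure effects on the other
covariates.

Because the underlying survey records are access-restricted, the package
includes a first-class synthetic cohort generator with a fully known
generative model, so every estimator can be validated by parameter recovery
against a brute-force oracle rather than against irreproducible point values.

## Synthetic generative model

Latent wellbeing per respondent:

```
W = mu0 + b_upf[u] + b_ex[e] + b_trauma * t + b_inc[i] + b_age[a] + b_sex[s] + eps
eps ~ Normal(0, noise_sd)
```

True distress is `W < 0`. Covariates are categorical; the exercise,
trauma-count and income distributions are exponentially tilted conditional on
the UPF category (`confound_*` parameters), producing observational
confounding while keeping the joint distribution enumerable: prevalences under
the observed and forced-reference exposure come in closed form from a
mixture-of-normals CDF, and `oracle_attributable_fraction` verifies this by
direct Monte-Carlo from the same model (never via a fitted classifier).

Item ratings are monotone noisy discretisations of W: the polarity-aligned raw
value for item j is `11/3 + loading_j * W + Normal(0, 1)`, rounded and clipped
to 1..9, with "problem" (symptom) items stored reverse-coded as `10 - r`. The
centring at 11/3 makes the composite-score distress boundary (score 0, i.e.
aligned mean 11/3) coincide with the latent threshold, so the downstream label
agrees with the latent truth for ~97% of records at the default item noise.

### Default study conditions

Chosen once to emulate the reported survey structure; the intercept `mu0` is
solved deterministically (Brent root-finding on the closed-form prevalence) so
overall distress is 27.7%.

| parameter | default | rationale |
|---|---|---|
| UPF marginals | .381/.308/.180/.080/.051 | 38.1% 'Rarely/Never' and 31.1% at-least-weekly are reported; the split of the 31.1% across the three at-least-weekly categories is not, and was fixed at a plausible decreasing profile |
| `beta_upf` | 0, −0.15, −0.35, −0.55, −0.75 (latent SD units) | reproduces the reported distress gradient across exposure extremes (≈20% vs ≈55%) via the closed-form oracle |
| `beta_exercise` | 0 … +0.9 | frequent-vs-infrequent exercise offset of ≈30 score points, additive with the exposure |
| `beta_trauma_per_event` | −0.18 | ≥3 traumas vs none ≈ −0.6 SD |
| `beta_income` | 0 … +0.45 | income available in 3 of 6 countries only; missing income carries no effect and its own indicator level |
| `confound_*` | 0.08 / 0.10 / 0.06 | mild lifestyle confounding correlated with the exposure, so the data-based estimate exceeds the causal truth |
| `noise_sd`, `item_noise_sd` | 1.0, 1.0 | latent and per-item noise; 47 items average the item noise down to ≈0.15 rating points |
| countries | 6 synthetic codes, fixed internet populations | enough cells to exercise two-step weighting; no real census tables |

The 108-column one-hot feature dictionary (demographics, exposure, exercise,
income incl. a 'Not available' level, 12 trauma flags, 13 context questions,
medical and substance checklists) is a constructed stand-in: the published
feature list is not public. The extra context variables carry **no** latent
effect by default; passing tests therefore demonstrates estimator correctness
under known conditions, not realism of any particular covariate's effect, and
real data would give every covariate some signal.

## Composite scoring

Score = `−100 + 300 · (weighted mean of polarity-aligned ratings − 1)/8`, so
all-worst → −100 and all-best → +200 for any positive weight vector, and
distress is a strictly negative score (0 counts as not distressed). The
published instrument's nonuniform item weighting is proprietary; the default
here is uniform with injectable weights, and the test suite shows the
pipeline's qualitative conclusions are invariant to random positive weight
perturbations. Item-difference tables flag items whose group mean difference
exceeds a threshold in the "worse" direction for their polarity (≥ +t for
problem items, ≤ −t for spectrum items).

## QC filtering

Strict boundaries as stated: completion < 7 min, item-rating SD < 0.2
(population SD recomputed from the ratings; the divisor convention is
configurable), comprehension flag, then countries with < 1,000 clean records.
Record-level rules run before the country rule so country counts reflect clean
records. The exclusion log satisfies kept + excluded = input on every run, and
both passes are idempotent.

## Post-stratification weighting

Cell weight = within-country population share over sample share, which
calibrates weighted cell totals to the country sample size (weights have
sample-weighted mean 1). Population shares are taken over the **sampled**
cells of each country — weight cannot be given to unsampled cells. Cells with
fewer than `min_cell_n = 30` respondents (a conventional survey floor; not
specified by the source analysis) are pooled greedily with adjacent age bands
within the same country–sex stratum, a deficient tail group merging into its
predecessor. Global estimates weight per-country estimates by internet-enabled
population share; the two-step procedure is verified against a single direct
weighted sum with combined record weights to 1e-9.

## Trend and contrast statistics

The dose-response trend is OLS of the composite score on the ordinal exposure
code (1..5, treated as numeric). Group contrasts use Welch's unequal-variance
two-sided t-test (the source analysis says only "standard two-tailed t-test")
with no multiple-testing correction, matching the stated rationale that the
items measure one construct. Degenerate zero-variance comparisons return p = 1
(equal means) / p = 0 (unequal) by convention. Confound stratification
reports per-stratum exposure profiles, extreme-category differences, trends,
and between-stratum offsets (near-constant offsets = additivity).

## Classifier and evaluation

XGBoost (hist, depth 4, 150 trees, learning rate 0.1, single thread — moderate
capacity, no early stopping; all exposed) is the primary algorithm, with
logistic regression, Bernoulli naive Bayes and random forest behind the same
estimator contract. Evaluation: stratified 3/5/10-fold cross-validation and
five repeated stratified 65/35 train/test splits. The source text's "65/45
split" cannot sum to 100; 65/35 is used. Precision/recall/F1 are
macro-averaged over the two classes; AUC and accuracy are class-symmetric.
Sensitivity analyses drop the later-ordered member of every feature pair with
|r| > 0.80, and refit without the five exposure columns; both report the AUC
change on a held-out split. Calibration tables use equal-width probability
bins, keeping empty bins as n = 0 rows.

## Attribution

Exact TreeSHAP values from XGBoost's native `pred_contribs` in margin
(log-odds) space — sign-stable and standard for tree ensembles. Signs are
flipped so positive attributions push toward *positive* wellbeing. Per record,
`base_value + Σ attributions` equals the (negated) margin to 1e-4. Fold-rank
stability is the mean Spearman correlation of mean-|attribution| feature
rankings over all pairwise fold combinations; on the synthetic cohort it is
computed over the features that carry generative signal, because the pure-noise
context features (zero effect by construction) rank randomly in the tail and
that tail noise is an artifact of the generator, not of the method.

## Counterfactual burden

`set_reference_exposure` rewrites only the exposure one-hot block. Per
iteration, a stratified random test set (35%) is drawn and the model refit on
the complement (refitting per iteration is the default; reusing one fit is
supported). Reported values are per-stratum means over 10 iterations, with
age bands 18–34 / 35–64 / 65+ available as default strata.

Two deliberate estimator choices:

* **Denominator** — the model-predicted distressed percentage on the
  unmanipulated test set, not the observed prevalence (the published
  simulation pair implies a model-predicted baseline; the observed-prevalence
  variant is available via `denominator="observed"`).
* **Decision rule** — the default 0.5-threshold classification mirrors the
  description of "percentage predicted to have a negative" score, but it is a
  *biased* estimator whenever the classifier's discrimination is moderate: at
  AUC ≈ 0.74 on the synthetic cohort, few individual probabilities cross 0.5,
  the thresholded baseline understates prevalence (≈15% vs 27.7%) and the
  burden ratio overshoots. `decision="expected"` (mean predicted probability)
  is the standard g-computation estimator and is what the parameter-recovery
  tests and the acceptance script use; it recovers the generative oracle
  within a fraction of a percentage point at n = 20,000.

Internal identity `burden × baseline = linked × 100` holds in every reported
cell; with the model denominator, `linked ≤ baseline` always.

## Numerical and degenerate-input conventions

Probability vectors validated to 1e-9; ratings validated as integers 1..9;
empty groups/strata raise or warn-and-omit as documented per operation; the
attributable fraction is undefined (error) at zero baseline prevalence;
unknown category levels and missing schema columns raise naming the offending
record/column.

## Problem sizes

Tests run the study-condition generator at n = 8,000 (shared session
fixtures), with targeted checks at n = 50,000 (marginals, monotone
dose-response) and the recovery check at n = 20,000 with a 10^6-draw
Monte-Carlo oracle; null safety uses 20 seeds at n = 4,000. The acceptance
script mirrors these sizes.

## Known limitations

* The generator is Gaussian-additive with independent-given-exposure
  covariates; it does not emulate non-response, recruitment bias, country-level
  effect heterogeneity, or real census margins.
* The composite score here is a documented uniform-weight transform, not the
  published proprietary scoring.
* The "negative score ≈ 5+ significant symptoms" interpretation has no public
  mapping formula and is not computed.
* Weighted statistics carry no variance estimation; error bars on group means
  are unweighted SEMs.
* The g-computation estimate assumes no indirect exposure effects on other
  covariates, as in the source analysis.
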