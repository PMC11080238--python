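# Methods

`mascard` implements an end-to-end diagnostic modelling workflow for
distinguishing macrophage activation syndrome (MAS) secondary to systemic
lupus erythematosus (SLE) from uncomplicated SLE, using routinely collected
clinical and laboratory variables. Because no patient-level dataset for this
problem is publicly available, the workflow is driven by a synthetic cohort
generator whose defaults encode the clinical structure of the problem; every
downstream stage — preprocessing, two-stage feature selection, multi-model
classification, and scorecard construction — is exercised and tested against
those cohorts.

## The synthetic cohort generator

The generator draws balanced case–control cohorts (default 94 SLE + 94 MAS,
the scale of the retrospective series the workflow is modelled on) over 13
informative predictors: maximum body temperature, duration of fever, serum
sodium, triglycerides (TG), HDL cholesterol, lactate dehydrogenase (LDH),
serum ferritin, C-reactive protein (CRP), fibrinogen (FIB), prothrombin time
(PT), TNF-α, and two binary composites, pancytopenia and liver damage.

Each feature has class-conditional sampling distributions. Heavy-tailed
analytes (ferritin, LDH, CRP, TG, fever duration, TNF-α) are log-normal;
the remainder are Gaussian, floored where an assay cannot be negative.
Location shifts follow the clinically reported directions: MAS cases run
hotter and longer fevers, with hyponatremia, hypertriglyceridemia, low HDL,
high LDH, marked hyperferritinemia, elevated CRP, hypofibrinogenemia,
prolonged PT, *lower* TNF-α at admission, and frequent pancytopenia and
liver damage. Defaults (medians / means, with clinical reference intervals
in the same units):

| feature | SLE | MAS | units |
|---|---|---|---|
| max_temperature | 37.9 | 39.4 | °C |
| fever_duration | 3.4 | 16 | days |
| sodium | 140.2 | 132.5 | mmol/L |
| TG | 1.12 | 3.0 | mmol/L |
| HDL | 1.22 | 0.59 | mmol/L |
| LDH | 210 | 610 | U/L |
| ferritin | 310 | 3800 | µg/L |
| CRP | 5.5 | 40 | mg/L |
| FIB | 3.8 | 1.95 | g/L |
| PT | 10.9 | 14.0 | s |
| TNF_alpha | 29 | 7.8 | pg/mL |
| pancytopenia | 3% | 75% | — |
| liver_damage | 6% | 78% | — |

These separations (≈2.3–2.6 within-class SDs per feature) were calibrated
once so that the cohorts realize the study conditions the package is tested
under: the combined signal puts every classifier family near ceiling
(matching the near-perfect internal AUCs typical of this diagnostic
contrast), and each individual predictor carries enough marginal signal that
penalized selection can recover the full panel at n = 188. The MAS ferritin
median lies well above the 1,242.25 µg/L level reported as discriminating in
this disease contrast, and the MAS TG median sits at the 3 mmol/L
hypertriglyceridemia criterion. They are deliberately *cleaner* than real
data: features are conditionally independent given the class, missingness is
completely at random, and there is no site, assay or temporal drift beyond
the explicit external-cohort perturbation. Passing tests therefore
demonstrate correctness of the machinery, not expected performance on real
patients.

Additional generator structure:

- **Noise features.** 20 standard-normal nuisance features drawn identically
  for both classes, so both selection stages face a genuine false-inclusion
  risk.
- **Missingness.** MCAR per feature at tiered rates (0–12%; TNF-α highest at
  12%, ferritin 8%), chosen to exercise both imputation tiers. Rates above
  20% are excluded by construction, mirroring the practice of dropping
  heavily missing variables.
- **Mortality.** An outcome column (`died`) assigns exactly
  round(15/94 · n_MAS) deaths among MAS patients and none among SLE patients,
  reproducing the reported in-hospital mortality contrast (15/94 ≈ 16% vs 0%).
- **External cohorts.** `generate_external_cohort` applies a location offset
  (default 0.25 overall SDs per continuous feature) and a residual scale
  inflation (default 1.10) to emulate inter-hospital drift with an unchanged
  schema.
- **Raw-lineage mode.** Optionally replaces the two Bernoulli composites
  with the five underlying analytes (HB, PLT, WBC, ALT, AST) so composite
  construction from raw counts is exercisable.

## Preprocessing

- **Tiered imputation.** Features missing < 5% are filled with the mode
  (binary) or mean (continuous); features between 5% and 20% by iterative
  random-forest imputation (100 trees, up to 10 iterations, seed-controlled).
  Features at ≥ 20% raise an error rather than being silently dropped.
  A Mann-Whitney U audit compares each imputed feature's observed values
  before imputation with the completed vector afterwards; imputation passes
  when no feature shifts at the chosen level (default α = 0.05).
- **Range flags.** Each continuous feature gains a ternary companion
  (`<feature>_flag`): 1 above the upper clinical reference limit, −1 below
  the lower limit, 0 inside. Bounds are inclusive (a value equal to a limit
  is "normal"), the usual convention for reference intervals.
- **Outliers.** Box-plot fences at Q1 − 1.5·IQR and Q3 + 1.5·IQR; flagged
  entries are winsorized to the fences by default (removal is available).
  Winsorizing rather than deleting preserves the small cohort and, for the
  heavily skewed analytes, materially improves the linear detectability of
  their signal.
- **Standardization.** A Z-score model (per-feature mean and population SD)
  is fitted on the training cohort only and stored; external cohorts are
  transformed with the stored parameters, never refit. External patients with
  any missing value are excluded per-patient before transformation.

Default order: impute → flags → outliers → Z-score.

## Two-stage feature selection

Stage one removes redundancy. For every feature pair with |Pearson r| ≥ 0.8
the member with the weaker absolute point-biserial correlation to the
diagnosis is dropped; then features are removed iteratively by largest
variance inflation factor until all VIF < 10. Both cutoffs are configurable;
ties break by ascending feature name so the result is invariant to column
order. The composites replace their source analytes: pancytopenia is the
conjunction of HB, PLT and WBC each below its lower reference limit
(three-lineage depression); liver damage is ALT or AST above its upper limit.
These composite definitions are an explicit modelling assumption of this
package.

Stage two is L1-penalized logistic regression over a 40-point log-spaced
penalty grid running from the null-model penalty max|Xᵀ(y − ȳ)|/n down 3.5
decades, scored by stratified 5-fold cross-validated binomial deviance.
Predicted probabilities are clamped at 10⁻⁵ inside the deviance (the glmnet
convention) so a single confidently misclassified held-out point cannot
dominate a fold. The penalty is chosen by the **one-standard-error rule**:
the largest penalty whose mean CV deviance is within one SE of the minimum.
The plain minimum rule is available (`rule="min"`) but is degenerate under
near-separable data — the CV curve keeps falling to the bottom of the grid,
admitting many chance-correlated noise features while dropping redundant
informative ones — so the 1-SE rule, the standard remedy for exactly this
overselection, is the default.

## Classification and evaluation

Four families: L2-penalized logistic regression (the penalty is always
active), random forest, RBF support-vector machine, and gradient-boosted
trees. Hyperparameters come from an exhaustive grid search with stratified
inner 5-fold CV on the training split; the shipped default grids are small
(logistic C ∈ {0.01, 0.1, 1, 10}; forest depth ∈ {3, 6, ∞} at 200 trees;
SVM C ∈ {0.1, 1, 10}; boosting depth ∈ {2, 3} at 150 rounds, learning rate
0.1). SVM probabilities come from the internally cross-validated sigmoid
(Platt) calibration.

Validation-column metrics use leave-one-out on the training split: n fits,
each scoring its held-out patient, with metrics pooled over the n
out-of-fold predictions. Test and external columns use direct prediction.
Metrics are the rank-based ROC-AUC (Mann-Whitney normalization, ties counted
half), F1, and F2 — the F-beta score (1+β²)PR/(β²P+R) with β = 2, which
weights recall four times as heavily as precision because a missed MAS
diagnosis is far costlier than a false alarm. Confusion-based metrics use a
0.5 probability threshold (the scorecard has its own threshold).

The internal split is stratified 80/20 train/test; all three evaluation
splits (LOO-validation, test, external) are exposed in the pipeline
configuration.

## The diagnostic scorecard

1. **Binning.** Continuous features are discretized by bottom-up chi-square
   (ChiMerge) binning from 20 quantile pre-bins (equal-width is available):
   the adjacent pair with the *smallest* chi-square statistic is merged while
   that pair does not differ at α = 0.05 or more than 8 bins remain, stopping
   at 3 bins at the latest. Zero-expectation cells contribute nothing to the
   statistic; empty bins are always absorbed. A `rule="literal"` mode merges
   the most *different* significant pair instead — an occasionally printed
   inversion of ChiMerge that destroys informative cuts; it is provided for
   comparison only. Binary
   features keep their two categories.
2. **Weight of evidence.** Per bin, WOE = ln(SLE% / MAS%), the log ratio of
   class-conditional bin shares; zero counts receive +0.5 smoothing and
   shares are renormalized. High WOE marks SLE-typical values.
3. **WOE-logistic model.** Logistic regression on the WOE-encoded features
   (MAS positive), with a mild L2 penalty to stabilize collinear WOE columns.
4. **Score scaling.** Score = A − B·ln(odds) with B = PD0/ln 2 and
   A = P0 + B·ln(odds0); defaults odds0 = 1/19, P0 = 70, PD0 = 4.14, giving
   A = 52.41 and B = 5.97. PD0 is the score drop per doubling of the MAS
   odds, so MAS-typical patients land at low scores.
5. **Points.** Bin points are round(−B·w_j·WOE_ij + base/p) with the base
   points A − B·intercept shared equally across the p features (standard
   scorecard practice); rounding is round-half-to-even, and the integer total
   deviates from the exact A − B·ln(odds) by at most half a point per
   feature.
6. **Threshold.** The Kolmogorov-Smirnov statistic over candidate scores in
   ascending order: KS = max |CDF_MAS − CDF_SLE|, threshold = the lowest
   score attaining it (ties resolved with a 10⁻¹² float guard); score ≤
   threshold predicts MAS.
7. **Risk bands.** Gaussian KDEs (Silverman bandwidth by default,
   overridable) of the two classes' score distributions give the risk of a
   unit score interval, risk(s) = π·∫f₊ / (π·∫f₊ + (1−π)·∫f₋) over
   [s−½, s+½] with the empirical class prior π (0.5 for the balanced
   design, where the risk reduces to the positive-interval mass ratio).
   For each level in {95%, 75%, 25%, 5%} the band threshold is the highest
   integer score whose risk still reaches the level; the four thresholds cut
   [0, 100] into five bands from extremely high risk (lowest scores) to
   extremely low. When the risk transition is sharper than one score point,
   adjacent levels can quantize to the same cut and a band is legitimately
   empty; genuine non-monotonicity of the risk (a rise exceeding 10⁻⁶
   anywhere on the integer grid) or an unattained level raises an error.
   Scores are clamped to [0, 100] for presentation; the raw total is also
   returned.

The scorecard is fitted on raw (imputed, unstandardized) feature values so a
patient can be scored directly from laboratory results; out-of-reference
inputs are flagged in the scoring output.

## Pipeline and reproducibility

`run_pipeline` executes simulate → preprocess → select → train → scorecard →
report into a run directory of plain CSV/JSON artifacts, with a manifest
carrying the configuration hash and the per-stage seeds. All randomness
derives from one master seed through named SHA-256 substreams, so a run is
reproducible from configuration + seed alone, and `resume=True` regenerates
any deleted artifact bit-identically. Constant columns (e.g. a range flag
that never fires in a split) are dropped with a warning before Z-scoring,
since a zero-variance feature cannot be standardized.

The metric report has one row per (model, split) for the four
ML families plus the scorecard across validation/test/external. The
scorecard's validation row scores the training pool itself (its LOO analogue
would require refitting the binning per fold and is out of scope).

## Problem sizes in tests and the acceptance script

Experiments run at the study scale, n = 188 per cohort. The 50-cohort
selection-recovery experiment uses mean/mode imputation throughout: it
measures selection, not imputation, and the iterative random-forest imputer
(which the pipeline default retains) adds nothing to that question. The
acceptance script's classifier comparison evaluates on the stratified
held-out fifth of one cohort (38 patients) with grids as shipped.

## Known limitations

- Generator features are conditionally independent given the class; real
  laboratory panels are correlated within class, which would lower selection
  stability at the same marginal effect sizes.
- MCAR missingness only; no MAR/MNAR mechanism, no multiple imputation.
- The near-ceiling class separation makes the fitted KS statistic ≈ 1 and
  the risk transition sharp, so the default risk bands are much narrower
  than they would be on noisier real data.
- The scorecard's probability bands inherit KDE boundary bias at the extreme
  ends of the score range; with well-separated classes this is immaterial,
  but on overlapping data a boundary-corrected density estimate would be
  preferable.
- External-cohort drift is a location/scale perturbation only; no
  site-specific assay recalibration or covariate shift in the binary
  composites.
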