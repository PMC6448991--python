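# Methods

`metapair` implements the analytical machinery of a nested case-control
untargeted LC-MS metabolomics study of an incident disease endpoint (the
motivating setting is incident type 2 diabetes): discovery of predictive
features in matched pairs, matched-pair effect estimation, long-term
biomarker reproducibility, and risk-score comparison.  Because the cohorts
such studies use are not public, the package ships a synthetic-cohort
generator with known ground truth; every downstream stage is validated by
recovering what the generator planted.

## Synthetic cohort generator

The generator emulates a 1:1 matched nested case-control design: each case
is matched to one control of the same sex with age within +/-2 years.  A
configurable fraction of pairs contributes a second sample at follow-up
(both members, same subject ids, a later timepoint).

**Intensity model.**  Feature intensities are log-normal; all structure is
imposed on the natural-log scale with unit total variance per feature, then
exponentiated.  For subject *s* and occasion *t*,

    x_st = mu + b_s + e_st,    b_s ~ N(0, rho),  e_st ~ N(0, 1 - rho)

so the correlation between the two sampling occasions equals the target ICC
`rho` (configurable per feature).  Informative features add `effect`
(standardized mean difference, SD units) to case samples; case follow-up
samples add a further `progression_shift` in the direction of the baseline
effect, optionally differing by diagnosis-timing group (A: sampled before
diagnosis, B: same year, C: after; group sizes follow the 26/52/109
proportions of the motivating design).  Default generator effects span
0.2-0.8 SD; this range is a plausible convention for metabolite biomarkers,
not a value calibrated to any specific cohort.

**Risk factors and covariate structure.**  A latent case liability `L`
(cases ~N(1,1), controls ~N(0,1)) drives 13 continuous traditional risk
factors (fasting and 2h glucose, BMI, HOMA indices, lipids, blood pressure,
diet) plus ordinal smoking/education/activity, with loadings whose
directions match the usual case-control contrasts.  A second latent factor,
independent of `L` by construction, is shared between informative features
and the adiposity/glycaemia factors: features therefore correlate with BMI,
2h-PG and HOMA-IR without that correlation confounding case status.  This
separation is deliberate — with all effect sizes zero the generator is an
exact null for every discovery statistic, which the test-suite exploits.
Risk factors are constant within subject across occasions; that is a known
simplification (real BMI drifts over 10 years).

**Instrumental structure.**  Pairs (with their follow-up samples) are
assigned to batches as whole blocks — pairs never straddle a batch — and
shuffled within batch; pooled-QC injections are interleaved every
`qc_interval` study injections.  QC truth is the pooled mean of all study
samples with 2% log-normal technical noise, typical replicate-injection
repeatability for abundant features and small enough that QC dispersion is
drift-dominated.  `inject_batch_drift` multiplies intensities by a per-batch
level factor (log-SD `drift_amplitude/2` by default, configurable) and a
log-linear monotone drift over injection order with total log amplitude
`drift_amplitude` and random per-feature/batch sign.  `inject_missingness`
masks study cells with probability logistic-decreasing in standardized log
intensity, intercept calibrated by root finding so the overall rate matches
`missing_rate`; QC samples are never masked, and the mask is returned so
imputation can be scored.

**What the generator does not emulate:** raw spectra, m/z and isotope
structure, retention-time drift, correlated feature blocks beyond the
planted covariate factor, non-log-normal heavy tails, and longitudinal
drift in risk factors.  Passing tests therefore demonstrate correctness of
the algorithms under a clean log-normal world, not performance on any real
cohort.

## Preprocessing

**Drift correction** works per feature and batch on the log scale.  A curve
over injection order is fitted to the QC injections; the family is selected
by leave-one-out error among constant, linear, and a cubic smoothing spline
(GCV-smoothed), requiring a 5% LOO improvement before adopting a more
flexible family.  After dividing out the curve, batch QC medians are aligned
exactly to the global QC median.  Batches with fewer than 3 usable QC points
fall back to median-only correction (logged), and a per-feature guard
reverts to median-only, then to no correction, whenever the QC CV would not
improve — so correction never makes a feature worse, and re-application is
an identity (the constant/linear fits are projections followed by an exact
median alignment).

**Feature aggregation** groups redundant features (adducts, isotopologues,
in-source fragments) by single linkage within platform/mode: edges require
retention-time difference <= `rt_tolerance` (default 0.05 min) and Spearman
correlation >= `corr_threshold` (default 0.8) over study samples; clusters
are connected components.  Each cluster is represented by its
highest-median-intensity member (best-detected ion proxy) or optionally the
member mean.  Defaults are conventions, configurable, since published
aggregation settings vary by laboratory.

**Imputation** replaces each missing cell by a draw from a normal
distribution truncated to the open interval (0, m_f), where m_f is the
feature's lowest observed intensity — the standard "below detection limit"
reading.  The distribution's location and spread inside the support are not
pinned down by that convention; this implementation centres mass
mid-interval (mean m_f/2, SD m_f/4), which is documented and configurable in
the obvious way by editing the call.  A QC-CV filter (default 30%, a common
community convention) is available but not applied by default.

## Discovery: multilevel PLS in repeated double cross-validation

The matched design is reduced to within-pair differences: for every pair,
`d = z_case - z_control` on per-feature standardized log intensities, plus
its negation, labelled +1/-1.  Matching factors are pair-constant and cancel
exactly; the +/- duplication makes the two-class problem symmetric.

A sparse-PLS pre-filter (soft-thresholded loading weights, run per
chromatographic platform, union of supports over components) removes the
bulk of uninformative features cheaply before the expensive engine runs.

The rdCV engine splits pairs — never single +/- rows — into outer folds.
Within each outer training set, an inner cross-validation tunes the number
of PLS components while variables are eliminated stepwise: at each step the
fraction `elimination_ratio` (default 20%) of variables with the lowest
`|loading weight x inner-relation coefficient|` (summed over components) is
dropped, down to 2 variables.  The chosen model is the *smallest* variable
set whose inner misclassification is within one standard error of the
minimum (parsimony rule).  The outer fold, untouched by any of this, yields
the reported misclassification.  Every repetition x outer fold produces a
full ranking of the features (chosen set first, by final-model importance;
then eliminated features in reverse removal order); the importance ranking
score is the mean rank (rank-sum available), so lower = more important, and
a feature that survives every elimination in every fold scores exactly 1.
Defaults (20 repetitions, 6 outer and 5 inner folds, <=5 components) are
desk-scale choices; the published analyses this emulates do not print
theirs.

Permutation validation flips pair orientations at random — the correct null
for the +/- structure — re-runs the engine, and reports
`p = (1 + #{null misclassification <= observed}) / (1 + n_permutations)`.

The PLS1 core is a minimal NIPALS implementation in numpy: the engine
performs up to ~10^6 small fits during permutation runs, and per-call
overhead dominates with a general-purpose implementation.  Its predictions
are checked against scikit-learn's `PLSRegression` in the test suite, and
its one-component direction against the closed form (covariance with the
class vector).

## Matched-pair inference

For 1:1 pairs the conditional likelihood is logistic regression on
within-pair differences without intercept: each pair contributes
`exp(b'd_i) / (1 + exp(b'd_i))`.  The implementation maximizes this by
Newton iterations with step halving (gradient tolerance 1e-8), flags
complete/quasi-complete separation (diverging coefficients) instead of
silently diverging, reports Wald CIs from the observed information, and
rejects collinear covariates by name.  Solutions are verified against
brute-force Nelder-Mead maximization of the same likelihood and against the
classic discordant-pair identity (binary exposure: OR = ratio of discordant
counts).

The adjustment ladder is: crude; model 1 (fasting glucose, BMI); model 2
(plus physical activity, education, smoking as full indicator sets with the
first-listed level as reference, and alcohol, fibre, red/processed meat,
coffee); model 3 (plus total cholesterol, triacylglycerols, systolic and
diastolic blood pressure).  Odds ratios are reported per SD increment
(metabolite standardized over all included samples) and per quartile (Q2-Q4
vs Q1; cut points over cases+controls combined — a documented choice, since
controls-only cuts are an equally defensible convention).  The sensitivity
exclusion removes pairs whose case had fasting glucose >= 5.9 mmol/l AND 2h
glucose > 11.1 mmol/l at baseline, or a diagnosis within 2 years; the
conjunctive reading follows the stated rule literally, with an `or_glucose`
flag for the disjunctive reading.  Multiplicity is handled by
Benjamini-Hochberg FDR (via statsmodels).

## Reproducibility and change over time

Long-term reproducibility among controls is ICC(1,1), the one-way
random-effects intra-class correlation for single measurements:
`(MSB - MSW) / (MSB + MSW)` for two occasions, with the exact F-based
confidence interval.  If the occasion means differ (paired t-test, alpha
0.05), the ICC is recomputed on rank-transformed data and flagged — a mean
shift then no longer masquerades as irreproducibility, at the cost of the
estimate being monotone-invariant only.  Bands: < 0.4 weak-to-moderate,
0.4-0.75 intermediate-to-good, > 0.75 excellent.  A two-way ICC(2,1) variant
is provided for users who prefer occasion as a crossed factor.

Change over time among cases uses a subject-random-intercept linear model.
In the balanced two-occasion case with no covariates the REML solution is
the paired t-test in closed form, and the implementation uses that closed
form directly; the iterative REML fit (statsmodels `MixedLM`) is reserved
for models with diagnosis-timing groups (time x group interactions) or
covariates, where no closed form exists.  Groups with fewer than 2 subjects
are merged into the reference with a log entry.  Medication-stratified
paired t-tests flag a metabolite "affected" when the per-subject changes
differ across strata (one-way ANOVA, alpha 0.05).

## Risk prediction

Scores are weighted sums of standardized predictors with unconditional
logistic-regression weights (tiny ridge, 1e-6, for collinearity;
near-separation flagged).  Prediction deliberately uses unconditional
logistic regression on individuals rather than the matched conditional
likelihood: a risk score must apply to unmatched future subjects.  The
traditional pool contains the 14 factors listed above under inference minus
alcohol (which only enters model 2); TS-2h-PG excludes the 2h glucose.

Variable selection reuses the rdCV skeleton with a random forest,
eliminating variables by lowest mean permutation importance measured on
inner validation folds (impurity importance available as a faster option)
and applying the same one-SE parsimony rule to the inner AUC.  The final
set is the top *s* variables by mean rank with *s* the median chosen size
across outer models.

Performance is the rank-sum (Mann-Whitney) AUC with tie correction —
checked exactly against brute-force concordant-pair counting — over
repeated random train/test splits (default 60/40; 500 splits by default at
desk scale, configurable to the 10,000 used in full-scale studies), with
percentile CIs and Wilcoxon signed-rank comparisons over the paired split
AUCs.  Weights are refitted on each training split with variable sets held
fixed (refit-per-split is the conservative reading; frozen weights are a
one-line change).  Incremental value uses the continuous (category-free)
NRI and the IDI with standard asymptotic SEs; scores are converted to risks
by one-dimensional logistic calibration unless the caller passes risks.  A
misclassification-rescue report gives the fraction of reference-model
misclassifications that a candidate model corrects at a stated risk
threshold (default 0.5).

## Correlations

Spearman matrices use average-rank tie handling with t-approximation
p-values and Bonferroni flags.  Partial Spearman is Pearson correlation of
rank residuals after least-squares adjustment for the rank-transformed
covariates, with degrees of freedom reduced accordingly; with no covariates
it reduces exactly to plain Spearman.  Case-control status enters partial
adjustments as an indicator (stratified estimation was the alternative).

## Numerical and design notes

- All randomness flows from named seeds; generator output is bit-identical
  under a fixed seed, and pipeline JSON summaries contain no timestamps so
  identical config + seed give identical summaries.
- Newton solver: gradient norm < 1e-8, max 200 iterations, separation
  declared when a coefficient's magnitude exceeds 15.
- Degenerate inputs are first-class: zero-variance metabolites, constant
  scores, all-zero pair differences, strata below size 2, batches with < 3
  QC points, and features with no observed values all have defined,
  logged behaviour.
- Problem sizes in the test suite and acceptance script (200-500 pairs,
  40-500 features, 10 rdCV repetitions, 99-permutation nulls, 500 splits)
  are desk-scale choices that keep each recovery check adequately powered
  (targets sit 2.5-3 sampling SDs inside their tolerance bands) while a
  full run stays comfortable on a laptop.

## Known limitations

- The generator's clean log-normal world understates real LC-MS pathology
  (correlated noise, nonlinear saturation, RT drift, annotation ambiguity).
- ICC confidence intervals assume normality; the rank-fallback estimate has
  no exact CI theory and reuses the F interval on ranks.
- The mixed model supports exactly two occasions.
- NRI/IDI p-values use asymptotic SEs, which are anticonservative in small
  samples.
- No external-cohort validation layer: the package validates algorithms
  against planted truth, not biomarkers against biology.
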