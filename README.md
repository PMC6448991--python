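# metapair

**Matched case-control untargeted metabolomics, end to end.**

`metapair` is a Python toolkit for the analysis pattern used in nested
case-control biomarker studies of incident disease (the motivating setting
is incident type 2 diabetes in a prospective cohort): plasma samples from
1:1 matched case-control pairs are profiled by untargeted LC-MS, candidate
metabolites are discovered by multivariate classification on the matched
structure, their effects are estimated by conditional logistic regression
under increasing covariate adjustment, their long-term reproducibility is
gauged on repeat samples, and their incremental value for risk prediction
is compared against traditional risk factors.

Because such cohort data are not public, the package includes a first-class
synthetic-cohort generator with known ground truth (planted effect sizes,
target within-person correlations, injected batch drift and missingness),
so every stage can be validated by recovering what was planted.

## What it computes

- **Synthetic cohorts** (`metapair.simulate`): 1:1 pairs matched on sex and
  age +/-2 y, informative features with stated standardized effects, 14
  traditional risk factors driven by a latent liability, pooled-QC
  injections, multiplicative batch levels plus injection-order drift,
  intensity-dependent missingness, paired follow-up samples with target
  ICCs and case-specific progression shifts.
- **Preprocessing** (`metapair.preprocess`): QC-anchored drift correction
  (per feature x batch, LOO-selected constant/linear/spline curve, exact
  batch median alignment), aggregation of redundant features by
  RT-window + Spearman-correlation connected components, truncated-normal
  imputation below each feature's observed minimum.
- **Discovery** (`metapair.discovery`): the multilevel construction
  (within-pair differences and their negations, labelled +/-1), a
  sparse-PLS pre-filter per chromatographic platform, and multilevel PLS
  inside repeated double cross-validation with stepwise variable
  elimination, one-SE parsimony, mean-rank importance scores and
  pair-orientation permutation validation.
- **Matched inference** (`metapair.inference`): Newton-solved conditional
  logistic regression for 1:1 pairs with separation diagnostics, per-SD and
  quartile odds ratios under the crude/model-1/2/3 adjustment ladder,
  sensitivity exclusion of near-diabetic or early-diagnosed cases,
  Benjamini-Hochberg FDR.
- **Reproducibility** (`metapair.reproducibility`): ICC(1,1) with exact F
  confidence intervals and a rank-transform fallback when occasion means
  shift, random-intercept change models (closed-form paired t in the
  balanced case), medication-stratified paired tests.
- **Risk prediction** (`metapair.prediction`): random-forest variable
  selection in the same rdCV skeleton, logistic-weighted standardized
  scores (metabolite score MS, traditional score TS and TS without 2h
  glucose, combined score CS), rank-sum AUC over repeated 60/40 splits with
  percentile CIs and signed-rank comparisons, continuous NRI and IDI, and
  misclassification-rescue reports.
- **Correlations** (`metapair.association`): Spearman matrices with
  Bonferroni flags, partial Spearman on rank residuals.

See `docs/methods.md` for the models, assumptions, defaults and
limitations.

## Worked example

```python
import numpy as np
from metapair.simulate import CohortConfig, generate_cohort
from metapair.discovery import RdcvConfig, mlpls_rdcv, multilevel_transform, select_top
from metapair.inference import adjustment_model, per_sd_or

config = CohortConfig(n_pairs=200, n_features=300, n_informative=15,
                      effect_sizes=0.6, missing_rate=0.0,
                      drift_amplitude=0.0, followup_fraction=0.0, seed=1)
cohort = generate_cohort(config)

pm = multilevel_transform(cohort.feature_table, cohort.design)
ranked = mlpls_rdcv(pm, RdcvConfig(n_repetitions=5, seed=2))
top = select_top(ranked, threshold=30)
planted = set(cohort.truth.index[cohort.truth.informative])
print(f"misclassification: {ranked.misclassification.mean():.3f}")
print(f"top-ranked features: {len(top)}, of which planted: "
      f"{len(set(top) & planted)}/{len(planted)}")

f = top[0]
est = per_sd_or(cohort.design, np.log(cohort.feature_table.intensities[f]),
                adjustment_model("model1"), name=f)
print(f"{f}: OR per SD {est.odds_ratio:.2f} "
      f"({est.ci_low:.2f}-{est.ci_high:.2f}), p={est.p:.2g}")
```

Output:

```
misclassification: 0.133
top-ranked features: 19, of which planted: 15/15
F00186: OR per SD 2.73 (1.91-3.91), p=3.7e-08
```

The engine classifies held-out pairs with ~13% error, all 15 planted
biomarkers sit among the 19 top-ranked features, and the
conditional-logistic odds ratio per SD is well above 1 with a tight CI, as
expected for a 0.6 SD planted shift.

## Command line

The `metapair` CLI chains the stages from one YAML config
(`simulate`, `preprocess`, `discover`, `infer`, `repro`, `predict`, `all`):

```bash
metapair all --config run.yaml --seed 11 --out-dir results/run1
```

Each stage writes delimited-text tables plus a JSON summary; identical
config + seed reproduce identical summaries.

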