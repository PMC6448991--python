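"""Long-term reproducibility and change-over-time of biomarkers.

Reproducibility over two sampling occasions is gauged by the one-way
random-effects intra-class correlation for single measurements, ICC(1,1):

    ICC = (MSB - MSW) / (MSB + (k-1) MSW),    k = 2 occasions

with an exact F-based confidence interval.  If the occasion means differ
significantly (paired t-test at 0.05) the ICC is recomputed on
rank-transformed data, mirroring the convention that a systematic shift
should not masquerade as poor reproducibility.  Conventional bands: ICC <
0.4 weak-to-moderate, 0.4-0.75 intermediate-to-good, > 0.75 excellent.

Change over time among cases uses a subject-random-intercept linear model
(REML); in the balanced two-occasion case with no covariates the time effect
and its SE coincide with the paired t-test, which is used directly then.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class IccResult:
    icc: float
    ci: tuple[float, float]
    used_rank_transform: bool
    mean_difference_p: float
    n_subjects: int
    undefined: bool = False

    @property
    def band(self) -> str:
        if self.undefined or not np.isfinite(self.icc):
            return "undefined"
        if self.icc > 0.75:
            return "excellent"
        if self.icc >= 0.4:
            return "intermediate_to_good"
        return "weak_to_moderate"


def _icc_oneway(x: np.ndarray, alpha: float) -> tuple[float, tuple[float, float]]:
    n, k = x.shape
    grand = x.mean()
    subj_means = x.mean(axis=1)
    msb = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((x - subj_means[:, None]) ** 2) / (n * (k - 1))
    if msb + (k - 1) * msw == 0:
        return np.nan, (np.nan, np.nan)
    if msw == 0:
        return 1.0, (1.0, 1.0)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f0 = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    fl = f0 / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f0 * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (fl - 1) / (fl + k - 1)
    hi = (fu - 1) / (fu + k - 1)
    return float(icc), (float(lo), float(hi))


def icc_two_occasion(values, alpha: float = 0.05) -> IccResult:
    """ICC(1,1) between two sampling occasions with rank-transform fallback.

    ``values`` is subjects x 2 (baseline, follow-up); rows with a missing
    occasion are dropped and logged.  Requires >= 3 complete subjects.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("values must be subjects x 2 occasions")
    complete = ~np.isnan(x).any(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("icc_two_occasion: dropped %d subjects with a missing "
                    "occasion", dropped)
    x = x[complete]
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 complete subjects, got {n}")
    if np.all(x == x.flat[0]):
        return IccResult(np.nan, (np.nan, np.nan), False, 1.0, n, undefined=True)

    d = x[:, 1] - x[:, 0]
    if np.allclose(d.std(ddof=1), 0.0):
        mean_p = 0.0 if abs(d.mean()) > 0 else 1.0
    else:
        mean_p = float(stats.ttest_rel(x[:, 1], x[:, 0]).pvalue)
    use_rank = mean_p < 0.05
    work = x
    if use_rank:
        work = stats.rankdata(x.ravel()).reshape(x.shape)
    icc, ci = _icc_oneway(work, alpha)
    return IccResult(icc=icc, ci=ci, used_rank_transform=use_rank,
                     mean_difference_p=mean_p, n_subjects=n,
                     undefined=not np.isfinite(icc))


def icc_two_way(values, alpha: float = 0.05) -> IccResult:
    """Two-way random-effects single-measurement ICC(2,1), offered as an
    alternative when occasion is treated as a crossed factor.  The CI is the
    approximate F interval on MSR/MSE."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 3:
        raise ValueError("need >= 3 complete subjects")
    grand = x.mean()
    msr = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
    mse = (np.sum((x - x.mean(axis=1, keepdims=True)
                   - x.mean(axis=0, keepdims=True) + grand) ** 2)
           / ((n - 1) * (k - 1)))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return IccResult(np.nan, (np.nan, np.nan), False, np.nan, n, True)
    icc = (msr - mse) / denom
    if mse == 0:
        ci = (float(icc), float(icc))
    else:
        f0 = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f0 / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f0 * stats.f.ppf(1 - alpha / 2, df2, df1)
        ci = (float((fl - 1) / (fl + k - 1)), float((fu - 1) / (fu + k - 1)))
    return IccResult(float(icc), ci, False, np.nan, n)


# ---------------------------------------------------------------------------
# change over time
# ---------------------------------------------------------------------------

@dataclass
class ChangeModelResult:
    time_effect: float
    se: float
    t_stat: float
    p: float
    interactions: pd.DataFrame = field(default_factory=pd.DataFrame)
    covariate_effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    method: str = "paired_t"


def mixed_change_model(values, group=None, covariates: pd.DataFrame | None = None,
                       ) -> ChangeModelResult:
    """Follow-up-vs-baseline change with optional diagnosis-timing groups.

    ``values`` is subjects x 2 (baseline, follow-up).  With no groups or
    covariates the balanced two-occasion REML fit is the paired t-test in
    closed form, which is returned directly.  Otherwise a subject-random-
    intercept linear mixed model of intensity on time, group, time x group
    and covariates is fitted by REML; groups with fewer than 2 subjects are
    merged into the reference with a log entry.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("values must be subjects x 2 occasions")
    n = x.shape[0]
    d = x[:, 1] - x[:, 0]
    no_cov = covariates is None or covariates.shape[1] == 0
    trivial_groups = group is None or pd.Series(list(group)).nunique() <= 1
    # balanced two-occasion REML has a closed form: the paired t-test;
    # iterate only when groups or covariates unbalance the design
    if no_cov and trivial_groups:
        sd = d.std(ddof=1)
        if sd == 0:
            eff = float(d.mean())
            return ChangeModelResult(eff, 0.0, 0.0 if eff == 0 else np.inf,
                                     1.0 if eff == 0 else 0.0)
        se = sd / np.sqrt(n)
        t = d.mean() / se
        p = 2 * stats.t.sf(abs(t), n - 1)
        return ChangeModelResult(float(d.mean()), float(se), float(t), float(p))

    import statsmodels.formula.api as smf

    groups = pd.Series(["all"] * n) if group is None else pd.Series(list(group))
    counts = groups.value_counts()
    small = counts[counts < 2].index.tolist()
    levels = sorted(groups.unique())
    ref = levels[0]
    if small:
        logger.info("groups %s have < 2 subjects; interactions dropped "
                    "(merged into reference %r)", small, ref)
        groups = groups.replace({g: ref for g in small})

    long = pd.DataFrame({
        "value": x.ravel(order="F"),
        "time": np.repeat([0.0, 1.0], n),
        "subject": np.tile(np.arange(n), 2),
        "group": np.tile(groups.to_numpy(), 2),
    })
    formula = "value ~ time"
    if groups.nunique() > 1:
        formula += " + C(group) + time:C(group)"
    if covariates is not None and covariates.shape[1] > 0:
        cov2 = pd.concat([covariates.reset_index(drop=True)] * 2,
                         ignore_index=True)
        long = pd.concat([long, cov2], axis=1)
        formula += " + " + " + ".join(covariates.columns)
    fit = smf.mixedlm(formula, long, groups=long["subject"]).fit(reml=True)
    inter_rows = []
    for name in fit.params.index:
        if name.startswith("time:"):
            g = name.split("[T.")[-1].rstrip("]")
            inter_rows.append({"group": g, "estimate": fit.params[name],
                               "se": fit.bse[name], "p": fit.pvalues[name]})
    cov_rows = [{"term": t, "estimate": fit.params[t], "se": fit.bse[t],
                 "p": fit.pvalues[t]}
                for t in (covariates.columns if covariates is not None else [])
                if t in fit.params.index]
    return ChangeModelResult(
        time_effect=float(fit.params["time"]), se=float(fit.bse["time"]),
        t_stat=float(fit.params["time"] / fit.bse["time"]),
        p=float(fit.pvalues["time"]),
        interactions=pd.DataFrame(inter_rows),
        covariate_effects=pd.DataFrame(cov_rows),
        method="mixed",
    )


# ---------------------------------------------------------------------------
# medication-stratified paired tests
# ---------------------------------------------------------------------------

@dataclass
class StratifiedTestResult:
    per_stratum: pd.DataFrame
    affected: bool
    interaction_p: float


def medication_stratified_tests(values, medication) -> StratifiedTestResult:
    """Paired t-test of follow-up minus baseline within each medication
    stratum; the metabolite is flagged "affected" when the per-subject
    changes differ across strata (one-way ANOVA p < 0.05).

    Strata with fewer than 2 subjects are skipped with a log entry; with a
    single usable stratum no interaction is computed.
    """
    x = np.asarray(values, dtype=float)
    med = pd.Series(list(medication))
    d = x[:, 1] - x[:, 0]
    rows, groups_for_anova = [], []
    for level, idx in med.groupby(med).groups.items():
        dd = d[np.asarray(list(idx))]
        if len(dd) < 2:
            logger.info("medication stratum %r has %d subject(s), skipped",
                        level, len(dd))
            continue
        if np.allclose(dd.std(ddof=1), 0.0):
            t_stat = 0.0 if np.allclose(dd.mean(), 0.0) else np.inf
            p = 1.0 if np.allclose(dd.mean(), 0.0) else 0.0
        else:
            res = stats.ttest_1samp(dd, 0.0)
            t_stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"stratum": level, "n": len(dd), "mean_change": dd.mean(),
                     "t": t_stat, "p": p})
        groups_for_anova.append(dd)
    per = pd.DataFrame(rows, columns=["stratum", "n", "mean_change", "t", "p"])
    if len(groups_for_anova) < 2:
        return StratifiedTestResult(per, affected=False, interaction_p=np.nan)
    if all(np.allclose(g, groups_for_anova[0][0]) for g in groups_for_anova) \
            and all(np.allclose(g.std(ddof=1), 0) for g in groups_for_anova):
        return StratifiedTestResult(per, affected=False, interaction_p=1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_p = stats.f_oneway(*groups_for_anova).pvalue
    f_p = float(f_p) if np.isfinite(f_p) else 1.0
    return StratifiedTestResult(per, affected=f_p < 0.05, interaction_p=f_p)
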