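"""Conditional logistic regression for 1:1 matched pairs.

For a matched pair *i* with case-minus-control covariate difference ``d_i``
the conditional likelihood contribution is ``exp(b'd_i) / (1 + exp(b'd_i))``
— logistic regression on within-pair differences without an intercept.  The
likelihood is maximized by Newton iterations with step halving; standard
errors come from the observed information and confidence intervals are Wald.
Matching factors are pair-constant and cancel in ``d_i`` exactly.

The module also provides the adjustment ladder used throughout (crude /
model 1 / model 2 / model 3), per-SD and per-quartile odds ratios, the
sensitivity exclusion of prevalent-like cases, and Benjamini-Hochberg FDR
adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .containers import PairedDesign

logger = logging.getLogger(__name__)

_Z975 = float(norm.ppf(0.975))

# categorical covariates enter as full indicator sets; the first listed
# level is the reference
SMOKING_LEVELS = ["smoker", "former_smoker", "occasional_smoker", "non_smoker"]
EDUCATION_LEVELS = ["elementary", "vocational", "secondary", "university"]
ACTIVITY_LEVELS = ["inactive", "moderately_inactive", "moderately_active", "active"]


@dataclass
class ConditionalLogitFit:
    """Maximum conditional-likelihood fit for 1:1 matched pairs."""

    params: pd.Series
    se: pd.Series
    loglik: float
    n_pairs: int
    converged: bool
    separation: bool = False

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def conf_int(self) -> pd.DataFrame:
        lo = np.exp(self.params - _Z975 * self.se)
        hi = np.exp(self.params + _Z975 * self.se)
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    @property
    def p_values(self) -> pd.Series:
        with np.errstate(invalid="ignore", divide="ignore"):
            z = self.params / self.se
        return pd.Series(2 * norm.sf(np.abs(z)), index=self.params.index)


def _check_collinear(D: np.ndarray, names: list[str]) -> None:
    nonzero = [j for j in range(D.shape[1]) if np.any(D[:, j] != 0)]
    sub = D[:, nonzero]
    if sub.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(sub)
    if rank == sub.shape[1]:
        return
    # name a minimal set of dependent columns by greedy scan
    dependent = []
    basis: list[int] = []
    for j in nonzero:
        cand = D[:, basis + [j]]
        if np.linalg.matrix_rank(cand) == len(basis) + 1:
            basis.append(j)
        else:
            dependent.append(names[j])
    raise ValueError(f"collinear covariates: {dependent}")


def fit_conditional_logistic(design: PairedDesign, exposure: pd.Series,
                             covariates: pd.DataFrame | None = None,
                             tol: float = 1e-8, max_iter: int = 200,
                             ) -> ConditionalLogitFit:
    """Fit the 1:1 matched conditional likelihood.

    ``exposure`` and ``covariates`` are per-sample (indexed by sample id;
    categoricals pre-expanded to indicators).  Complete separation is flagged
    rather than silently diverging; collinear covariates raise with the
    offending column names.
    """
    cols = pd.DataFrame({"exposure": exposure.astype(float)})
    if covariates is not None and covariates.shape[1] > 0:
        cols = cols.join(covariates.astype(float))
    if cols.isna().any().any():
        bad = cols.columns[cols.isna().any()].tolist()
        raise ValueError(f"missing values in columns: {bad}")
    D = (cols.loc[design.case_ids].to_numpy()
         - cols.loc[design.control_ids].to_numpy())
    names = cols.columns.tolist()
    _check_collinear(D, names)

    k = D.shape[1]
    beta = np.zeros(k)
    converged, separation = False, False
    for _ in range(max_iter):
        eta = D @ beta
        mu = expit(eta)
        grad = D.T @ (1.0 - mu)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = (D * w[:, None]).T @ D
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        ll_old = float(log_expit(eta).sum())
        lam = 1.0
        while lam > 1e-8:
            cand = beta + lam * step
            if float(log_expit(D @ cand).sum()) >= ll_old - 1e-12:
                break
            lam /= 2.0
        beta = beta + lam * step
        if np.max(np.abs(beta)) > 25.0:
            break
    # a diverging coefficient means the discordant pattern is one-sided:
    # the MLE sits at infinity (complete or quasi-complete separation)
    if np.max(np.abs(beta), initial=0.0) > 15.0:
        separation = True
        converged = False

    eta = D @ beta
    mu = expit(eta)
    loglik = float(log_expit(eta).sum())
    w = mu * (1.0 - mu)
    H = (D * w[:, None]).T @ D
    se = np.full(k, np.inf)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        good = diag > 0
        se[good] = np.sqrt(diag[good])
    except np.linalg.LinAlgError:
        pass
    zero_cols = ~np.any(D != 0, axis=0)
    beta = beta.copy()
    beta[zero_cols] = 0.0
    se[zero_cols] = np.inf
    if separation:
        se[:] = np.inf
        logger.warning("complete or quasi-complete separation: "
                       "coefficients diverge, fit flagged")
    return ConditionalLogitFit(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        loglik=loglik, n_pairs=len(D),
        converged=converged, separation=separation,
    )


# ---------------------------------------------------------------------------
# adjustment ladder
# ---------------------------------------------------------------------------

@dataclass
class AdjustmentModel:
    """A labelled covariate set; model1 < model2 < model3 are nested."""

    label: str
    continuous: list[str] = field(default_factory=list)
    categorical: dict[str, list[str]] = field(default_factory=dict)

    def build_matrix(self, meta: pd.DataFrame) -> pd.DataFrame:
        out = meta[self.continuous].astype(float).copy()
        for name, levels in self.categorical.items():
            cat = pd.Categorical(meta[name], categories=levels)
            dummies = pd.get_dummies(cat, prefix=name, drop_first=True)
            dummies.index = meta.index
            out = out.join(dummies.astype(float))
        return out


def adjustment_model(label: str) -> AdjustmentModel:
    """The study's adjustment ladder: model 1 (FPG, BMI), model 2 (+ lifestyle),
    model 3 (+ lipids and blood pressure)."""
    if label == "crude":
        return AdjustmentModel("crude")
    m1 = ["fpg", "bmi"]
    m2_cont = m1 + ["alcohol", "fibre", "meat", "coffee"]
    m2_cat = {"activity": ACTIVITY_LEVELS, "education": EDUCATION_LEVELS,
              "smoking": SMOKING_LEVELS}
    if label == "model1":
        return AdjustmentModel("model1", continuous=m1)
    if label == "model2":
        return AdjustmentModel("model2", continuous=m2_cont, categorical=m2_cat)
    if label == "model3":
        m3_cont = m2_cont + ["total_cholesterol", "triacylglycerols", "sbp", "dbp"]
        return AdjustmentModel("model3", continuous=m3_cont, categorical=m2_cat)
    raise ValueError(f"unknown adjustment model: {label!r}")


@dataclass
class EffectEstimate:
    """Per-metabolite odds ratio under one adjustment model."""

    exposure: str
    model: str
    contrast: str      # "per_sd" or "Q2".."Q4"
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n_pairs: int
    q: float | None = None

    def as_dict(self) -> dict:
        return {
            "exposure": self.exposure, "model": self.model,
            "contrast": self.contrast, "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p, "q": self.q, "n_pairs": self.n_pairs,
        }


def _included_samples(design: PairedDesign) -> np.ndarray:
    return np.concatenate([design.case_ids, design.control_ids])


def per_sd_or(design: PairedDesign, values: pd.Series,
              model: AdjustmentModel, name: str = "metabolite") -> EffectEstimate:
    """Odds ratio per SD increment of a metabolite under ``model``.

    The metabolite is standardized to unit SD over all included samples, so
    the estimate is invariant to its measurement scale.
    """
    ids = _included_samples(design)
    v = values.loc[ids].astype(float)
    if v.isna().any():
        raise ValueError("metabolite values must be complete")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance metabolite")
    z = (v - v.mean()) / sd
    cov = model.build_matrix(design.meta.loc[ids])
    fit = fit_conditional_logistic(design, z, cov)
    return EffectEstimate(
        exposure=name, model=model.label, contrast="per_sd",
        odds_ratio=float(fit.odds_ratios["exposure"]),
        ci_low=float(fit.conf_int.loc["exposure", "ci_low"]),
        ci_high=float(fit.conf_int.loc["exposure", "ci_high"]),
        p=float(fit.p_values["exposure"]), n_pairs=fit.n_pairs,
    )


def quartile_or(design: PairedDesign, values: pd.Series,
                model: AdjustmentModel, name: str = "metabolite",
                ) -> list[EffectEstimate]:
    """Odds ratios for quartiles Q2-Q4 versus Q1.

    Cut points are quartiles over all included samples; ties collapsing a
    boundary are resolved by nudging to the next distinct value (logged).
    """
    ids = _included_samples(design)
    v = values.loc[ids].astype(float)
    if v.nunique() < 4:
        raise ValueError("need at least 4 distinct metabolite values")
    edges = np.quantile(v, [0.25, 0.5, 0.75])
    distinct = np.unique(edges)
    if len(distinct) < 3:
        logger.info("tied quartile boundaries %s nudged by stable tie-breaking",
                    edges.tolist())
        uniq = np.unique(v)
        edges = np.array([uniq[min(np.searchsorted(uniq, e, side="right"),
                                   len(uniq) - 1)] for i, e in enumerate(edges)])
        edges = np.maximum.accumulate(edges + np.arange(3) * 1e-12)
    quart = np.searchsorted(edges, v, side="left")  # 0..3
    dummies = pd.DataFrame(
        {f"Q{k + 1}": (quart == k).astype(float) for k in (1, 2, 3)},
        index=v.index)
    cov = model.build_matrix(design.meta.loc[ids])
    out = []
    for k in (2, 3, 4):
        col = f"Q{k}"
        others = dummies.drop(columns=col).join(cov)
        fit = fit_conditional_logistic(design, dummies[col], others)
        out.append(EffectEstimate(
            exposure=name, model=model.label, contrast=col,
            odds_ratio=float(fit.odds_ratios["exposure"]),
            ci_low=float(fit.conf_int.loc["exposure", "ci_low"]),
            ci_high=float(fit.conf_int.loc["exposure", "ci_high"]),
            p=float(fit.p_values["exposure"]), n_pairs=fit.n_pairs,
        ))
    return out


def sensitivity_exclude(design: PairedDesign, fpg_col: str = "fpg",
                        pg2h_col: str = "pg2h",
                        time_col: str = "time_to_diagnosis",
                        or_glucose: bool = False,
                        ) -> tuple[PairedDesign, pd.DataFrame]:
    """Drop pairs whose case had near-diabetic glucose at baseline or was
    diagnosed within 2 years of baseline.

    The glucose rule excludes cases with FPG >= 5.9 mmol/l AND 2h plasma
    glucose > 11.1 mmol/l (strict on the 2h-PG side); ``or_glucose=True``
    switches to the disjunctive reading.  Cases with missing glucose values
    are retained and logged.  Returns the reduced design and an exclusion
    log (pair id, reason).
    """
    meta = design.meta
    records = []
    keep = []
    for pid, row in design.pairs.iterrows():
        case = meta.loc[row["case"]]
        fpg, pg2h = case.get(fpg_col, np.nan), case.get(pg2h_col, np.nan)
        ttd = case.get(time_col, np.nan)
        reason = None
        if pd.isna(fpg) or pd.isna(pg2h):
            logger.info("pair %s: missing glucose values, retained", pid)
        else:
            high_fpg, high_pg2h = fpg >= 5.9, pg2h > 11.1
            glucose_hit = (high_fpg or high_pg2h) if or_glucose \
                else (high_fpg and high_pg2h)
            if glucose_hit:
                reason = "abnormal_glucose"
        if reason is None and not pd.isna(ttd) and ttd <= 2.0:
            reason = "early_diagnosis"
        if reason:
            records.append({"pair_id": pid, "reason": reason})
        else:
            keep.append(pid)
    log = pd.DataFrame(records, columns=["pair_id", "reason"])
    return design.subset(keep), log


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q >= p elementwise)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
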