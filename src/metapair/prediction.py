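"""Risk-score construction and comparison.

Scores are weighted sums of standardized predictors with logistic-regression
weights: a metabolite score (MS) from selected metabolites, a traditional
risk score (TS) from 14 traditional risk factors (TS-2h-PG excludes the 2h
plasma glucose), a combined score (CS) selected over both pools, and fixed
covariate models.  Variable selection uses a random forest inside the same
repeated double cross-validation skeleton as the discovery engine,
eliminating variables by lowest permutation importance.  Performance is the
AUC of the ROC curve over repeated random train/test splits (rank-sum
formulation with tie correction), compared pairwise by Wilcoxon signed-rank
tests over the paired split AUCs, and incremental value is quantified by the
continuous net reclassification improvement (NRI) and the integrated
discrimination improvement (IDI).

Prediction deliberately uses unconditional logistic regression on
individuals, not the matched conditional likelihood: a risk score must apply
to unmatched future subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, rankdata, wilcoxon
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .discovery import RdcvConfig

logger = logging.getLogger(__name__)

_Z975 = float(norm.ppf(0.975))

#: the 14-factor traditional risk pool (ordinal-coded categoricals included)
TS_VARIABLES = ["age", "fpg", "bmi", "pg2h", "total_cholesterol",
                "triacylglycerols", "sbp", "dbp", "coffee", "fibre", "meat",
                "education", "activity", "smoking"]
TS_NO_2HPG_VARIABLES = [v for v in TS_VARIABLES if v != "pg2h"]

_ORDINAL = {
    "education": ["elementary", "vocational", "secondary", "university"],
    "activity": ["inactive", "moderately_inactive", "moderately_active", "active"],
    "smoking": ["smoker", "former_smoker", "occasional_smoker", "non_smoker"],
    "sex": ["F", "M"],
}


def encode_predictors(meta: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Numeric predictor matrix; categorical factors become ordinal codes."""
    out = {}
    for v in variables:
        col = meta[v]
        if v in _ORDINAL:
            out[v] = pd.Categorical(col, categories=_ORDINAL[v]).codes.astype(float)
        else:
            out[v] = col.astype(float)
    return pd.DataFrame(out, index=meta.index)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc_rank(scores, outcome) -> float:
    """AUC by the rank-sum (Mann-Whitney) formulation with tie correction.

    Equals the proportion of concordant case-control pairs, ties counted
    half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    r = rankdata(s)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# score models
# ---------------------------------------------------------------------------

@dataclass
class ScoreModel:
    """Logistic-weighted sum of standardized predictors.

    Standardization uses the training split's means and SDs; applying the
    model to test data reuses them, so train and test live on one scale.
    """

    label: str
    variables: list[str]
    means: np.ndarray
    sds: np.ndarray
    coef: np.ndarray
    intercept: float
    separation: bool = False

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        Z = (data[self.variables].to_numpy(dtype=float) - self.means) / self.sds
        return Z @ self.coef + self.intercept

    def risk(self, data: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(data))


def build_score(data: pd.DataFrame, outcome, variables: list[str],
                label: str = "score", ridge: float = 1e-6) -> ScoreModel:
    """Fit a :class:`ScoreModel` on training data.

    A tiny ridge penalty resolves collinearity; (quasi-)separation is flagged
    via very large weights, not silently accepted.
    """
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise ValueError(f"variables absent from data: {missing}")
    X = data[variables].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in predictors")
    y = np.asarray(outcome, dtype=int)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    sds[sds == 0] = 1.0
    Z = (X - means) / sds
    lr = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=2000)
    lr.fit(Z, y)
    coef = lr.coef_.ravel()
    sep = bool(np.max(np.abs(coef)) > 30)
    if sep:
        logger.warning("score %r: near-separation (max |coef| = %.1f)",
                       label, np.max(np.abs(coef)))
    return ScoreModel(label, list(variables), means, sds, coef,
                      float(lr.intercept_[0]), separation=sep)


# ---------------------------------------------------------------------------
# random-forest rdCV variable selection
# ---------------------------------------------------------------------------

@dataclass
class RfSelection:
    selected: list[str]
    ranking: pd.Series
    selection_frequency: pd.Series
    inner_auc: float
    chosen_sizes: list[int]


def _perm_importance(rf, Xv: np.ndarray, yv: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    base = auc_rank(rf.predict_proba(Xv)[:, 1], yv)
    imp = np.empty(Xv.shape[1])
    for j in range(Xv.shape[1]):
        sav = Xv[:, j].copy()
        Xv[:, j] = rng.permutation(sav)
        imp[j] = base - auc_rank(rf.predict_proba(Xv)[:, 1], yv)
        Xv[:, j] = sav
    return imp


def rf_rdcv_select(predictors: pd.DataFrame, outcome, config: RdcvConfig,
                   n_estimators: int = 100, importance: str = "permutation",
                   ) -> RfSelection:
    """Optimal-variable selection with a random forest in repeated double CV.

    Same skeleton as the discovery engine, on individuals rather than pairs:
    outer folds estimate performance, the inner loop eliminates the variables
    with lowest mean permutation importance (measured on inner validation
    folds; ``importance='impurity'`` uses the forest's impurity importances
    instead) and picks the smallest set within one SE of the best inner AUC.
    The returned set is the top *s* variables by mean rank, where *s* is the
    median chosen size over all outer models.
    """
    X_all = predictors.to_numpy(dtype=float)
    names = np.asarray(predictors.columns)
    y_all = np.asarray(outcome, dtype=int)
    const = X_all.std(axis=0) == 0
    if const.any():
        logger.info("dropping constant variables: %s", names[const].tolist())
        X_all, names = X_all[:, ~const], names[~const]
    n, p = X_all.shape
    if p == 0:
        raise ValueError("no non-constant predictors")
    if p == 1:
        return RfSelection([names[0]], pd.Series([1.0], index=names),
                           pd.Series([1.0], index=names), np.nan, [1])

    rng = np.random.default_rng(config.seed)
    rank_sum = np.zeros(p)
    sel_count = np.zeros(p)
    n_models = 0
    sizes: list[int] = []
    inner_aucs: list[float] = []

    def _rf(seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(n_estimators=n_estimators,
                                      min_samples_leaf=3, n_jobs=1,
                                      random_state=seed)

    for _rep in range(config.n_repetitions):
        perm = rng.permutation(n)
        folds = np.array_split(perm, config.n_outer_folds)
        for k, test_idx in enumerate(folds):
            train_idx = np.concatenate([f for i, f in enumerate(folds) if i != k])
            active = np.arange(p)
            path, removal = [], []
            while True:
                inner_perm = rng.permutation(train_idx)
                inner_folds = np.array_split(inner_perm, config.n_inner_folds)
                aucs, imps = [], []
                for v, val_idx in enumerate(inner_folds):
                    fit_idx = np.concatenate(
                        [f for i, f in enumerate(inner_folds) if i != v])
                    if len(np.unique(y_all[val_idx])) < 2:
                        continue
                    rf = _rf(int(rng.integers(2**31 - 1)))
                    rf.fit(X_all[np.ix_(fit_idx, active)], y_all[fit_idx])
                    Xv = X_all[np.ix_(val_idx, active)].copy()
                    aucs.append(auc_rank(rf.predict_proba(Xv)[:, 1],
                                         y_all[val_idx]))
                    if importance == "permutation":
                        imps.append(_perm_importance(rf, Xv, y_all[val_idx], rng))
                    else:
                        imps.append(rf.feature_importances_)
                mean_auc = float(np.mean(aucs))
                se = float(np.std(aucs, ddof=1) / np.sqrt(len(aucs))) \
                    if len(aucs) > 1 else 0.0
                mean_imp = np.mean(imps, axis=0)
                path.append((active, mean_auc, se))
                if len(active) <= 1:
                    break
                n_keep = max(1, len(active) - max(1, int(np.floor(
                    config.elimination_ratio * len(active)))))
                order = np.argsort(mean_imp, kind="stable")
                removal.extend(active[order[:len(active) - n_keep]].tolist())
                active = np.sort(active[order[len(active) - n_keep:]])

            best_auc = max(e[1] for e in path)
            se_at_best = next(e[2] for e in path if e[1] == best_auc)
            chosen = None
            for entry in path:
                if entry[1] >= best_auc - se_at_best:
                    chosen, chosen_auc = entry[0], entry[1]
            ranks = np.empty(p)
            # chosen variables keep their within-set order by the last
            # importance ranking; approximate with elimination order
            in_chosen = np.zeros(p, dtype=bool)
            in_chosen[chosen] = True
            late_first = [f for f in reversed(removal) if not in_chosen[f]]
            ranks[chosen] = np.arange(1, len(chosen) + 1)
            ranks[np.array(late_first, dtype=int)] = np.arange(
                len(chosen) + 1, len(chosen) + 1 + len(late_first))
            rank_sum += ranks
            sel_count[chosen] += 1
            sizes.append(len(chosen))
            inner_aucs.append(chosen_auc)
            n_models += 1

    mean_rank = pd.Series(rank_sum / n_models, index=names)
    freq = pd.Series(sel_count / n_models, index=names)
    size = int(round(float(np.median(sizes))))
    selected = mean_rank.nsmallest(size).index.tolist()
    return RfSelection(selected=selected, ranking=mean_rank,
                       selection_frequency=freq,
                       inner_auc=float(np.mean(inner_aucs)),
                       chosen_sizes=sizes)


# ---------------------------------------------------------------------------
# repeated-split evaluation
# ---------------------------------------------------------------------------

@dataclass
class PredictionEval:
    auc: pd.DataFrame                 # per model: mean, ci_low, ci_high
    auc_per_split: pd.DataFrame       # n_splits x models
    pairwise_p: pd.DataFrame          # signed-rank p over paired split AUCs

    def summary(self) -> dict:
        return {m: {"mean_auc": float(self.auc.loc[m, "mean"]),
                    "ci_low": float(self.auc.loc[m, "ci_low"]),
                    "ci_high": float(self.auc.loc[m, "ci_high"])}
                for m in self.auc.index}


def evaluate_auc_splits(data: pd.DataFrame, outcome,
                        model_variables: dict[str, list[str]],
                        n_splits: int = 500, train_fraction: float = 0.6,
                        seed: int = 0) -> PredictionEval:
    """Mean AUC and percentile CI over repeated random train/test splits.

    Every model sees the identical split sequence, so the per-split AUCs are
    paired and the Wilcoxon signed-rank test applies.  Weights are refitted
    on each training split (variable sets held fixed).  A test split lacking
    one of the classes is redrawn (logged).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0,1)")
    y = np.asarray(outcome, dtype=int)
    n = len(y)
    n_train = int(round(train_fraction * n))
    rng = np.random.default_rng(seed)
    labels = list(model_variables)
    aucs = np.empty((n_splits, len(labels)))
    for s in range(n_splits):
        for _attempt in range(100):
            perm = rng.permutation(n)
            train_idx, test_idx = perm[:n_train], perm[n_train:]
            if (len(np.unique(y[train_idx])) == 2
                    and len(np.unique(y[test_idx])) == 2):
                break
            logger.info("split %d lacked both classes, redrawn", s)
        train = data.iloc[train_idx]
        test = data.iloc[test_idx]
        for j, lab in enumerate(labels):
            model = build_score(train, y[train_idx], model_variables[lab], lab)
            aucs[s, j] = auc_rank(model.linear_predictor(test), y[test_idx])
    per_split = pd.DataFrame(aucs, columns=labels)
    summary = pd.DataFrame({
        "mean": per_split.mean(),
        "ci_low": per_split.quantile(0.025),
        "ci_high": per_split.quantile(0.975),
    })
    pw = pd.DataFrame(np.ones((len(labels), len(labels))),
                      index=labels, columns=labels)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if j <= i:
                continue
            diff = aucs[:, i] - aucs[:, j]
            p = 1.0 if np.allclose(diff, 0.0) else float(
                wilcoxon(diff, zero_method="wilcox").pvalue)
            pw.loc[a, b] = pw.loc[b, a] = p
    return PredictionEval(auc=summary, auc_per_split=per_split, pairwise_p=pw)


# ---------------------------------------------------------------------------
# reclassification
# ---------------------------------------------------------------------------

@dataclass
class NriIdiResult:
    nri: float
    nri_ci: tuple[float, float]
    nri_p: float
    idi: float
    idi_ci: tuple[float, float]
    idi_p: float


def _calibrate(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    if np.std(scores) == 0:
        return np.full_like(scores, y.mean(), dtype=float)
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
    lr.fit(scores.reshape(-1, 1), y)
    return lr.predict_proba(scores.reshape(-1, 1))[:, 1]


def nri_idi(base_scores, new_scores, outcome,
            scores_are_risks: bool = False) -> NriIdiResult:
    """Continuous (category-free) NRI and IDI of a new score over a base.

    Scores are turned into predicted risks by one-dimensional logistic
    calibration unless ``scores_are_risks`` is set.  NRI counts any risk
    movement in the right direction (range [-2, 2]); IDI is the change in
    discrimination slope.  Standard errors use the usual asymptotic
    formulas; ties in risk count as neither up nor down.
    """
    y = np.asarray(outcome, dtype=int)
    base = np.asarray(base_scores, dtype=float)
    new = np.asarray(new_scores, dtype=float)
    if not scores_are_risks:
        base = _calibrate(base, y)
        new = _calibrate(new, y)
    case, ctrl = y == 1, y == 0
    n1, n0 = int(case.sum()), int(ctrl.sum())
    up, down = new > base, new < base

    p_up_c, p_dn_c = up[case].mean(), down[case].mean()
    p_up_n, p_dn_n = up[ctrl].mean(), down[ctrl].mean()
    nri = (p_up_c - p_dn_c) + (p_dn_n - p_up_n)
    var_c = (p_up_c + p_dn_c - (p_up_c - p_dn_c) ** 2) / n1
    var_n = (p_up_n + p_dn_n - (p_dn_n - p_up_n) ** 2) / n0
    se_nri = float(np.sqrt(var_c + var_n))
    z = nri / se_nri if se_nri > 0 else (0.0 if nri == 0 else np.inf)

    d = new - base
    idi = float(d[case].mean() - d[ctrl].mean())
    se_idi = float(np.sqrt(d[case].var(ddof=1) / n1 + d[ctrl].var(ddof=1) / n0))
    z_idi = idi / se_idi if se_idi > 0 else (0.0 if idi == 0 else np.inf)

    return NriIdiResult(
        nri=float(nri),
        nri_ci=(float(nri - _Z975 * se_nri), float(nri + _Z975 * se_nri)),
        nri_p=float(2 * norm.sf(abs(z))),
        idi=idi,
        idi_ci=(idi - _Z975 * se_idi, idi + _Z975 * se_idi),
        idi_p=float(2 * norm.sf(abs(z_idi))),
    )


@dataclass
class RescueReport:
    n_misclassified: int
    n_rescued: int
    fraction: float
    by_class: pd.DataFrame


def misclassified_rescue(reference_risks, candidate_risks, outcome,
                         threshold: float = 0.5) -> RescueReport:
    """Of the subjects misclassified by the reference model, the fraction the
    candidate model classifies correctly (risk >= threshold means predicted
    case), overall and by class."""
    y = np.asarray(outcome, dtype=int)
    ref = np.asarray(reference_risks, dtype=float) >= threshold
    cand = np.asarray(candidate_risks, dtype=float) >= threshold
    miss = ref != (y == 1)
    rows = []
    for cls, label in ((1, "case"), (0, "control")):
        m = miss & (y == cls)
        resc = m & (cand == (y == 1))
        rows.append({"class": label, "n_misclassified": int(m.sum()),
                     "n_rescued": int(resc.sum()),
                     "fraction": float(resc.sum() / m.sum()) if m.sum() else np.nan})
    n_miss = int(miss.sum())
    n_resc = int((miss & (cand == (y == 1))).sum())
    return RescueReport(
        n_misclassified=n_miss, n_rescued=n_resc,
        fraction=float(n_resc / n_miss) if n_miss else np.nan,
        by_class=pd.DataFrame(rows))
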