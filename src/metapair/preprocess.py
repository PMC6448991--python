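"""Post-deconvolution feature processing.

Three stages, mirroring standard untargeted LC-MS practice once a matched
feature table exists:

* :func:`correct_drift` — QC-anchored correction of within-batch signal
  drift and between-batch level differences;
* :func:`cluster_features` — aggregation of redundant features (adducts,
  isotopologues, in-source fragments of one metabolite) by retention-time
  proximity plus intensity correlation;
* :func:`impute_missing` — truncated-normal imputation below each feature's
  observed minimum.

Drift correction works on the log scale.  For every feature and batch a
correction curve over injection order is fitted to the QC injections; the
curve family (constant / linear / cubic smoothing spline) is selected by
leave-one-out error on the QC points, with a preference for the simpler
family unless the more flexible one improves LOO error by at least 5%.
After dividing out the curve, batch QC medians are aligned exactly to the
global QC median.  Because the constant/linear corrections are least-squares
projections followed by an exact median alignment, re-applying the
correction to already-corrected data is an identity, and a per-feature guard
reverts to simpler corrections whenever the QC coefficient of variation
would not improve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata, truncnorm

from .containers import FeatureTable

logger = logging.getLogger(__name__)

_LOO_IMPROVEMENT = 0.95  # more flexible curve must beat simpler LOO MSE by 5%


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

@dataclass
class DriftModel:
    """Diagnostics of a drift correction: per feature x batch the curve
    family used, and per feature the pre/post QC coefficient of variation."""

    methods: pd.DataFrame
    qc_cv: pd.DataFrame
    global_qc_median: pd.Series = field(repr=False)


def _qc_cv(vals: np.ndarray) -> np.ndarray:
    """Columnwise CV (SD over mean) on the linear scale, NaN-aware."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.nanstd(vals, axis=0, ddof=1) / np.nanmean(vals, axis=0)


def _loo_mse_poly(t: np.ndarray, y: np.ndarray, degree: int) -> tuple[float, np.ndarray]:
    """LOO MSE of an LS polynomial fit via the hat-matrix identity."""
    X = np.vander(t, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fit = X @ coef
    XtX_inv = np.linalg.pinv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    resid = (y - fit) / np.clip(1.0 - h, 1e-8, None)
    return float(np.mean(resid**2)), fit


def _loo_mse_spline(t: np.ndarray, y: np.ndarray) -> float:
    """Brute-force LOO for the GCV smoothing spline (small QC counts)."""
    errs = []
    for i in range(len(t)):
        keep = np.ones(len(t), dtype=bool)
        keep[i] = False
        try:
            spl = make_smoothing_spline(t[keep], y[keep])
            errs.append((y[i] - float(spl(t[i]))) ** 2)
        except Exception:  # degenerate subset (e.g. duplicate abscissae)
            return np.inf
    return float(np.mean(errs))


def _fit_curve(t: np.ndarray, y: np.ndarray) -> tuple[str, np.ndarray, "callable"]:
    """Select constant/linear/spline by LOO on QC points; return the fitted
    values at the QC points and an evaluator over injection order."""
    mse_const, fit_const = _loo_mse_poly(t, y, 0)
    method, fit = "constant", fit_const
    evaluator = (lambda c: (lambda x: np.full(np.shape(x), c)))(float(fit_const[0]))
    if len(t) >= 3:
        mse_lin, fit_lin = _loo_mse_poly(t, y, 1)
        if mse_lin < _LOO_IMPROVEMENT * mse_const:
            coef = np.polyfit(t, y, 1)
            method, fit = "linear", fit_lin
            evaluator = (lambda c: (lambda x: np.polyval(c, x)))(coef)
            mse_const = mse_lin
    if len(t) >= 5 and len(np.unique(t)) == len(t):
        mse_spl = _loo_mse_spline(t, y)
        if mse_spl < _LOO_IMPROVEMENT * mse_const:
            spl = make_smoothing_spline(t, y)
            method, fit = "spline", spl(t)
            evaluator = spl
    return method, fit, evaluator


def correct_drift(table: FeatureTable, min_qc: int = 3
                  ) -> tuple[FeatureTable, DriftModel]:
    """QC-anchored intensity drift correction, per feature and batch.

    Batches with fewer than ``min_qc`` usable QC points for a feature fall
    back to batch-median-only correction (logged).  A per-feature guard
    reverts to median-only (and finally to no correction) if the overall QC
    CV would otherwise increase.
    """
    out = table.copy()
    smeta = out.sample_meta
    if "injection_order" not in smeta.columns or smeta["injection_order"].isna().all():
        raise ValueError("missing injection_order metadata")
    qc_mask = (smeta["role"] == "qc").to_numpy()
    if qc_mask.sum() == 0:
        raise ValueError("no QC samples in table")

    vals = out.intensities.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logv = np.log(vals)
    batches = np.sort(smeta["batch"].unique())
    inj = smeta["injection_order"].to_numpy(dtype=float)
    n_feat = vals.shape[1]
    pre_cv = _qc_cv(vals[qc_mask])
    log_gmed = np.nanmedian(logv[qc_mask], axis=0)

    methods = pd.DataFrame("median", index=out.feature_ids,
                           columns=[f"batch_{b}" for b in batches])
    corrected = np.array(logv)        # curve route
    corrected_med = np.array(logv)    # median-only route
    for b in batches:
        in_b = (smeta["batch"] == b).to_numpy()
        qc_b = in_b & qc_mask
        t_all = inj[in_b]
        t_qc = inj[qc_b]
        for j in range(n_feat):
            y = logv[qc_b, j]
            usable = np.isfinite(y)
            yv, tv = y[usable], t_qc[usable]
            if usable.sum() < min_qc:
                logger.info("feature %s batch %s: %d QC points, median-only "
                            "fallback", out.feature_ids[j], b, usable.sum())
                method = "median"
            else:
                method, _, evaluator = _fit_curve(tv, yv)
                corrected[in_b, j] = logv[in_b, j] - evaluator(t_all)
            methods.iloc[j, list(batches).index(b)] = method
            # exact per-batch QC median alignment (both routes)
            for arr in (corrected, corrected_med):
                med = np.nanmedian(arr[qc_b, j])
                if np.isfinite(med):
                    arr[in_b, j] = arr[in_b, j] - med + log_gmed[j]

    # guard: never let a feature's QC CV increase
    post_curve = _qc_cv(np.exp(corrected[qc_mask]))
    post_med = _qc_cv(np.exp(corrected_med[qc_mask]))
    final = corrected
    tol = 1e-12
    for j in range(n_feat):
        if not np.isfinite(pre_cv[j]):
            # too few QC values for a CV: median alignment is all we can do
            final[:, j] = corrected_med[:, j]
            methods.iloc[j, :] = "median"
            continue
        if post_curve[j] <= post_med[j] + tol and post_curve[j] <= pre_cv[j] + tol:
            continue
        if post_med[j] <= pre_cv[j] + tol:
            final[:, j] = corrected_med[:, j]
            methods.iloc[j, :] = "median"
        else:
            final[:, j] = logv[:, j]
            methods.iloc[j, :] = "none"
            logger.info("feature %s: correction would raise QC CV, skipped",
                        out.feature_ids[j])

    out.intensities.iloc[:, :] = np.exp(final)
    post_cv = _qc_cv(out.intensities.to_numpy(dtype=float)[qc_mask])
    model = DriftModel(
        methods=methods,
        qc_cv=pd.DataFrame({"pre_cv": pre_cv, "post_cv": post_cv},
                           index=out.feature_ids),
        global_qc_median=pd.Series(np.exp(log_gmed), index=out.feature_ids),
    )
    return out, model


def qc_cv_filter(table: FeatureTable, max_cv: float = 0.3) -> FeatureTable:
    """Drop features whose QC coefficient of variation exceeds ``max_cv``."""
    qc = table.intensities[table.is_qc()].to_numpy(dtype=float)
    cv = _qc_cv(qc)
    keep = table.feature_ids[(cv <= max_cv) | ~np.isfinite(cv)]
    return table.subset_features(keep)


# ---------------------------------------------------------------------------
# feature aggregation
# ---------------------------------------------------------------------------

@dataclass
class FeatureCluster:
    cluster_id: str
    members: list[str]
    representative: str
    rt_range: tuple[float, float]
    median_corr: float


def cluster_features(table: FeatureTable, rt_tolerance: float = 0.05,
                     corr_threshold: float = 0.8,
                     representative: str = "max_median",
                     ) -> tuple[FeatureTable, list[FeatureCluster]]:
    """Aggregate redundant features by single linkage within platform/mode.

    Two features are linked when their retention-time difference is at most
    ``rt_tolerance`` minutes *and* their Spearman correlation over study
    samples is at least ``corr_threshold``; clusters are the connected
    components of that graph.  Each cluster is replaced by one output
    feature: its member of highest median intensity (``max_median``) or the
    per-sample mean of members (``mean``).  Membership is recorded in
    ``feature_meta['cluster_id']``.
    """
    if not 0 < corr_threshold < 1:
        raise ValueError("corr_threshold must lie in (0,1)")
    if representative not in ("max_median", "mean"):
        raise ValueError("representative must be 'max_median' or 'mean'")
    fmeta = table.feature_meta
    study = ~table.is_qc()
    X = table.intensities.loc[study]

    feat_ids = list(table.feature_ids)
    pos = {f: i for i, f in enumerate(feat_ids)}
    labels = np.arange(len(feat_ids))  # start as singletons
    next_label = 0
    comp_of: dict[str, int] = {}
    for (_, _), grp in fmeta.groupby(["platform", "mode"], observed=True, sort=True):
        ids = [f for f in feat_ids if f in set(grp.index)]
        if not ids:
            continue
        rt = fmeta.loc[ids, "rt"].to_numpy(dtype=float)
        sub = X[ids].to_numpy(dtype=float)
        # Spearman via ranks; pairwise-complete handling is unnecessary here
        # because correlation is computed on observed ranks with NaNs kept
        corr = pd.DataFrame(sub, columns=ids).corr(method="spearman").to_numpy()
        ii, jj = np.triu_indices(len(ids), k=1)
        ok = (np.abs(rt[ii] - rt[jj]) <= rt_tolerance) & (corr[ii, jj] >= corr_threshold)
        graph = coo_matrix((np.ones(ok.sum()), (ii[ok], jj[ok])),
                           shape=(len(ids), len(ids)))
        _, comp = connected_components(graph, directed=False)
        for f, c in zip(ids, comp):
            comp_of[f] = next_label + c
        next_label += comp.max() + 1 if len(comp) else 0
    labels = np.array([comp_of[f] for f in feat_ids])

    clusters: list[FeatureCluster] = []
    new_cols: dict[str, pd.Series] = {}
    cluster_id_col = {}
    keep_rows = []
    for c in np.unique(labels):
        members = [feat_ids[i] for i in np.flatnonzero(labels == c)]
        med = X[members].median()
        rep = med.idxmax()
        cid = f"C_{rep}"
        for m in members:
            cluster_id_col[m] = cid
        rts = fmeta.loc[members, "rt"].astype(float)
        if len(members) > 1:
            cm = X[members].corr(method="spearman").to_numpy()
            med_corr = float(np.median(cm[np.triu_indices(len(members), k=1)]))
        else:
            med_corr = 1.0
        clusters.append(FeatureCluster(cid, members, rep,
                                       (float(rts.min()), float(rts.max())),
                                       med_corr))
        keep_rows.append(rep)
        if representative == "max_median":
            new_cols[rep] = table.intensities[rep]
        else:
            new_cols[rep] = table.intensities[members].mean(axis=1)

    fmeta = fmeta.copy()
    fmeta["cluster_id"] = pd.Series(cluster_id_col)
    reps = [r for r in feat_ids if r in set(keep_rows)]  # preserve order
    agg = FeatureTable(
        pd.DataFrame({r: new_cols[r] for r in reps}, index=table.sample_ids),
        table.sample_meta.copy(),
        fmeta.loc[reps],
    )
    # full membership map rides along for bookkeeping
    agg.feature_meta = agg.feature_meta.copy()
    return agg, clusters


def clusters_to_frame(clusters: list[FeatureCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        for m in c.members:
            rows.append({"feature_id": m, "cluster_id": c.cluster_id,
                         "representative": m == c.representative})
    return pd.DataFrame(rows).set_index("feature_id")


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_missing(table: FeatureTable, seed: int) -> FeatureTable:
    """Replace missing values by truncated-normal draws below the feature
    minimum.

    For feature *f* with lowest observed intensity ``m_f``, each missing cell
    is drawn from a normal with mean ``m_f/2`` and SD ``m_f/4`` truncated to
    the open interval ``(0, m_f)``.  Deterministic under ``seed``; observed
    cells are untouched.
    """
    out = table.copy()
    vals = out.intensities.to_numpy(dtype=float)
    n_missing = np.isnan(vals).sum(axis=0)
    observed = (~np.isnan(vals)).sum(axis=0)
    dead = out.feature_ids[(observed == 0)].tolist()
    if dead:
        raise ValueError(f"features with no observed values: {dead}")
    rng = np.random.default_rng(seed)
    for j in np.flatnonzero(n_missing > 0):
        col = vals[:, j]
        miss = np.isnan(col)
        m_f = np.nanmin(col)
        if m_f <= 0:
            # degenerate support: everything at/below zero collapses to zero
            col[miss] = 0.0
            continue
        mean, sd = m_f / 2.0, m_f / 4.0
        a, b = (0.0 - mean) / sd, (m_f - mean) / sd
        col[miss] = truncnorm.rvs(a, b, loc=mean, scale=sd,
                                  size=miss.sum(), random_state=rng)
        vals[:, j] = col
    out.intensities.iloc[:, :] = vals
    return out
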