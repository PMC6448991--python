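"""Biomarker discovery: multilevel PLS in repeated double cross-validation.

The matched design is reduced to its within-pair structure: for every pair
the standardized log-intensity difference ``d = x_case - x_control`` and its
negation enter as two rows labelled +1/-1 (the *multilevel* construction —
between-pair variation, and with it every matching factor, cancels exactly).
A sparse-PLS pre-filter removes the bulk of uninformative features per
chromatographic platform; the surviving features enter a repeated double
cross-validation (rdCV) engine that tunes component count and eliminates
variables in an inner loop, estimates performance on outer folds it never
touched, and aggregates per-feature ranks across all repetitions and outer
folds into an importance ranking score (lower = more important).  Model
validity is assessed by permutation of pair orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._pls import fit_pls1
from .containers import FeatureTable, PairedDesign

_MIN_FEATURES = 2  # elimination floor


@dataclass
class PairedMatrix:
    """Within-pair difference vectors and their negations, labelled +/-1.

    Rows ``i`` and ``i + n_pairs`` are an exact +/- duo for pair ``i``; the
    class is balanced by construction.
    """

    X: np.ndarray
    y: np.ndarray
    pair_ids: np.ndarray          # length n_pairs; row r belongs to pair r % n_pairs
    feature_ids: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def rows_for_pairs(self, idx: np.ndarray) -> np.ndarray:
        return np.concatenate([idx, idx + self.n_pairs])

    def subset_features(self, cols: np.ndarray) -> "PairedMatrix":
        return PairedMatrix(self.X[:, cols], self.y, self.pair_ids,
                            self.feature_ids[cols])

    def flip_pairs(self, signs: np.ndarray) -> "PairedMatrix":
        """Flip the orientation of pairs where ``signs`` is -1 (null model)."""
        m = self.n_pairs
        X = self.X.copy()
        X[:m] *= signs[:, None]
        X[m:] *= signs[:, None]
        return PairedMatrix(X, self.y, self.pair_ids, self.feature_ids)


def multilevel_transform(table: FeatureTable, design: PairedDesign,
                         standardize: bool = True) -> PairedMatrix:
    """Build the paired +/- difference matrix from (imputed) intensities.

    Intensities are logged and, by default, standardized per feature over the
    samples in the design before differencing, so effect sizes are in SD
    units.  Raises if any pair is missing a member or has unmeasured cells.
    """
    used = np.concatenate([design.case_ids, design.control_ids])
    missing_samples = [s for s in used if s not in table.sample_ids]
    if missing_samples:
        raise ValueError(f"samples absent from table: {missing_samples}")
    sub = table.intensities.loc[used]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise ValueError(f"unimputed missing values in samples: {bad}")
    vals = np.log(sub.to_numpy(dtype=float))
    if standardize:
        sd = vals.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        vals = (vals - vals.mean(axis=0)) / sd
    m = design.n_pairs
    d = vals[:m] - vals[m:]
    X = np.vstack([d, -d])
    y = np.concatenate([np.ones(m), -np.ones(m)])
    return PairedMatrix(X, y, design.pairs.index.to_numpy(),
                        table.feature_ids.to_numpy())


# ---------------------------------------------------------------------------
# sparse-PLS pre-filter
# ---------------------------------------------------------------------------

def spls_prefilter(pm: PairedMatrix, keep_components: int = 2,
                   sparsity: float = 0.1,
                   platform: np.ndarray | None = None) -> list:
    """Retain features with nonzero soft-thresholded sPLS loading weights.

    Per platform (the pre-filter runs on each chromatography separately when
    ``platform`` labels are given) and per component, the loading weight
    vector ``w = X'y`` is soft-thresholded so that a fraction ``sparsity`` of
    entries stays nonzero, the component scores deflate ``X``, and the union
    of nonzero supports over ``keep_components`` components is retained.
    ``sparsity = 1`` keeps every non-degenerate feature.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    if pm.X.shape[0] == 0:
        raise ValueError("empty paired matrix")
    groups = (pd.Series(platform).groupby(platform).groups.values()
              if platform is not None else [np.arange(pm.X.shape[1])])
    retained: list = []
    for cols in groups:
        cols = np.asarray(list(cols))
        Xg = pm.X[:, cols].astype(float).copy()
        variances = Xg.var(axis=0)
        live = variances > 0
        n_dead = int((~live).sum())
        if n_dead:
            import logging
            logging.getLogger(__name__).info(
                "spls_prefilter: dropped %d zero-variance features", n_dead)
        keep = np.zeros(Xg.shape[1], dtype=bool)
        y = pm.y.astype(float).copy()
        n_keep = max(1, int(np.ceil(sparsity * live.sum())))
        for _ in range(keep_components):
            w = Xg.T @ y
            w[~live] = 0.0
            aw = np.abs(w)
            if aw.max() <= 0:
                break
            if n_keep < live.sum():
                lam = np.sort(aw[live])[-(n_keep + 1)]
            else:
                lam = 0.0
            ws = np.sign(w) * np.clip(aw - lam, 0.0, None)
            support = ws != 0
            keep |= support
            nw = np.linalg.norm(ws)
            ws = ws / nw
            t = Xg @ ws
            tt = t @ t
            if tt <= 0:
                break
            Xg -= np.outer(t, (Xg.T @ t) / tt)
            y = y - t * ((y @ t) / tt)
        retained.extend(pm.feature_ids[cols[keep]].tolist())
    order = {f: i for i, f in enumerate(pm.feature_ids)}
    return sorted(retained, key=order.get)


# ---------------------------------------------------------------------------
# repeated double cross-validation
# ---------------------------------------------------------------------------

@dataclass
class RdcvConfig:
    """Knobs of the rdCV engine (counts per repetition/fold, elimination
    schedule, permutation count and the top-rank threshold)."""

    n_repetitions: int = 20
    n_outer_folds: int = 6
    n_inner_folds: int = 5
    max_components: int = 5
    elimination_ratio: float = 0.2
    n_permutations: int = 500
    rank_threshold: float = 100.0
    rank_aggregation: str = "mean"   # or "sum"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if not 0 < self.elimination_ratio < 1:
            raise ValueError("elimination_ratio must lie in (0,1)")
        if self.rank_threshold <= 0:
            raise ValueError("rank_threshold must be positive")
        if self.rank_aggregation not in ("mean", "sum"):
            raise ValueError("rank_aggregation must be 'mean' or 'sum'")


@dataclass
class RankedFeatures:
    """Per-feature importance ranking scores and rdCV model summaries."""

    scores: pd.Series                 # importance ranking score (lower = better)
    selection_frequency: pd.Series    # fraction of outer models containing it
    misclassification: np.ndarray     # outer misclassification per repetition
    chosen_sizes: list[int] = field(default_factory=list)
    chosen_ncomps: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ranking_score": self.scores,
                             "selection_frequency": self.selection_frequency})


def _misclass(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(np.where(pred > 0, 1.0, -1.0) != y))


def _inner_cv(pm: PairedMatrix, train_pairs: np.ndarray, active: np.ndarray,
              config: RdcvConfig, rng: np.random.Generator
              ) -> tuple[int, float, float]:
    """Inner CV over component counts; returns (best ncomp, mean misclass at
    best, SE over inner folds at best)."""
    perm = rng.permutation(train_pairs)
    folds = np.array_split(perm, config.n_inner_folds)
    max_a = max(1, min(config.max_components, len(active)))
    errs = np.full((len(folds), max_a), np.nan)
    for k, val_pairs in enumerate(folds):
        fit_pairs = np.setdiff1d(perm, val_pairs)
        rows_fit = pm.rows_for_pairs(fit_pairs)
        rows_val = pm.rows_for_pairs(val_pairs)
        model = fit_pls1(pm.X[np.ix_(rows_fit, active)], pm.y[rows_fit], max_a)
        Xv = pm.X[np.ix_(rows_val, active)]
        for a, B in enumerate(model.coefs_per_ncomp()):
            errs[k, a] = _misclass((Xv - model.x_mean) @ B, pm.y[rows_val])
        if model.n_components < max_a:       # early stop: pad with last
            errs[k, model.n_components:] = errs[k, model.n_components - 1]
    mean_err = errs.mean(axis=0)
    best_a = int(np.argmin(mean_err))        # ties -> fewer components
    se = float(errs[:, best_a].std(ddof=1) / np.sqrt(len(folds)))
    return best_a + 1, float(mean_err[best_a]), se


def mlpls_rdcv(pm: PairedMatrix, config: RdcvConfig) -> RankedFeatures:
    """Multilevel-PLS classification in repeated double cross-validation with
    stepwise variable elimination.

    Pairs (never single +/- rows) are split into outer folds.  Within each
    outer training set, an inner CV tunes the component count while variables
    are eliminated stepwise by lowest ``|loading weight x inner-relation
    coefficient|``; the minimal variable set within one SE of the best inner
    misclassification is chosen, refitted, and scored on the untouched outer
    fold.  Feature ranks from every repetition x outer fold are aggregated
    into the importance ranking score.
    """
    m, p = pm.n_pairs, pm.X.shape[1]
    if m < config.n_outer_folds:
        raise ValueError(
            f"{m} pairs cannot fill {config.n_outer_folds} outer folds")
    rng = np.random.default_rng(config.seed)
    rank_sum = np.zeros(p)
    sel_count = np.zeros(p)
    n_models = 0
    outer_miss = []
    chosen_sizes: list[int] = []
    chosen_ncomps: list[int] = []

    for _rep in range(config.n_repetitions):
        perm = rng.permutation(m)
        folds = np.array_split(perm, config.n_outer_folds)
        rep_err, rep_n = 0.0, 0
        for k, test_pairs in enumerate(folds):
            train_pairs = np.concatenate([f for i, f in enumerate(folds) if i != k])
            rows_tr = pm.rows_for_pairs(train_pairs)

            active = np.arange(p)
            path: list[tuple[np.ndarray, int, float, float]] = []
            removal_order: list[int] = []   # first removed ... last removed
            while True:
                ncomp, miss, se = _inner_cv(pm, train_pairs, active, config, rng)
                path.append((active, ncomp, miss, se))
                if len(active) <= _MIN_FEATURES:
                    break
                model = fit_pls1(pm.X[np.ix_(rows_tr, active)],
                                 pm.y[rows_tr], ncomp)
                imp = model.importance()
                n_keep = max(_MIN_FEATURES,
                             len(active) - max(1, int(np.floor(
                                 config.elimination_ratio * len(active)))))
                order = np.argsort(imp, kind="stable")
                n_drop = len(active) - n_keep
                removal_order.extend(active[order[:n_drop]].tolist())
                active = np.sort(active[order[n_drop:]])

            best_miss = min(entry[2] for entry in path)
            se_at_best = next(e[3] for e in path if e[2] == best_miss)
            threshold = best_miss + se_at_best
            chosen, chosen_ncomp = None, 1
            for entry in path:                       # path is decreasing in size
                if entry[2] <= threshold:
                    chosen, chosen_ncomp = entry[0], entry[1]
            assert chosen is not None

            final = fit_pls1(pm.X[np.ix_(rows_tr, chosen)], pm.y[rows_tr],
                             chosen_ncomp)
            rows_te = pm.rows_for_pairs(test_pairs)
            pred = final.predict(pm.X[np.ix_(rows_te, chosen)])
            rep_err += np.sum(np.where(pred > 0, 1.0, -1.0) != pm.y[rows_te])
            rep_n += len(rows_te)

            # per-model full ranking: chosen set 1..k by final importance,
            # then eliminated features in reverse removal order
            ranks = np.empty(p)
            imp_final = final.importance()
            order_chosen = np.argsort(-imp_final, kind="stable")
            ranks[chosen[order_chosen]] = np.arange(1, len(chosen) + 1)
            eliminated = [f for f in reversed(removal_order) if f not in set(chosen)]
            ranks[np.array(eliminated, dtype=int)] = np.arange(
                len(chosen) + 1, len(chosen) + 1 + len(eliminated))
            rank_sum += ranks
            sel_count[chosen] += 1
            n_models += 1
            chosen_sizes.append(len(chosen))
            chosen_ncomps.append(chosen_ncomp)
        outer_miss.append(rep_err / rep_n)

    scores = rank_sum if config.rank_aggregation == "sum" else rank_sum / n_models
    return RankedFeatures(
        scores=pd.Series(scores, index=pm.feature_ids, name="ranking_score"),
        selection_frequency=pd.Series(sel_count / n_models, index=pm.feature_ids,
                                      name="selection_frequency"),
        misclassification=np.asarray(outer_miss),
        chosen_sizes=chosen_sizes,
        chosen_ncomps=chosen_ncomps,
    )


@dataclass
class PermutationResult:
    p_value: float
    observed: float
    null_distribution: np.ndarray


def permutation_validation(pm: PairedMatrix, config: RdcvConfig,
                           observed: float | None = None) -> PermutationResult:
    """Permutation test of the rdCV model: pair orientations are flipped at
    random (the null respecting the +/- structure), the engine is re-run, and
    the p-value is ``(1 + #{null misclassification <= observed}) /
    (1 + n_permutations)``.
    """
    if observed is None:
        observed = float(mlpls_rdcv(pm, config).misclassification.mean())
    rng = np.random.default_rng(config.seed + 2_000_003)
    null = np.empty(config.n_permutations)
    for i in range(config.n_permutations):
        signs = rng.choice([-1.0, 1.0], size=pm.n_pairs)
        sub_config = RdcvConfig(**{**config.__dict__,
                                   "seed": int(rng.integers(2**31 - 1))})
        null[i] = float(mlpls_rdcv(pm.flip_pairs(signs),
                                   sub_config).misclassification.mean())
    p = (1.0 + np.sum(null <= observed)) / (1.0 + config.n_permutations)
    return PermutationResult(p_value=float(p), observed=observed,
                             null_distribution=null)


def select_top(ranked: RankedFeatures, threshold: float | None = None) -> list:
    """Features with ranking score strictly below ``threshold``, sorted
    ascending; ties broken by higher selection frequency, then feature id."""
    if len(ranked.scores) == 0:
        raise ValueError("empty ranking")
    thr = threshold if threshold is not None else np.inf
    df = ranked.to_frame().rename_axis("feature_id")
    hits = df[df["ranking_score"] < thr].reset_index()
    hits = hits.sort_values(
        by=["ranking_score", "selection_frequency", "feature_id"],
        ascending=[True, False, True],
        kind="stable",
    )
    return hits["feature_id"].tolist()
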