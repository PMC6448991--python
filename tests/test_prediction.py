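"""AUC formulation, score models, RF selection, repeated splits, NRI/IDI."""

import numpy as np
import pandas as pd
import pytest

from metapair.discovery import RdcvConfig
from metapair.prediction import (auc_rank, build_score, encode_predictors,
                                 evaluate_auc_splits, misclassified_rescue,
                                 nri_idi, rf_rdcv_select,
                                 TS_NO_2HPG_VARIABLES, TS_VARIABLES)


def _auc_bruteforce(scores, y):
    """All-pairs concordance count; ties count half."""
    s = np.asarray(scores, dtype=float)
    pos = s[np.asarray(y) == 1]
    neg = s[np.asarray(y) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


@pytest.mark.parametrize("n, tie_fraction", [(10, 0.0), (57, 0.5), (200, 0.2)])
def test_rank_sum_auc_equals_bruteforce(n, tie_fraction, rng):
    y = rng.integers(0, 2, n)
    y[:2] = [0, 1]  # both classes present
    s = rng.normal(0, 1, n)
    tied = rng.random(n) < tie_fraction
    s[tied] = np.round(s[tied])  # induce ties
    assert auc_rank(s, y) == pytest.approx(_auc_bruteforce(s, y), abs=1e-12)


def test_auc_needs_both_classes():
    with pytest.raises(ValueError, match="both classes"):
        auc_rank([1.0, 2.0], [1, 1])


def test_single_variable_score_preserves_auc(rng):
    n = 120
    y = rng.integers(0, 2, n)
    x = rng.normal(0, 1, n) + 0.8 * y
    data = pd.DataFrame({"v": x})
    model = build_score(data, y, ["v"])
    # monotone transform invariance: score AUC equals raw-variable AUC
    assert auc_rank(model.linear_predictor(data), y) == pytest.approx(
        auc_rank(np.sign(model.coef[0]) * x, y), abs=1e-12)


def test_training_auc_never_below_half_and_monotone_in_nesting(rng):
    n = 150
    y = rng.integers(0, 2, n)
    data = pd.DataFrame(rng.normal(0, 1, (n, 6)),
                        columns=[f"v{i}" for i in range(6)])
    data["v0"] += 0.5 * y
    small = build_score(data, y, ["v0", "v1"])
    large = build_score(data, y, ["v0", "v1", "v2", "v3"])
    auc_small = auc_rank(small.linear_predictor(data), y)
    auc_large = auc_rank(large.linear_predictor(data), y)
    assert auc_small >= 0.5
    assert auc_large >= auc_small - 1e-9


def test_gaussian_two_class_closed_form(rng):
    from scipy.stats import norm as normal

    n, delta = 5000, np.array([0.5, 0.3, 0.4])
    y = rng.integers(0, 2, n)
    X = rng.normal(0, 1, (n, 3)) + np.outer(y, delta)
    data = pd.DataFrame(X, columns=["a", "b", "c"])
    model = build_score(data, y, ["a", "b", "c"])
    expected = normal.cdf(np.linalg.norm(delta) / np.sqrt(2))
    assert auc_rank(model.linear_predictor(data), y) == pytest.approx(
        expected, abs=0.02)


# ---------------------------------------------------------------------------
# repeated splits
# ---------------------------------------------------------------------------

def test_outcome_indicator_scores_auc_one(rng):
    n = 80
    y = rng.integers(0, 2, n)
    y[:2] = [0, 1]
    data = pd.DataFrame({"oracle": y.astype(float),
                         "noise": rng.normal(0, 1, n)})
    ev = evaluate_auc_splits(data, y, {"oracle": ["oracle"]}, n_splits=25,
                             seed=3)
    assert (ev.auc_per_split["oracle"] == 1.0).all()


def test_pure_noise_score_concentrates_at_half(rng):
    n = 400
    y = rng.integers(0, 2, n)
    data = pd.DataFrame({"noise": rng.normal(0, 1, n)})
    ev = evaluate_auc_splits(data, y, {"noise": ["noise"]}, n_splits=200,
                             seed=4)
    assert 0.47 <= ev.auc.loc["noise", "mean"] <= 0.53


def test_identical_models_signed_rank_p_is_one(rng):
    n = 100
    y = rng.integers(0, 2, n)
    data = pd.DataFrame({"v": rng.normal(0, 1, n) + 0.5 * y})
    ev = evaluate_auc_splits(data, y, {"a": ["v"], "b": ["v"]}, n_splits=30,
                             seed=5)
    assert ev.pairwise_p.loc["a", "b"] == 1.0


def test_split_evaluation_deterministic_under_seed(rng):
    n = 120
    y = rng.integers(0, 2, n)
    data = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=["a", "b", "c"])
    data["a"] += 0.6 * y
    kw = dict(n_splits=40, seed=11)
    e1 = evaluate_auc_splits(data, y, {"m": ["a", "b"]}, **kw)
    e2 = evaluate_auc_splits(data, y, {"m": ["a", "b"]}, **kw)
    pd.testing.assert_frame_equal(e1.auc_per_split, e2.auc_per_split)


# ---------------------------------------------------------------------------
# NRI / IDI
# ---------------------------------------------------------------------------

def test_identical_models_give_zero_nri_idi(rng):
    y = rng.integers(0, 2, 50)
    risks = rng.random(50)
    res = nri_idi(risks, risks, y, scores_are_risks=True)
    assert res.nri == 0.0 and res.idi == 0.0


def test_perfect_improvement_attains_maxima(rng):
    y = rng.integers(0, 2, 60)
    y[:2] = [0, 1]
    res = nri_idi(np.full(60, 0.5), y.astype(float), y, scores_are_risks=True)
    assert res.nri == 2.0 and res.idi == 1.0


def test_four_subject_enumeration():
    # 2 cases moved up, 2 controls moved down
    y = np.array([1, 1, 0, 0])
    base = np.array([0.5, 0.5, 0.5, 0.5])
    new = np.array([0.7, 0.6, 0.3, 0.2])
    res = nri_idi(base, new, y, scores_are_risks=True)
    assert res.nri == pytest.approx(2.0, abs=1e-12)
    idi_hand = ((0.7 + 0.6) / 2 - (0.3 + 0.2) / 2) - (0.5 - 0.5)
    assert res.idi == pytest.approx(idi_hand, abs=1e-12)


def test_nri_idi_antisymmetry(rng):
    y = rng.integers(0, 2, 80)
    base, new = rng.random(80), rng.random(80)
    fwd = nri_idi(base, new, y, scores_are_risks=True)
    rev = nri_idi(new, base, y, scores_are_risks=True)
    assert fwd.nri == pytest.approx(-rev.nri, abs=1e-12)
    assert fwd.idi == pytest.approx(-rev.idi, abs=1e-12)


def test_constant_scores_move_nobody(rng):
    y = rng.integers(0, 2, 40)
    res = nri_idi(np.full(40, 0.3), np.full(40, 0.3), y, scores_are_risks=True)
    assert res.nri == 0.0 and res.idi == 0.0


# ---------------------------------------------------------------------------
# misclassification rescue
# ---------------------------------------------------------------------------

def test_rescue_identical_candidate_rescues_nothing(rng):
    y = rng.integers(0, 2, 50)
    risks = rng.random(50)
    rep = misclassified_rescue(risks, risks, y)
    assert rep.n_rescued == 0 and rep.fraction == 0.0


def test_rescue_oracle_candidate_rescues_all(rng):
    y = rng.integers(0, 2, 50)
    y[:2] = [0, 1]
    rep = misclassified_rescue(np.full(50, 0.6), y.astype(float), y)
    assert rep.fraction == 1.0
    assert rep.n_misclassified == int((y == 0).sum())


def test_rescue_complementary_scores_partial(rng):
    n = 300
    y = rng.integers(0, 2, n)
    a = 0.3 * y + rng.normal(0.35, 0.2, n)
    b = 0.3 * y + rng.normal(0.35, 0.2, n)
    rep = misclassified_rescue(np.clip(a, 0, 1), np.clip(b, 0, 1), y)
    assert 0.0 < rep.fraction < 1.0
    again = misclassified_rescue(np.clip(a, 0, 1), np.clip(b, 0, 1), y)
    assert rep.fraction == again.fraction


# ---------------------------------------------------------------------------
# RF rdCV selection
# ---------------------------------------------------------------------------

def test_single_predictor_is_selected(rng):
    data = pd.DataFrame({"only": rng.normal(0, 1, 50)})
    sel = rf_rdcv_select(data, rng.integers(0, 2, 50), RdcvConfig(seed=1))
    assert sel.selected == ["only"]


def test_constant_predictors_dropped(caplog, rng):
    import logging

    n = 90
    y = rng.integers(0, 2, n)
    data = pd.DataFrame({"flat": np.ones(n),
                         "good": rng.normal(0, 1, n) + 0.9 * y,
                         "noise": rng.normal(0, 1, n)})
    cfg = RdcvConfig(n_repetitions=1, n_outer_folds=3, n_inner_folds=3,
                     elimination_ratio=0.4, seed=2)
    with caplog.at_level(logging.INFO, logger="metapair.prediction"):
        sel = rf_rdcv_select(data, y, cfg, n_estimators=40)
    assert "flat" in caplog.text
    assert "flat" not in sel.ranking.index
    assert "good" in sel.selected


def test_informative_variables_recovered():
    hits = []
    for seed in range(3):
        gen = np.random.default_rng(seed)
        n = 300
        y = gen.integers(0, 2, n)
        X = pd.DataFrame(gen.normal(0, 1, (n, 20)),
                         columns=[f"v{i}" for i in range(20)])
        for j in range(5):
            X[f"v{j}"] += 0.6 * y
        cfg = RdcvConfig(n_repetitions=1, n_outer_folds=3, n_inner_folds=3,
                         elimination_ratio=0.3, seed=seed)
        sel = rf_rdcv_select(X, y, cfg, n_estimators=60,
                             importance="impurity")
        hits.append(sum(f"v{j}" in sel.selected for j in range(5)))
    assert sum(h >= 4 for h in hits) >= 2


def test_permutation_importance_route(rng):
    n = 150
    y = rng.integers(0, 2, n)
    X = pd.DataFrame(rng.normal(0, 1, (n, 6)),
                     columns=[f"v{i}" for i in range(6)])
    X["v0"] += 1.0 * y
    cfg = RdcvConfig(n_repetitions=1, n_outer_folds=3, n_inner_folds=3,
                     elimination_ratio=0.4, seed=3)
    sel = rf_rdcv_select(X, y, cfg, n_estimators=40, importance="permutation")
    assert "v0" in sel.selected


def test_ts_variable_pools():
    assert len(TS_VARIABLES) == 14
    assert "pg2h" not in TS_NO_2HPG_VARIABLES
    assert len(TS_NO_2HPG_VARIABLES) == 13


def test_encode_predictors_orders_categories(small_cohort):
    _, ds = small_cohort
    meta = ds.design.meta
    enc = encode_predictors(meta, ["education", "bmi"])
    assert enc["education"].between(0, 3).all()
    assert enc["bmi"].dtype == float
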