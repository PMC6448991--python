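"""Conditional-logistic oracle checks, adjustment ladder, sensitivity
exclusions and FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import log_expit

from metapair.containers import PairedDesign
from metapair.inference import (adjustment_model, fdr_adjust,
                                fit_conditional_logistic, per_sd_or,
                                quartile_or, sensitivity_exclude)

from conftest import toy_design


def _loglik(beta, D):
    return float(log_expit(D @ np.atleast_1d(beta)).sum())


def test_discordant_pair_odds_ratio_identity():
    # 6 case-exposed-only, 2 control-exposed-only, 2 concordant pairs
    diffs = np.array([1.0] * 6 + [-1.0] * 2 + [0.0] * 2)
    design, exposure = toy_design(diffs)
    fit = fit_conditional_logistic(design, exposure)
    assert fit.converged
    assert fit.odds_ratios["exposure"] == pytest.approx(3.0, abs=1e-8)
    # oracle: 1-D grid search of the conditional likelihood
    grid = np.linspace(-3, 3, 20001)
    lls = [_loglik(b, diffs.reshape(-1, 1)) for b in grid]
    assert np.exp(grid[int(np.argmax(lls))]) == pytest.approx(3.0, abs=1e-3)


def test_all_zero_differences_flag_infinite_se():
    design, exposure = toy_design(np.zeros(6))
    fit = fit_conditional_logistic(design, exposure)
    assert fit.params["exposure"] == 0.0
    assert np.isinf(fit.se["exposure"])
    assert fit.odds_ratios["exposure"] == 1.0


def test_newton_matches_nelder_mead_oracle(rng):
    for _ in range(5):
        n = 15
        D = rng.normal(0, 1, (n, 3))
        case_ids = [f"c{i}" for i in range(n)]
        ctrl_ids = [f"k{i}" for i in range(n)]
        pairs = pd.DataFrame({"case": case_ids, "control": ctrl_ids},
                             index=pd.Index([f"p{i}" for i in range(n)],
                                            name="pair_id"))
        meta = pd.DataFrame(index=case_ids + ctrl_ids)
        design = PairedDesign(pairs, meta)
        exposure = pd.Series(np.concatenate([D[:, 0], np.zeros(n)]),
                             index=case_ids + ctrl_ids)
        cov = pd.DataFrame(np.vstack([D[:, 1:], np.zeros((n, 2))]),
                           index=case_ids + ctrl_ids, columns=["a", "b"])
        fit = fit_conditional_logistic(design, exposure, cov)
        best = None
        for start in (np.zeros(3), np.ones(3), -np.ones(3)):
            res = minimize(lambda b: -_loglik(b, D), start,
                           method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12,
                                    "maxiter": 20000})
            if best is None or res.fun < best.fun:
                best = res
        np.testing.assert_allclose(fit.params.to_numpy(), best.x, atol=1e-5)


def test_label_swap_negates_coefficients(rng):
    diffs = rng.normal(0.3, 1.0, 12)
    design, exposure = toy_design(diffs)
    fit = fit_conditional_logistic(design, exposure)
    swapped = PairedDesign(
        design.pairs.rename(columns={"case": "control", "control": "case"}),
        design.meta)
    fit2 = fit_conditional_logistic(swapped, exposure)
    assert fit2.params["exposure"] == pytest.approx(-fit.params["exposure"],
                                                    abs=1e-9)


def test_separation_is_flagged_not_divergent():
    design, exposure = toy_design(np.ones(10))
    fit = fit_conditional_logistic(design, exposure)
    assert fit.separation
    assert np.isinf(fit.se["exposure"])


def test_collinear_covariates_named():
    design, exposure = toy_design(np.array([1.0, -1.0, 0.5, 2.0, -0.5]))
    cov = pd.DataFrame({"dup": 2 * exposure}, index=exposure.index)
    with pytest.raises(ValueError, match="dup"):
        fit_conditional_logistic(design, exposure, cov)


def test_conditional_likelihood_immune_to_pair_constants(rng):
    diffs = rng.normal(0.2, 1.0, 20)
    design, exposure = toy_design(diffs)
    fit0 = fit_conditional_logistic(design, exposure)
    shifted = exposure.copy()
    for i, pid in enumerate(design.pairs.index):
        row = design.pairs.loc[pid]
        shift = rng.normal(0, 5)
        shifted[row["case"]] += shift
        shifted[row["control"]] += shift
    fit1 = fit_conditional_logistic(design, shifted)
    assert fit1.params["exposure"] == pytest.approx(fit0.params["exposure"],
                                                    abs=1e-8)


def test_null_pvalues_are_uniform(rng):
    """1:1 matched fits under the null produce uniform p-values."""
    from scipy.stats import kstest

    pvals = []
    for _ in range(1000):
        diffs = rng.normal(0, 1, 60)
        design, exposure = toy_design(diffs)
        fit = fit_conditional_logistic(design, exposure)
        pvals.append(fit.p_values["exposure"])
    assert kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# per-SD and quartile ORs on generator output
# ---------------------------------------------------------------------------

def test_per_sd_or_is_scale_invariant(small_cohort):
    _, ds = small_cohort
    f = ds.truth.index[ds.truth.informative][0]
    vals = np.log(ds.feature_table.intensities[f])
    crude = adjustment_model("crude")
    a = per_sd_or(ds.design, vals, crude)
    b = per_sd_or(ds.design, 2.0 * vals, crude)
    assert a.odds_ratio == pytest.approx(b.odds_ratio, rel=1e-10)


def test_adjustment_ladder_is_nested(small_cohort):
    _, ds = small_cohort
    m1 = adjustment_model("model1").build_matrix(ds.design.meta)
    m2 = adjustment_model("model2").build_matrix(ds.design.meta)
    m3 = adjustment_model("model3").build_matrix(ds.design.meta)
    assert set(m1.columns) < set(m2.columns) < set(m3.columns)


def test_per_sd_log_odds_recovery(rng):
    """Generative within-pair slope 0.5 per SD is recovered on average."""
    est = []
    for _ in range(50):
        n = 500
        d = rng.normal(0, 1.0, n)
        keep = rng.random(n) < 1.0 / (1.0 + np.exp(-0.5 * d))
        d = np.where(keep, d, -d)  # orient pairs by the conditional model
        design, exposure = toy_design(d)
        fit = fit_conditional_logistic(design, exposure)
        est.append(fit.params["exposure"])
    assert abs(np.mean(est) - 0.5) < 0.1


def test_quartile_or_monotone_under_strong_effect(small_cohort):
    _, ds = small_cohort
    f = ds.truth.index[ds.truth.informative][0]
    vals = np.log(ds.feature_table.intensities[f])
    ests = quartile_or(ds.design, vals, adjustment_model("crude"))
    assert [e.contrast for e in ests] == ["Q2", "Q3", "Q4"]
    assert all(e.odds_ratio > 0 for e in ests)


def test_quartile_null_coverage(rng):
    covered = 0
    for seed in range(20):
        gen = np.random.default_rng(seed)
        d = gen.normal(0, 1, 200)
        design, exposure = toy_design(d)
        ests = quartile_or(design, exposure, adjustment_model("crude"))
        covered += all(e.ci_low <= 1.0 <= e.ci_high for e in ests)
    assert covered >= 17  # >= 85% of null datasets cover OR = 1


def test_constant_metabolite_rejected(small_cohort):
    _, ds = small_cohort
    const = pd.Series(1.0, index=ds.feature_table.sample_ids)
    with pytest.raises(ValueError):
        quartile_or(ds.design, const, adjustment_model("crude"))
    with pytest.raises(ValueError, match="zero-variance"):
        per_sd_or(ds.design, const, adjustment_model("crude"))


# ---------------------------------------------------------------------------
# sensitivity exclusion
# ---------------------------------------------------------------------------

def _design_with_glucose(fpg, pg2h, ttd):
    n = len(fpg)
    case_ids = [f"c{i}" for i in range(n)]
    ctrl_ids = [f"k{i}" for i in range(n)]
    pairs = pd.DataFrame({"case": case_ids, "control": ctrl_ids},
                         index=pd.Index([f"p{i}" for i in range(n)],
                                        name="pair_id"))
    meta = pd.DataFrame({
        "fpg": list(fpg) + [5.0] * n,
        "pg2h": list(pg2h) + [6.0] * n,
        "time_to_diagnosis": list(ttd) + [np.nan] * n,
    }, index=case_ids + ctrl_ids)
    return PairedDesign(pairs, meta)


def test_sensitivity_exclusion_boundaries():
    design = _design_with_glucose(
        fpg=[6.0, 6.0, 5.8, 5.0, 6.5, np.nan],
        pg2h=[11.2, 11.1, 12.0, 8.0, 11.2, 12.0],
        ttd=[5.0, 5.0, 5.0, 1.5, 2.0, 5.0])
    reduced, log = sensitivity_exclude(design)
    excluded = set(log["pair_id"])
    assert "p0" in excluded                      # FPG>=5.9 AND 2hPG>11.1
    assert "p1" not in excluded                  # 2hPG exactly 11.1: retained
    assert "p2" not in excluded                  # FPG below 5.9
    assert "p3" in excluded                      # diagnosed within 2 years
    assert "p4" in excluded                      # both criteria
    assert "p5" not in excluded                  # missing FPG: retained
    assert reduced.n_pairs == 3
    # disjunctive reading also excludes isolated high FPG or high 2h-PG;
    # the pair with a missing glucose value is still retained
    reduced_or, _ = sensitivity_exclude(design, or_glucose=True)
    assert reduced_or.n_pairs == 1
    assert reduced_or.pairs.index.tolist() == ["p5"]


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def _bh_oracle(p):
    """Independent step-up implementation for cross-checking."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


def test_bh_worked_example():
    np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


@pytest.mark.parametrize("case", [
    [1.0, 1.0, 1.0],
    [0.2],
    [0.001, 0.5, 0.03, 0.9, 0.02],
])
def test_bh_matches_oracle_and_dominates_p(case):
    q = fdr_adjust(case)
    np.testing.assert_allclose(q, _bh_oracle(case), atol=1e-12)
    assert np.all(q >= np.asarray(case) - 1e-12)


def test_bh_random_inputs_match_oracle(rng):
    for _ in range(20):
        p = rng.random(rng.integers(1, 40))
        np.testing.assert_allclose(fdr_adjust(p), _bh_oracle(p), atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.2])
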