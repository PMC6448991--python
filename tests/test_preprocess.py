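"""Drift correction, feature aggregation and truncated-normal imputation."""

import numpy as np
import pandas as pd
import pytest

from metapair.containers import FeatureTable
from metapair.preprocess import (cluster_features, correct_drift,
                                 impute_missing, qc_cv_filter)
from metapair.simulate import CohortConfig, generate_cohort, inject_batch_drift


def _manual_table(intensities: np.ndarray, batch, inj, roles, rt=None,
                  platform=None):
    n, p = intensities.shape
    sids = [f"s{i:02d}" for i in range(n)]
    fids = [f"F{j:02d}" for j in range(p)]
    n_pairs = sum(1 for r in roles if r == "case")
    pair_ids, ci = [], 0
    case_seen = 0
    for r in roles:
        if r == "qc":
            pair_ids.append("")
        elif r == "case":
            pair_ids.append(f"p{case_seen}")
            case_seen += 1
        else:
            pair_ids.append(f"p{ci}")
            ci += 1
    smeta = pd.DataFrame({
        "subject_id": sids, "pair_id": pair_ids, "role": roles,
        "batch": batch, "injection_order": inj, "timepoint": "baseline",
    }, index=pd.Index(sids, name="sample_id"))
    fmeta = pd.DataFrame({
        "mass": np.linspace(100, 500, p),
        "rt": rt if rt is not None else np.linspace(1, 2, p),
        "platform": platform if platform is not None else ["RP"] * p,
        "mode": ["pos"] * p, "cluster_id": fids, "annotation_level": 4,
    }, index=pd.Index(fids, name="feature_id"))
    return FeatureTable(pd.DataFrame(intensities, index=sids, columns=fids),
                        smeta, fmeta)


def _alternating_roles(n, every=4):
    roles, k = [], 0
    for i in range(n):
        if i % every == 0:
            roles.append("qc")
        else:
            roles.append("case" if k % 2 == 0 else "control")
            k += 1
    # ensure pairing closes: trim trailing unmatched case
    if roles.count("case") != roles.count("control"):
        roles[max(i for i, r in enumerate(roles) if r == "case")] = "qc"
    return roles


def test_constant_qc_no_drift_is_identity():
    rng = np.random.default_rng(0)
    n = 17
    roles = _alternating_roles(n)
    vals = rng.uniform(1e4, 1e5, (n, 3))
    qc = [i for i, r in enumerate(roles) if r == "qc"]
    vals[qc] = 5e4
    table = _manual_table(vals, [1] * n, np.arange(1, n + 1), roles)
    out, model = correct_drift(table)
    np.testing.assert_allclose(out.intensities.to_numpy(), vals, rtol=1e-9)


def test_injected_linear_drift_restores_qc_cv():
    config = CohortConfig(n_pairs=100, n_features=30, n_informative=0,
                          n_batches=2, drift_amplitude=0.2, qc_interval=6,
                          missing_rate=0.0, followup_fraction=0.0, seed=21)
    ds = generate_cohort(config)
    drifted = inject_batch_drift(ds.feature_table, config)
    out, model = correct_drift(drifted)
    loud = model.qc_cv["pre_cv"] > 0.10
    assert loud.sum() >= 10  # the injected drift is visible
    assert (model.qc_cv.loc[loud, "post_cv"] < 0.05).all()


def test_between_batch_level_factors_align_qc_medians():
    rng = np.random.default_rng(1)
    n = 34
    roles = _alternating_roles(n)
    base = rng.uniform(1e4, 1e5, (n, 4))
    qc = np.array([i for i, r in enumerate(roles) if r == "qc"])
    base[qc] = 5e4
    batch = np.array([1] * (n // 2) + [2] * (n - n // 2))
    vals = base * np.where(batch == 1, 1.0, 2.0)[:, None]
    inj = np.concatenate([np.arange(1, n // 2 + 1),
                          np.arange(1, n - n // 2 + 1)])
    table = _manual_table(vals, batch, inj, roles)
    out, _ = correct_drift(table)
    qcmask = out.is_qc()
    for f in out.feature_ids:
        med = out.intensities.loc[qcmask, f].groupby(
            out.sample_meta.loc[qcmask, "batch"]).median()
        assert abs(med.loc[1] / med.loc[2] - 1.0) < 1e-9


def test_drift_correction_is_idempotent():
    config = CohortConfig(n_pairs=60, n_features=10, n_informative=0,
                          n_batches=2, drift_amplitude=0.2, qc_interval=6,
                          missing_rate=0.0, followup_fraction=0.0, seed=22)
    ds = generate_cohort(config)
    once, m1 = correct_drift(inject_batch_drift(ds.feature_table, config))
    twice, m2 = correct_drift(once)
    assert np.all(np.abs(m2.qc_cv["post_cv"] - m1.qc_cv["post_cv"]) < 1e-6)


def test_too_few_qc_points_falls_back_to_median(caplog):
    rng = np.random.default_rng(2)
    n = 9
    roles = ["qc", "case", "control", "case", "control", "case", "control",
             "case", "control"]
    vals = rng.uniform(1e4, 1e5, (n, 2))
    table = _manual_table(vals, [1] * n, np.arange(1, n + 1), roles)
    import logging
    with caplog.at_level(logging.INFO, logger="metapair.preprocess"):
        out, model = correct_drift(table)
    assert (model.methods == "median").all().all()
    assert "median-only" in caplog.text


def test_qc_cv_never_increases_property():
    config = CohortConfig(n_pairs=40, n_features=20, n_informative=0,
                          n_batches=2, drift_amplitude=0.05, qc_interval=5,
                          missing_rate=0.0, followup_fraction=0.0, seed=23)
    ds = generate_cohort(config)
    out, model = correct_drift(inject_batch_drift(ds.feature_table, config))
    assert (model.qc_cv["post_cv"] <= model.qc_cv["pre_cv"] + 1e-12).all()


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _cluster_fixture(rng, n_samples=40):
    """10 features from 3 latent metabolites (within r ~ 0.95, between ~ 0.1)."""
    latents = rng.normal(0, 1, (n_samples, 3))
    assign = [0, 0, 0, 0, 1, 1, 1, 2, 2, 2]
    X = np.empty((n_samples, 10))
    for j, a in enumerate(assign):
        X[:, j] = 0.97 * latents[:, a] + 0.15 * rng.normal(0, 1, n_samples)
    rt = np.array([1.0, 1.01, 1.02, 1.03, 2.0, 2.01, 2.02, 3.0, 3.01, 3.02])
    return np.exp(X + 10), rt, assign


def _connected_components_oracle(adjacency: np.ndarray) -> int:
    """Brute-force DFS component count, independent of scipy.csgraph."""
    n = adjacency.shape[0]
    seen, count = set(), 0
    for start in range(n):
        if start in seen:
            continue
        count += 1
        stack = [start]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(np.flatnonzero(adjacency[v]).tolist())
    return count


def test_identical_features_same_rt_merge_to_one():
    rng = np.random.default_rng(3)
    n = 21
    roles = _alternating_roles(n)
    col = rng.uniform(1e4, 1e5, n)
    vals = np.column_stack([col, col])
    table = _manual_table(vals, [1] * n, np.arange(1, n + 1), roles,
                          rt=[1.0, 1.0])
    out, clusters = cluster_features(table)
    assert len(clusters) == 1 and len(clusters[0].members) == 2
    assert out.n_features == 1


def test_rt_gate_blocks_correlated_features():
    rng = np.random.default_rng(4)
    n = 21
    roles = _alternating_roles(n)
    col = rng.uniform(1e4, 1e5, n)
    table = _manual_table(np.column_stack([col, col]), [1] * n,
                          np.arange(1, n + 1), roles, rt=[1.0, 2.0])
    out, clusters = cluster_features(table, rt_tolerance=0.05)
    assert len(clusters) == 2 and out.n_features == 2


def test_latent_metabolite_grid_recovers_three_clusters(rng):
    vals, rt, assign = _cluster_fixture(rng)
    n = vals.shape[0]
    roles = ["case" if i % 2 == 0 else "control" for i in range(n)]
    table = _manual_table(vals, [1] * n, np.arange(1, n + 1), roles, rt=rt)
    out, clusters = cluster_features(table, rt_tolerance=0.05,
                                     corr_threshold=0.8)
    assert len(clusters) == 3
    # oracle: components of the thresholded correlation+RT graph
    corr = pd.DataFrame(np.log(vals)).corr(method="spearman").to_numpy()
    adj = (corr >= 0.8) & (np.abs(rt[:, None] - rt[None, :]) <= 0.05)
    np.fill_diagonal(adj, False)
    assert _connected_components_oracle(adj) == 3
    # representative is the member with highest median intensity
    for c in clusters:
        med = pd.DataFrame(vals, columns=table.feature_ids)[c.members].median()
        assert c.representative == med.idxmax()


def test_aggregation_never_increases_feature_count_and_map_is_total(small_cohort):
    _, ds = small_cohort
    out, clusters = cluster_features(ds.feature_table)
    assert out.n_features <= ds.feature_table.n_features
    covered = {m for c in clusters for m in c.members}
    assert covered == set(ds.feature_table.feature_ids)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def test_imputation_bounds_seeding_and_identity(small_cohort):
    from metapair.simulate import inject_missingness

    config, ds = small_cohort
    table, mask = inject_missingness(ds.feature_table, config)
    full = impute_missing(table, seed=1)
    again = impute_missing(table, seed=1)
    other = impute_missing(table, seed=2)
    assert not full.intensities.isna().any().any()
    pd.testing.assert_frame_equal(full.intensities, again.intensities)
    # different seed: observed cells identical, imputed cells differ
    m = mask.to_numpy()
    obs_equal = full.intensities.to_numpy()[~m] == other.intensities.to_numpy()[~m]
    assert obs_equal.all()
    assert (full.intensities.to_numpy()[m] != other.intensities.to_numpy()[m]).any()
    # strict support (0, feature minimum)
    for j, f in enumerate(table.feature_ids):
        col_mask = m[:, j]
        if not col_mask.any():
            continue
        m_f = np.nanmin(table.intensities[f].to_numpy())
        imputed = full.intensities[f].to_numpy()[col_mask]
        assert np.all(imputed > 0) and np.all(imputed < m_f)
    # no missing cells -> identity
    same = impute_missing(full, seed=3)
    pd.testing.assert_frame_equal(same.intensities, full.intensities)


def test_feature_with_no_observations_rejected():
    rng = np.random.default_rng(5)
    n = 9
    roles = ["case", "control"] * 4 + ["qc"]
    vals = rng.uniform(1e3, 1e4, (n, 2))
    vals[:, 1] = np.nan
    table = _manual_table(vals, [1] * n, np.arange(1, n + 1), roles)
    with pytest.raises(ValueError, match="F01"):
        impute_missing(table, seed=0)


def test_qc_cv_filter_drops_noisy_features():
    config = CohortConfig(n_pairs=30, n_features=10, n_informative=0,
                          n_batches=1, drift_amplitude=0.8, qc_interval=4,
                          missing_rate=0.0, followup_fraction=0.0, seed=30)
    ds = generate_cohort(config)
    drifted = inject_batch_drift(ds.feature_table, config)
    kept = qc_cv_filter(drifted, max_cv=0.1)
    assert kept.n_features < drifted.n_features
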