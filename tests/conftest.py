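import numpy as np
import pandas as pd
import pytest

from metapair.containers import PairedDesign
from metapair.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured cohort shared by read-only tests."""
    config = CohortConfig(
        n_pairs=60, n_features=50, n_informative=6, effect_sizes=0.8,
        covariate_effects=0.3, n_batches=3, drift_amplitude=0.2,
        qc_interval=10, missing_rate=0.05, followup_fraction=0.5,
        target_icc=0.6, progression_shift=0.3, seed=42,
    )
    return config, generate_cohort(config)


@pytest.fixture(scope="session")
def null_cohort():
    """All effects zero: every discovery statistic should behave as null."""
    config = CohortConfig(
        n_pairs=80, n_features=40, n_informative=8, effect_sizes=0.0,
        covariate_effects=0.3, n_batches=2, drift_amplitude=0.0,
        missing_rate=0.0, followup_fraction=0.5, target_icc=0.5, seed=7,
    )
    return config, generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_paired_matrix(n_pairs, n_features, n_informative=0, effect=0.0,
                       seed=0):
    """Direct paired difference matrix: d ~ N(2*effect_shift, 2) per feature
    (difference of two unit-variance member values)."""
    from metapair.discovery import PairedMatrix

    gen = np.random.default_rng(seed)
    d = gen.normal(0.0, np.sqrt(2.0), (n_pairs, n_features))
    d[:, :n_informative] += effect
    X = np.vstack([d, -d])
    y = np.concatenate([np.ones(n_pairs), -np.ones(n_pairs)])
    return PairedMatrix(X, y, np.arange(n_pairs),
                        np.array([f"F{i:04d}" for i in range(n_features)]))


@pytest.fixture(scope="session")
def small_design(small_cohort):
    _, ds = small_cohort
    return ds.design


def toy_design(diffs: np.ndarray):
    """PairedDesign plus exposure Series from a pair-difference vector, with
    controls at zero."""
    n = len(diffs)
    case_ids = [f"c{i}" for i in range(n)]
    ctrl_ids = [f"k{i}" for i in range(n)]
    pairs = pd.DataFrame(
        {"case": case_ids, "control": ctrl_ids},
        index=pd.Index([f"p{i}" for i in range(n)], name="pair_id"))
    meta = pd.DataFrame(index=case_ids + ctrl_ids)
    design = PairedDesign(pairs=pairs, meta=meta)
    exposure = pd.Series(np.concatenate([diffs, np.zeros(n)]),
                         index=case_ids + ctrl_ids)
    return design, exposure
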