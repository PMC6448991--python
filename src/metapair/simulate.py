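"""Synthetic matched case-control metabolomics cohorts with known ground truth.

The generator emulates the structure of a nested case-control study of
incident type 2 diabetes: 1:1 pairs matched on sex and age (+/-2 years), a
minority of truly discriminative features with stated standardized effect
sizes, traditional risk factors driven by a latent case liability, pooled QC
samples interspersed through the injection sequence, multiplicative batch
levels with smooth injection-order drift, intensity-dependent missingness,
and paired follow-up samples with a controllable within-person correlation
(target ICC) plus case-specific systematic change.

Intensities are generated on the natural-log scale with unit total variance
per feature and exponentiated, so ``effect_sizes`` are standardized mean
case-control differences in SD units.  Within a feature the log intensity of
subject *s* at occasion *t* is

    x_st = mu + b_s + e_st,   b_s ~ N(0, icc),  e_st ~ N(0, 1 - icc)

which makes the correlation between the two sampling occasions equal to the
target ICC.  Informative features additionally load on a shared covariate
factor that also feeds the adiposity/glycaemia risk factors; that factor is
independent of the case liability, so configurations with all effects zero
are exact nulls for every downstream discovery statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .containers import FeatureTable, PairedDesign

# observed relative sizes of the diagnosis-timing and medication groups
GROUP_PROBS = {"A": 26 / 187, "B": 52 / 187, "C": 109 / 187}
MEDICATION_PROBS = {
    "none": 19 / 187,
    "glucose_lowering": 13 / 187,
    "other": 48 / 187,
    "glucose_lowering_and_other": 107 / 187,
}

#: the 14 traditional risk factors every cohort emits
RISK_FACTORS = [
    "age", "fpg", "bmi", "pg2h", "total_cholesterol", "triacylglycerols",
    "sbp", "dbp", "coffee", "fibre", "meat",
    "education", "activity", "smoking",
]

# continuous factor -> (control mean, case-control contrast per SD of
# liability, residual SD, floor).  Contrasts are directionally consistent
# with the cohorts this emulates; exact moments are not targets.
_CONTINUOUS_FACTORS = {
    "fpg": (5.5, 0.5, 0.7, 3.0),
    "pg2h": (6.5, 1.8, 1.5, 2.0),
    "bmi": (25.5, 4.0, 3.5, 16.0),
    "homa_ir": (0.9, 0.8, 0.5, 0.1),
    "homa_b": (74.5, 27.0, 30.0, 10.0),
    "triacylglycerols": (1.4, 0.6, 0.7, 0.3),
    "total_cholesterol": (5.7, 0.2, 1.1, 2.5),
    "sbp": (128.0, 10.0, 15.0, 90.0),
    "dbp": (80.0, 5.0, 9.0, 50.0),
    "fibre": (19.5, -0.6, 7.5, 2.0),
    "meat": (80.0, 8.0, 30.0, 0.0),
    "coffee": (400.0, 20.0, 200.0, 0.0),
    "alcohol": (3.6, -0.3, 4.5, 0.0),
}

# adiposity/glycaemia factors additionally load on the shared covariate
# factor that informative features correlate with
_COVARIATE_FACTOR_LOADINGS = {"bmi": 1.2, "pg2h": 0.5, "homa_ir": 0.15}

_SMOKING = ["non_smoker", "occasional_smoker", "former_smoker", "smoker"]
_EDUCATION = ["elementary", "vocational", "secondary", "university"]
_ACTIVITY = ["inactive", "moderately_inactive", "moderately_active", "active"]


class ConfigError(ValueError):
    """A cohort configuration violates its invariants."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``effect_sizes`` may be a scalar (shared by all informative features) or a
    sequence of length ``n_informative``; ``target_icc`` a scalar or a
    sequence of length ``n_features``.  ``drift_amplitude`` is the total
    log-scale drift over a batch as a fraction of median intensity (small
    amplitudes; the injected curve is log-linear in injection order).
    """

    n_pairs: int = 503
    n_features: int = 1200
    n_informative: int = 40
    effect_sizes: float | list[float] = 0.5
    covariate_effects: float | list[float] = 0.3
    n_batches: int = 8
    drift_amplitude: float = 0.2
    qc_interval: int = 10
    missing_rate: float = 0.05
    followup_fraction: float = 187 / 503
    target_icc: float | list[float] = 0.5
    progression_shift: float | dict[str, float] = 0.3
    seed: int = 0
    qc_noise_sd: float = 0.02
    batch_level_sd: float | None = None  # defaults to drift_amplitude / 2

    effect_vec: np.ndarray = field(init=False, repr=False)
    cov_effect_vec: np.ndarray = field(init=False, repr=False)
    icc_vec: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("n_pairs", "n_features", "n_batches", "qc_interval"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive count")
        if not 0 <= self.n_informative <= self.n_features:
            raise ConfigError("n_informative must satisfy 0 <= n_informative <= n_features")
        self.effect_vec = self._as_vec("effect_sizes", self.n_informative)
        if not np.all(np.isfinite(self.effect_vec)):
            raise ConfigError("effect_sizes must be finite")
        self.cov_effect_vec = self._as_vec("covariate_effects", self.n_informative)
        self.icc_vec = self._as_vec("target_icc", self.n_features)
        if np.any(self.icc_vec < 0) or np.any(self.icc_vec > 1):
            raise ConfigError("target_icc must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if not 0 <= self.followup_fraction <= 1:
            raise ConfigError("followup_fraction must lie in [0, 1]")
        if self.drift_amplitude < 0:
            raise ConfigError("drift_amplitude must be non-negative")
        if isinstance(self.progression_shift, dict):
            unknown = set(self.progression_shift) - set(GROUP_PROBS)
            if unknown:
                raise ConfigError(f"progression_shift has unknown groups: {sorted(unknown)}")

    def _as_vec(self, name: str, n: int) -> np.ndarray:
        val = getattr(self, name)
        vec = np.atleast_1d(np.asarray(val, dtype=float))
        if vec.size == 1:
            return np.full(n, float(vec[0]))
        if vec.size != n:
            raise ConfigError(f"{name} must be scalar or length {n}, got {vec.size}")
        return vec.copy()

    def shift_for_group(self, group: str) -> float:
        if isinstance(self.progression_shift, dict):
            return float(self.progression_shift.get(group, 0.0))
        return float(self.progression_shift)


@dataclass
class CohortDataset:
    """Generator output: clean intensities, pairing, risk factors and truth."""

    feature_table: FeatureTable
    design: PairedDesign
    risk_factors: pd.DataFrame
    truth: pd.DataFrame
    missing_mask: pd.DataFrame | None = None  # filled by inject_missingness


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Draw a complete cohort (no drift, no missingness) under ``config``.

    Drift and missingness are injected by :func:`inject_batch_drift` and
    :func:`inject_missingness` so each distortion can be tested against the
    clean truth.  Output is bit-identical across runs at a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n_pairs, n_feat = config.n_pairs, config.n_features

    # --- subjects, matching, follow-up ------------------------------------
    pair_ids = [f"pair{i:04d}" for i in range(n_pairs)]
    case_age = rng.normal(50.2, 7.9, n_pairs).clip(30, 75)
    ctrl_age = case_age + rng.integers(-2, 3, n_pairs)
    sex = rng.choice(["M", "F"], size=n_pairs, p=[0.445, 0.555])
    n_follow = int(round(config.followup_fraction * n_pairs))
    follow_pairs = set(rng.choice(n_pairs, size=n_follow, replace=False).tolist())
    groups = rng.choice(list(GROUP_PROBS), size=n_pairs, p=list(GROUP_PROBS.values()))
    meds = rng.choice(list(MEDICATION_PROBS), size=n_pairs,
                      p=list(MEDICATION_PROBS.values()))
    time_to_dx = np.exp(rng.normal(np.log(7.0), 0.5, n_pairs)).clip(0.5, 15.0)

    # --- latent structure --------------------------------------------------
    # liability separates cases from controls by 1 SD; z_cov is the shared
    # covariate factor, independent of liability by construction
    liab = np.empty((n_pairs, 2))          # columns: case, control
    liab[:, 0] = rng.normal(1.0, 1.0, n_pairs)
    liab[:, 1] = rng.normal(0.0, 1.0, n_pairs)
    z_cov = rng.normal(0.0, 1.0, (n_pairs, 2))

    # --- feature-level truth ----------------------------------------------
    feat_ids = [f"F{j:05d}" for j in range(n_feat)]
    informative = np.sort(rng.choice(n_feat, size=config.n_informative, replace=False))
    effects = np.zeros(n_feat)
    effects[informative] = config.effect_vec
    cov_effects = np.zeros(n_feat)
    cov_effects[informative] = config.cov_effect_vec
    icc = config.icc_vec
    mu = rng.uniform(np.log(1e4), np.log(1e6), n_feat)
    platform = np.where(np.arange(n_feat) % 2 == 0, "RP", "HILIC")
    mode = np.where(np.arange(n_feat) % 4 < 2, "pos", "neg")
    rt = np.where(platform == "RP", rng.uniform(0.5, 15.0, n_feat),
                  rng.uniform(0.5, 10.0, n_feat))
    mass = rng.uniform(80.0, 900.0, n_feat)

    # --- intensities -------------------------------------------------------
    # subject effects: (pairs, 2 members, features); occasion noise drawn per
    # emitted sample.  occasion 0 = baseline, 1 = follow-up.
    sd_b = np.sqrt(icc)
    sd_e = np.sqrt(1.0 - icc)
    subj_eff = rng.normal(0.0, 1.0, (n_pairs, 2, n_feat)) * sd_b
    occ_noise = rng.normal(0.0, 1.0, (n_pairs, 2, 2, n_feat)) * sd_e

    rows: list[np.ndarray] = []
    sample_records: list[dict] = []
    for p in range(n_pairs):
        timepoints = [0, 1] if p in follow_pairs else [0]
        for m, role in ((0, "case"), (1, "control")):
            subj = f"subj{p:04d}{'c' if m == 0 else 'n'}"
            for t in timepoints:
                x = mu + subj_eff[p, m] + occ_noise[p, m, t]
                x = x + cov_effects * z_cov[p, m]
                if role == "case":
                    x = x + effects
                    if t == 1:
                        shift = config.shift_for_group(groups[p])
                        x = x + np.where(effects != 0,
                                         np.sign(effects) * shift, 0.0)
                rows.append(x)
                sample_records.append({
                    "sample_id": f"{subj}_t{t}",
                    "subject_id": subj,
                    "pair_id": pair_ids[p],
                    "role": role,
                    "timepoint": "baseline" if t == 0 else "followup",
                    "pair_index": p,
                    "member": m,
                })
    log_x = np.vstack(rows)

    smeta = pd.DataFrame(sample_records).set_index("sample_id")

    # --- risk factors (constant within subject across occasions) -----------
    rf = _risk_factors(rng, smeta, liab, z_cov, case_age, ctrl_age, sex,
                       groups, meds, time_to_dx)
    smeta = smeta.join(rf)

    # --- QC samples, batches, injection order ------------------------------
    intensities = pd.DataFrame(np.exp(log_x), index=smeta.index, columns=feat_ids)
    pooled_mean = intensities.mean(axis=0).to_numpy()
    intensities, smeta = _assign_batches_and_qc(
        rng, intensities, smeta, pooled_mean, config, pair_ids)

    smeta = smeta.drop(columns=["pair_index", "member"])
    fmeta = pd.DataFrame(
        {"mass": mass, "rt": rt, "platform": platform, "mode": mode,
         "cluster_id": feat_ids, "annotation_level": 4},
        index=pd.Index(feat_ids, name="feature_id"))
    table = FeatureTable(intensities, smeta, fmeta).validate()

    truth = pd.DataFrame(
        {"feature_id": feat_ids, "effect": effects, "target_icc": icc,
         "covariate_effect": cov_effects,
         "informative": np.isin(np.arange(n_feat), informative)}
    ).set_index("feature_id")

    design = PairedDesign.from_table(table, "baseline")
    risk_cols = list(_CONTINUOUS_FACTORS) + ["age", "sex", "education",
                                             "activity", "smoking"]
    risk = smeta.loc[smeta["role"] != "qc", risk_cols]
    return CohortDataset(feature_table=table, design=design,
                         risk_factors=risk, truth=truth)


def _risk_factors(rng, smeta, liab, z_cov, case_age, ctrl_age, sex,
                  groups, meds, time_to_dx) -> pd.DataFrame:
    """Per-sample traditional risk factors; values fixed within subject."""
    p_idx = smeta["pair_index"].to_numpy()
    m_idx = smeta["member"].to_numpy()
    is_case = m_idx == 0
    n_pairs = liab.shape[0]
    out = pd.DataFrame(index=smeta.index)
    out["age"] = np.where(is_case, case_age[p_idx], ctrl_age[p_idx])
    out["sex"] = sex[p_idx]

    L = liab[p_idx, m_idx]
    Z = z_cov[p_idx, m_idx]
    for name, (base, contrast, sd, floor) in _CONTINUOUS_FACTORS.items():
        noise = rng.normal(0.0, 1.0, (n_pairs, 2))[p_idx, m_idx] * sd
        val = base + contrast * L + noise
        val = val + _COVARIATE_FACTOR_LOADINGS.get(name, 0.0) * Z
        out[name] = np.maximum(val, floor)

    for name, levels, slope in (("smoking", _SMOKING, 0.15),
                                ("education", _EDUCATION, -0.15),
                                ("activity", _ACTIVITY, -0.1)):
        latent = slope * L + rng.normal(0.0, 1.0, (n_pairs, 2))[p_idx, m_idx]
        cuts = np.quantile(latent, [0.25, 0.5, 0.75])
        out[name] = np.asarray(levels)[np.searchsorted(cuts, latent)]

    out["diagnosis_group"] = np.where(is_case, groups[p_idx], "")
    out["medication"] = np.where(is_case, meds[p_idx], "")
    out["time_to_diagnosis"] = np.where(is_case, time_to_dx[p_idx], np.nan)
    return out


def _assign_batches_and_qc(rng, intensities, smeta, pooled_mean, config,
                           pair_ids):
    """Split pairs over batches (pairs and their follow-ups never straddle a
    batch), shuffle within batch and interleave QC injections."""
    n_pairs = len(pair_ids)
    batch_of_pair = np.repeat(np.arange(config.n_batches),
                              int(np.ceil(n_pairs / config.n_batches)))[:n_pairs]
    pair_index = smeta["pair_index"].to_numpy()
    smeta = smeta.copy()
    smeta["batch"] = batch_of_pair[pair_index] + 1

    qc_rows, qc_meta, order_frames = [], [], []
    qc_template = {c: ("" if smeta[c].dtype == object else np.nan)
                   for c in smeta.columns if c not in ("batch",)}
    for b, grp in smeta.groupby("batch"):
        ids = grp.index.to_numpy()
        rng.shuffle(ids)
        inj, qc_count, pos = {}, 0, 1
        for k, sid in enumerate(ids):
            if k % config.qc_interval == 0:
                qc_id = f"qc_b{b}_{qc_count:03d}"
                noise = np.exp(rng.normal(0.0, config.qc_noise_sd,
                                          pooled_mean.size))
                qc_rows.append(pooled_mean * noise)
                qc_meta.append({**qc_template, "sample_id": qc_id, "batch": b,
                                "role": "qc", "injection_order": pos,
                                "pair_id": "", "subject_id": qc_id,
                                "timepoint": "baseline"})
                qc_count += 1
                pos += 1
            inj[sid] = pos
            pos += 1
        order_frames.append(pd.Series(inj, name="injection_order"))

    smeta["injection_order"] = pd.concat(order_frames)
    if qc_rows:
        qc_df = pd.DataFrame(qc_rows, columns=intensities.columns,
                             index=[m["sample_id"] for m in qc_meta])
        intensities = pd.concat([intensities, qc_df])
        qmeta = pd.DataFrame(qc_meta).set_index("sample_id")
        smeta = pd.concat([smeta, qmeta[smeta.columns]])
    # stable order: batch then injection order
    order = smeta.sort_values(["batch", "injection_order"]).index
    return intensities.loc[order], smeta.loc[order]


# ---------------------------------------------------------------------------
# distortions
# ---------------------------------------------------------------------------

def inject_batch_drift(table: FeatureTable, config: CohortConfig) -> FeatureTable:
    """Multiply intensities by per-batch level factors and a smooth
    (log-linear, monotone in injection order) within-batch drift curve.

    QC samples receive the same distortion as study samples.  Raises if the
    table lacks injection-order metadata or if any pair (or a pair's
    follow-up samples) straddles batches — randomisation is constrained to
    keep them together.
    """
    smeta = table.sample_meta
    for col in ("injection_order", "batch"):
        if col not in smeta.columns or smeta[col].isna().all():
            raise ValueError(f"missing {col} metadata")
    nonqc = smeta[smeta["role"] != "qc"]
    split = nonqc.groupby("pair_id")["batch"].nunique()
    bad = split[split > 1].index.tolist()
    if bad:
        raise ValueError(f"pairs split across batches: {bad}")

    rng = np.random.default_rng(config.seed + 104729)  # decoupled stream
    out = table.copy()
    vals = out.intensities.to_numpy(dtype=float)
    n_feat = vals.shape[1]
    level_sd = (config.batch_level_sd if config.batch_level_sd is not None
                else config.drift_amplitude / 2)
    for b in np.sort(smeta["batch"].unique()):
        rows = np.flatnonzero((smeta["batch"] == b).to_numpy())
        inj = smeta["injection_order"].to_numpy(dtype=float)[rows]
        span = max(inj.max() - inj.min(), 1.0)
        frac = (inj - inj.min()) / span - 0.5
        level = rng.normal(0.0, level_sd) if level_sd > 0 else 0.0
        direction = rng.choice([-1.0, 1.0], size=n_feat)
        log_factor = level + np.outer(frac, direction * config.drift_amplitude)
        vals[rows] = vals[rows] * np.exp(log_factor)
    out.intensities.iloc[:, :] = vals
    return out


def inject_missingness(table: FeatureTable, config: CohortConfig
                       ) -> tuple[FeatureTable, pd.DataFrame]:
    """Mask values missing with probability decreasing in log intensity.

    The masking probability is logistic in the standardized log intensity,
    ``p = expit(c - z)``, with the intercept ``c`` calibrated so the overall
    realized rate is ``missing_rate`` (+/- binomial noise).  QC samples are
    never masked (the pool is abundant and well measured).  Returns the
    masked table and the boolean mask (True = masked) so imputation can be
    scored against truth.
    """
    out = table.copy()
    mask = pd.DataFrame(False, index=out.intensities.index,
                        columns=out.intensities.columns)
    if config.missing_rate == 0:
        return out, mask
    rng = np.random.default_rng(config.seed + 15485863)
    study = (out.sample_meta["role"] != "qc").to_numpy()
    vals = out.intensities.to_numpy(dtype=float)
    logv = np.log(vals[study])
    z = (logv - logv.mean()) / logv.std()

    def realized(c: float) -> float:
        return float(expit(c - z).mean()) - config.missing_rate

    c = brentq(realized, -30.0, 30.0)
    p = expit(c - z)
    hit = rng.random(p.shape) < p
    sub = vals[study]
    sub[hit] = np.nan
    vals[study] = sub
    out.intensities.iloc[:, :] = vals
    m = mask.to_numpy()
    m[study] = hit
    mask.iloc[:, :] = m
    return out, mask
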