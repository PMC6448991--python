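"""In-memory containers shared by every pipeline stage.

The lingua franca of the pipeline is the :class:`FeatureTable`: a samples x
features intensity matrix (``NaN`` marks a missing measurement) plus two
metadata frames, one per sample and one per feature.  The matched
case-control structure is carried separately by :class:`PairedDesign`, which
is derived from the sample metadata and drives the multilevel transform and
the conditional likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sample roles recognised in ``sample_meta["role"]``
ROLES = ("case", "control", "qc")
TIMEPOINTS = ("baseline", "followup")


class FeatureTableError(ValueError):
    """Raised when a feature table violates its structural invariants."""


@dataclass
class FeatureTable:
    """Samples x features intensity matrix with sample and feature metadata.

    Parameters
    ----------
    intensities
        Wide frame, one row per sample, one column per feature.  Values are
        non-negative where present; ``NaN`` is the missing marker (zeros are
        measured values).
    sample_meta
        Indexed by sample id.  Required columns: ``subject_id``, ``pair_id``,
        ``role`` (case/control/qc), ``batch``, ``injection_order``,
        ``timepoint``.  Risk-factor columns ride along.
    feature_meta
        Indexed by feature id.  Expected columns include ``mass``, ``rt``
        (minutes), ``platform`` (RP/HILIC), ``mode`` (pos/neg) and, after
        aggregation, ``cluster_id``.
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame

    # -- structural checks -------------------------------------------------
    def validate(self) -> "FeatureTable":
        ints, smeta, fmeta = self.intensities, self.sample_meta, self.feature_meta
        if ints.shape[1] == 0:
            raise FeatureTableError("no features")
        if ints.shape[0] == 0:
            raise FeatureTableError("no samples")
        if ints.index.duplicated().any():
            dupes = ints.index[ints.index.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate sample ids: {dupes}")
        if ints.columns.duplicated().any():
            dupes = ints.columns[ints.columns.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate feature ids: {dupes}")
        if not ints.index.equals(smeta.index):
            raise FeatureTableError("sample_meta index does not match intensity rows")
        if not ints.columns.equals(fmeta.index):
            raise FeatureTableError("feature_meta index does not match intensity columns")
        vals = ints.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise FeatureTableError("negative intensities present")
        bad_roles = set(smeta["role"].unique()) - set(ROLES)
        if bad_roles:
            raise FeatureTableError(f"unknown sample roles: {sorted(bad_roles)}")
        nonqc = smeta[smeta["role"] != "qc"]
        if nonqc["pair_id"].isna().any():
            missing = nonqc.index[nonqc["pair_id"].isna()].tolist()
            raise FeatureTableError(f"non-QC samples without pair id: {missing}")
        self._check_pairing(nonqc)
        return self

    @staticmethod
    def _check_pairing(nonqc: pd.DataFrame) -> None:
        """Every (pair, timepoint) must hold exactly one case and one control."""
        for (pid, tp), grp in nonqc.groupby(["pair_id", "timepoint"], observed=True):
            roles = sorted(grp["role"].tolist())
            if roles != ["case", "control"]:
                raise FeatureTableError(
                    f"pair {pid!r} at {tp!r} has roles {roles}; "
                    "expected exactly one case and one control"
                )

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.columns

    def is_qc(self) -> pd.Series:
        return self.sample_meta["role"] == "qc"

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.sample_meta.copy(), self.feature_meta.copy()
        )

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(
            self.intensities.loc[sample_ids],
            self.sample_meta.loc[sample_ids],
            self.feature_meta,
        )

    def subset_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(
            self.intensities[list(feature_ids)],
            self.sample_meta,
            self.feature_meta.loc[list(feature_ids)],
        )


@dataclass
class PairedDesign:
    """Case-control pairing at one timepoint.

    ``pairs`` has one row per pair id with columns ``case`` and ``control``
    holding sample ids.  ``meta`` is the sample metadata for the involved
    samples (risk factors included) so downstream models can pull covariates.
    """

    pairs: pd.DataFrame
    meta: pd.DataFrame = field(repr=False)

    @classmethod
    def from_table(cls, table: FeatureTable, timepoint: str = "baseline") -> "PairedDesign":
        smeta = table.sample_meta
        sel = (smeta["role"] != "qc") & (smeta["timepoint"] == timepoint)
        sub = smeta[sel]
        rows = {}
        for pid, grp in sub.groupby("pair_id", observed=True):
            case = grp.index[grp["role"] == "case"]
            ctrl = grp.index[grp["role"] == "control"]
            if len(case) != 1 or len(ctrl) != 1:
                raise FeatureTableError(
                    f"pair {pid!r} at {timepoint!r} is incomplete "
                    f"({len(case)} case(s), {len(ctrl)} control(s))"
                )
            rows[pid] = {"case": case[0], "control": ctrl[0]}
        pairs = pd.DataFrame.from_dict(rows, orient="index").rename_axis("pair_id")
        pairs = pairs.sort_index()
        return cls(pairs=pairs, meta=sub)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def case_ids(self) -> np.ndarray:
        return self.pairs["case"].to_numpy()

    @property
    def control_ids(self) -> np.ndarray:
        return self.pairs["control"].to_numpy()

    def subset(self, pair_ids) -> "PairedDesign":
        pairs = self.pairs.loc[list(pair_ids)]
        keep = np.concatenate([pairs["case"].to_numpy(), pairs["control"].to_numpy()])
        return PairedDesign(pairs=pairs, meta=self.meta.loc[self.meta.index.isin(keep)])

    def covariate(self, name: str) -> pd.Series:
        """Per-sample covariate values for all samples in the design."""
        return self.meta[name]
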