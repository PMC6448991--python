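"""Reading and writing the feature-table exchange format and run configuration.

The exchange format is wide delimited text (TSV by default, comma accepted):
``<prefix>.intensities.tsv`` holds the samples x features matrix (empty cell =
missing; zeros are measured values), ``<prefix>.samples.tsv`` the per-sample
metadata and ``<prefix>.features.tsv`` the per-feature metadata.  Round trips
are value-exact: ``write`` then ``read`` reproduces intensities to full float
precision and metadata exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .containers import FeatureTable, FeatureTableError

_SUFFIXES = {"\t": ".tsv", ",": ".csv"}


def _paths(prefix: str | Path, sep: str) -> tuple[Path, Path, Path]:
    prefix = Path(prefix)
    ext = _SUFFIXES[sep]
    return (
        prefix.with_name(prefix.name + ".intensities" + ext),
        prefix.with_name(prefix.name + ".samples" + ext),
        prefix.with_name(prefix.name + ".features" + ext),
    )


def write_feature_table(table: FeatureTable, prefix: str | Path, sep: str = "\t") -> None:
    """Write a validated table to ``<prefix>.{intensities,samples,features}``."""
    table.validate()
    ip, sp, fp = _paths(prefix, sep)
    ip.parent.mkdir(parents=True, exist_ok=True)
    # repr-round-trip float format keeps full precision in plain text
    table.intensities.rename_axis("sample_id").to_csv(ip, sep=sep, float_format="%.17g")
    table.sample_meta.rename_axis("sample_id").to_csv(sp, sep=sep, float_format="%.17g")
    table.feature_meta.rename_axis("feature_id").to_csv(fp, sep=sep, float_format="%.17g")


def read_feature_table(prefix: str | Path, sep: str = "\t") -> FeatureTable:
    """Read a table written by :func:`write_feature_table` and validate it.

    Raises
    ------
    FeatureTableError
        On duplicate ids, non-numeric intensity cells (other than the empty
        missing marker), orphan pair ids or an empty feature set.
    FileNotFoundError
        If any of the three component files is absent.
    """
    ip, sp, fp = _paths(prefix, sep)
    for p in (ip, sp, fp):
        if not p.exists():
            raise FileNotFoundError(f"missing component file: {p}")
    ints = pd.read_csv(ip, sep=sep, index_col="sample_id",
                       float_precision="round_trip")
    non_numeric = ints.columns[
        [not pd.api.types.is_numeric_dtype(ints[c]) for c in ints.columns]
    ]
    if len(non_numeric):
        raise FeatureTableError(
            f"non-numeric intensity cells in features: {non_numeric.tolist()}"
        )
    smeta = pd.read_csv(sp, sep=sep, index_col="sample_id",
                        float_precision="round_trip")
    fmeta = pd.read_csv(fp, sep=sep, index_col="feature_id")
    table = FeatureTable(ints, smeta, fmeta)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Stage-specific parameter blocks for a pipeline run.

    Any block set to ``None`` disables that stage.  Every stage draws its
    randomness from ``seed`` combined with a fixed per-stage offset, so a run
    is reproducible from the YAML alone.
    """

    out_dir: str = "metapair_run"
    seed: int = 1
    simulate: dict | None = None
    preprocess: dict | None = None
    discover: dict | None = None
    infer: dict | None = None
    repro: dict | None = None
    predict: dict | None = None
    input_table: str | None = None

    def __post_init__(self) -> None:
        if self.simulate is None and self.input_table is None:
            raise ValueError("config needs either a 'simulate' block or 'input_table'")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ValueError("seed must be an integer")
        for block_name in ("discover", "predict"):
            block = getattr(self, block_name)
            if not block:
                continue
            for key in ("n_repetitions", "n_outer_folds", "n_inner_folds",
                        "n_permutations", "n_splits", "max_components"):
                if key in block and int(block[key]) < 1:
                    raise ValueError(f"{block_name}.{key} must be >= 1")
            for key in ("train_fraction", "elimination_ratio"):
                if key in block and not 0.0 < float(block[key]) < 1.0:
                    raise ValueError(f"{block_name}.{key} must be in (0,1)")
        if self.infer and "fdr_level" in self.infer:
            if not 0.0 < float(self.infer["fdr_level"]) < 1.0:
                raise ValueError("infer.fdr_level must be in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw: Mapping[str, Any] = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
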