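"""End-to-end orchestration: simulate -> preprocess -> discover -> infer ->
reproducibility -> predict, driven by a :class:`~metapair.io.RunConfig`.

Every stage writes delimited-text outputs plus a JSON summary into the run
directory; seeds, package version and stage timings go to ``run.log``.  The
JSON summaries contain no timestamps, so identical config + seed produce
byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import FeatureTable, PairedDesign
from .io import RunConfig, read_feature_table, write_feature_table
from .simulate import CohortConfig, generate_cohort, inject_batch_drift, inject_missingness
from .preprocess import (correct_drift, cluster_features, clusters_to_frame,
                         impute_missing, qc_cv_filter)
from .discovery import (RdcvConfig, mlpls_rdcv, multilevel_transform,
                        permutation_validation, select_top, spls_prefilter)
from .inference import adjustment_model, fdr_adjust, per_sd_or
from .reproducibility import icc_two_occasion, medication_stratified_tests, mixed_change_model
from .prediction import (TS_NO_2HPG_VARIABLES, TS_VARIABLES, encode_predictors,
                         evaluate_auc_splits, nri_idi, rf_rdcv_select)

logger = logging.getLogger(__name__)

# per-stage seed offsets keep streams decoupled under one base seed
_OFFSETS = {"simulate": 0, "preprocess": 11, "discover": 23, "infer": 37,
            "repro": 41, "predict": 53}


class StageError(RuntimeError):
    pass


def _dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: RunConfig, only: set[str] | None = None) -> dict:
    """Execute the configured stages; returns the collected JSON summaries.

    ``only`` restricts execution to a subset of stages (the CLI subcommands);
    an unlisted stage is skipped even if configured.  Stage failures raise
    :class:`StageError` naming the stage and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"metapair {__version__} seed={config.seed}"]
    summaries: dict[str, dict] = {}

    def stage_enabled(name: str) -> bool:
        return getattr(config, name) is not None and (only is None or name in only)

    def run_stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            summaries[name] = fn()
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        log_lines.append(f"{name}: seed={config.seed + _OFFSETS[name]} "
                         f"elapsed={time.perf_counter() - t0:.2f}s")
        _dump(summaries[name], out / f"{name}.json")

    # --- obtain the table -------------------------------------------------
    dataset = None
    if stage_enabled("simulate"):
        def _simulate():
            nonlocal dataset
            cc = CohortConfig(**{**config.simulate,
                                 "seed": config.simulate.get(
                                     "seed", config.seed + _OFFSETS["simulate"])})
            dataset = generate_cohort(cc)
            table = inject_batch_drift(dataset.feature_table, cc)
            table, mask = inject_missingness(table, cc)
            dataset.feature_table = table
            dataset.missing_mask = mask
            write_feature_table(table, out / "cohort")
            dataset.truth.to_csv(out / "truth.tsv", sep="\t")
            return {"n_pairs": cc.n_pairs, "n_features": cc.n_features,
                    "n_informative": cc.n_informative,
                    "n_samples": int(table.n_samples)}
        run_stage("simulate", _simulate)
        table = dataset.feature_table
    elif config.input_table is not None:
        table = read_feature_table(config.input_table)
    elif (out / "processed.intensities.tsv").exists():
        table = read_feature_table(out / "processed")
    elif (out / "cohort.intensities.tsv").exists():
        table = read_feature_table(out / "cohort")
    else:
        raise StageError("no input: neither simulate block nor input_table "
                         "nor a previous run in out_dir")

    truth_path = out / "truth.tsv"

    # --- preprocess --------------------------------------------------------
    if stage_enabled("preprocess"):
        def _preprocess():
            nonlocal table
            block = config.preprocess or {}
            drift_summary = {}
            if (table.sample_meta["role"] == "qc").any():
                table, model = correct_drift(table)
                model.qc_cv.to_csv(out / "drift_diagnostics.tsv", sep="\t")
                drift_summary = {
                    "median_pre_cv": float(model.qc_cv["pre_cv"].median()),
                    "median_post_cv": float(model.qc_cv["post_cv"].median()),
                }
                if block.get("qc_cv_max") is not None:
                    table = qc_cv_filter(table, float(block["qc_cv_max"]))
                    drift_summary["n_after_qc_cv_filter"] = int(table.n_features)
            table, clusters = cluster_features(
                table, rt_tolerance=block.get("rt_tolerance", 0.05),
                corr_threshold=block.get("corr_threshold", 0.8))
            clusters_to_frame(clusters).to_csv(out / "clusters.tsv", sep="\t")
            table = impute_missing(table, config.seed + _OFFSETS["preprocess"])
            write_feature_table(table, out / "processed")
            return {**drift_summary, "n_clusters": len(clusters),
                    "n_features_out": int(table.n_features)}
        run_stage("preprocess", _preprocess)

    design = PairedDesign.from_table(table, "baseline")
    top_features: list = []

    # --- discover ----------------------------------------------------------
    if stage_enabled("discover"):
        def _discover():
            nonlocal top_features
            block = dict(config.discover or {})
            prefilter_sparsity = block.pop("prefilter_sparsity", 0.2)
            prefilter_components = block.pop("prefilter_components", 2)
            run_permutation = block.pop("run_permutation", False)
            threshold = block.pop("rank_threshold", 100.0)
            rd = RdcvConfig(**{**block, "rank_threshold": threshold,
                               "seed": block.get("seed",
                                                 config.seed + _OFFSETS["discover"])})
            pm = multilevel_transform(table, design)
            platform = table.feature_meta["platform"].to_numpy()
            kept = spls_prefilter(pm, prefilter_components, prefilter_sparsity,
                                  platform=platform)
            cols = np.flatnonzero(np.isin(pm.feature_ids, kept))
            pm_f = pm.subset_features(cols)
            ranked = mlpls_rdcv(pm_f, rd)
            ranked.to_frame().to_csv(out / "ranked_features.tsv", sep="\t")
            top_features = select_top(ranked, rd.rank_threshold)
            summary = {
                "n_prefiltered": len(kept),
                "n_top": len(top_features),
                "top_features": top_features,
                "mean_misclassification": float(ranked.misclassification.mean()),
            }
            if run_permutation:
                perm = permutation_validation(
                    pm_f, rd, observed=float(ranked.misclassification.mean()))
                pd.Series(perm.null_distribution, name="null_misclassification"
                          ).to_csv(out / "permutation_null.tsv", sep="\t")
                summary["permutation_p"] = perm.p_value
            return summary
        run_stage("discover", _discover)

    if not top_features and truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col="feature_id")
        top_features = [f for f in truth.index[truth["informative"]]
                        if f in set(table.feature_ids)]

    # --- infer -------------------------------------------------------------
    if stage_enabled("infer"):
        def _infer():
            block = config.infer or {}
            models = [adjustment_model(m) for m in
                      block.get("models", ["crude", "model1", "model2", "model3"])]
            feats = block.get("features", top_features)
            if not feats:
                raise ValueError("no features to test; run discover first or "
                                 "list infer.features")
            rows = []
            logints = np.log(table.intensities)
            for model in models:
                ests = [per_sd_or(design, logints[f], model, name=f) for f in feats]
                qs = fdr_adjust([e.p for e in ests])
                for e, q in zip(ests, qs):
                    e.q = float(q)
                    rows.append(e.as_dict())
            df = pd.DataFrame(rows)
            df.to_csv(out / "effect_estimates.tsv", sep="\t", index=False)
            alpha = float(block.get("fdr_level", 0.05))
            n_sig = int((df.loc[df["model"] != "crude", "q"] < alpha).sum())
            return {"n_features": len(feats), "n_models": len(models),
                    "n_significant_adjusted": n_sig}
        run_stage("infer", _infer)

    # --- reproducibility ---------------------------------------------------
    if stage_enabled("repro"):
        def _repro():
            feats = (config.repro or {}).get("features", top_features)
            if not feats:
                raise ValueError("no features for reproducibility analysis")
            smeta = table.sample_meta
            ctrl = two_occasion_values(table, "control")
            case = two_occasion_values(table, "case")
            case_meta = smeta[(smeta["role"] == "case")
                              & (smeta["timepoint"] == "baseline")]
            med = case_meta.set_index("subject_id")["medication"]
            rows = []
            for f in feats:
                rec = {"feature_id": f}
                if ctrl is not None and len(ctrl[0]) >= 3:
                    vals = np.column_stack([np.log(ctrl[0][f]), np.log(ctrl[1][f])])
                    icc = icc_two_occasion(vals)
                    rec.update(icc=icc.icc, icc_low=icc.ci[0], icc_high=icc.ci[1],
                               rank_fallback=icc.used_rank_transform,
                               band=icc.band)
                if case is not None and len(case[0]) >= 3:
                    vals = np.column_stack([np.log(case[0][f]), np.log(case[1][f])])
                    chg = mixed_change_model(vals)
                    rec.update(change=chg.time_effect, change_p=chg.p,
                               direction="higher" if chg.time_effect > 0
                               else "lower")
                    strat = medication_stratified_tests(
                        vals, med.reindex(case[0].index).to_numpy())
                    rec.update(medication_affected=strat.affected,
                               medication_p=strat.interaction_p)
                rows.append(rec)
            df = pd.DataFrame(rows)
            df.to_csv(out / "reproducibility.tsv", sep="\t", index=False)
            n_good = int((df.get("icc", pd.Series(dtype=float)) >= 0.4).sum())
            return {"n_features": len(feats), "n_icc_ge_0.4": n_good}
        run_stage("repro", _repro)

    # --- predict -----------------------------------------------------------
    if stage_enabled("predict"):
        def _predict():
            block = dict(config.predict or {})
            seed = block.get("seed", config.seed + _OFFSETS["predict"])
            n_splits = int(block.get("n_splits", 500))
            feats = block.get("metabolites", top_features)
            if not feats:
                raise ValueError("no metabolite candidates for prediction")
            smeta = table.sample_meta
            base = smeta[(smeta["role"] != "qc")
                         & (smeta["timepoint"] == "baseline")]
            y = (base["role"] == "case").astype(int).to_numpy()
            mets = np.log(table.intensities.loc[base.index, feats])
            mets.columns = [f"met_{c}" for c in mets.columns]
            # model 2 additionally adjusts for alcohol, which is not in the
            # 14-factor TS pool
            trad = encode_predictors(base, TS_VARIABLES + ["alcohol"])
            data = pd.concat([trad, mets], axis=1)

            rd = RdcvConfig(
                n_repetitions=int(block.get("n_repetitions", 3)),
                n_outer_folds=int(block.get("n_outer_folds", 4)),
                n_inner_folds=int(block.get("n_inner_folds", 3)),
                elimination_ratio=float(block.get("elimination_ratio", 0.3)),
                seed=seed)
            imp = block.get("importance", "permutation")
            ms = rf_rdcv_select(data[mets.columns], y, rd, importance=imp)
            ts = rf_rdcv_select(data[TS_VARIABLES], y, rd, importance=imp)
            ts2 = rf_rdcv_select(data[TS_NO_2HPG_VARIABLES], y, rd, importance=imp)
            cs = rf_rdcv_select(data, y, rd, importance=imp)

            model_vars = {
                "MS": ms.selected, "TS": ts.selected, "TS_no2hPG": ts2.selected,
                "CS": cs.selected,
                "model1": ["fpg", "bmi"],
                "model2": ["fpg", "bmi", "alcohol", "fibre", "meat", "coffee",
                           "education", "activity", "smoking"],
            }
            model_vars["model1+MS"] = model_vars["model1"] + ms.selected
            model_vars["model2+MS"] = model_vars["model2"] + ms.selected
            model_vars["TS+MS"] = [v for v in ts.selected] + ms.selected
            ev = evaluate_auc_splits(data, y, model_vars, n_splits=n_splits,
                                     train_fraction=float(
                                         block.get("train_fraction", 0.6)),
                                     seed=seed)
            ev.auc.to_csv(out / "auc_summary.tsv", sep="\t")
            ev.pairwise_p.to_csv(out / "auc_pairwise_p.tsv", sep="\t")

            from .prediction import build_score
            reclass = {}
            for base_lab, new_lab in (("model1", "model1+MS"),
                                      ("model2", "model2+MS"),
                                      ("TS", "TS+MS")):
                b = build_score(data, y, model_vars[base_lab], base_lab)
                nmod = build_score(data, y, model_vars[new_lab], new_lab)
                res = nri_idi(b.risk(data), nmod.risk(data), y,
                              scores_are_risks=True)
                reclass[f"{new_lab}_vs_{base_lab}"] = {
                    "nri": res.nri, "nri_ci": list(res.nri_ci),
                    "idi": res.idi, "idi_ci": list(res.idi_ci)}
            _dump({"selected": {k: list(v) for k, v in model_vars.items()},
                   "reclassification": reclass}, out / "prediction_models.json")
            return {"auc": ev.summary(), "reclassification": reclass,
                    "selected": {k: list(map(str, v))
                                 for k, v in model_vars.items()}}
        run_stage("predict", _predict)

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    _dump(summaries, out / "summary.json")
    return summaries


def two_occasion_values(table: FeatureTable, role: str
                        ) -> tuple[pd.DataFrame, pd.DataFrame] | None:
    """Baseline and follow-up intensities of subjects with both occasions,
    aligned by subject id (one row per subject, identical order)."""
    smeta = table.sample_meta
    sub = smeta[smeta["role"] == role]
    counts = sub.groupby("subject_id")["timepoint"].nunique()
    both = counts[counts == 2].index
    if len(both) == 0:
        return None
    b = sub[(sub["subject_id"].isin(both)) & (sub["timepoint"] == "baseline")]
    f = sub[(sub["subject_id"].isin(both)) & (sub["timepoint"] == "followup")]
    b, f = b.sort_values("subject_id"), f.sort_values("subject_id")
    base = table.intensities.loc[b.index].set_axis(b["subject_id"].to_numpy())
    follow = table.intensities.loc[f.index].set_axis(f["subject_id"].to_numpy())
    return base, follow
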