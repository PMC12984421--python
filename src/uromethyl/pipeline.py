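"""End-to-end orchestration: marker discovery -> model development -> validation.

`run_analysis` drives the whole study on an in-memory simulated cohort and
is what the tests and the acceptance script use. The disk-stage functions
(`stage_*`) expose the same flow file-by-file for the command-line
interface: each stage reads the artifacts of its upstream stages from the
output directory and writes its own, so stages are individually
rerunnable. A single config seed fans out into per-stage seeds through a
stable hash, and a manifest records the config so any threshold override
is auditable.

Split discipline: the marker cohort (cancer tissue + healthy urine), the
training/validation cohort, and the independent test cohort are disjoint
sample sets; markers, imputation medians, CNV panel of normals, and model
fits are learned without any test-set sample.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cnv import estimate_tumor_fraction, log2_ratio_profile
from .concordance import summarize_concordance
from .ensemble import (
    compare_with_mutation,
    decision_curve,
    ensemble_score,
    roc_auc,
    select_best_subset,
    subset_search,
    threshold_at_specificity,
)
from .markers import select_markers, write_marker_bed
from .methylome import (
    build_amf_matrix,
    conversion_efficiency,
    global_methylation,
    read_bedgraph_counts,
    read_blacklist,
    tile_windows,
)
from .modeling import (
    CNV_GBT,
    METHYL_GBT,
    CVScheme,
    GBTConfig,
    HealthyMedianImputer,
    cv_model_scores,
    fit_final_models,
    make_folds,
)
from .simulate import SimCohort, SimParams, simulate_cohort, write_cohort

STAGES = (
    "simulate", "qc", "features", "markers", "concordance",
    "cnv", "train", "ensemble", "evaluate", "all",
)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class Thresholds:
    """Analysis constants; defaults are the study's stated values."""

    min_window_reads: int = 30
    conversion_min: float = 0.97
    fdr_max: float = 1e-5
    delta_min: float = 0.25
    min_healthy_support: int = 12
    min_cancer_support: int = 4
    target_specificity: float = 0.80
    # where the operating point is set: "train" (healthy training scores,
    # default) or "test" (healthy test scores, for reproduction studies)
    threshold_source: str = "train"


@dataclass
class PipelineConfig:
    out_dir: str = "uromethyl_out"
    sim: SimParams | None = field(default_factory=SimParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    cv: CVScheme = field(default_factory=CVScheme)
    gbt_methyl: GBTConfig = METHYL_GBT
    gbt_cnv: GBTConfig = CNV_GBT
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("sim") and "cohort_sizes" in d["sim"]:
            d["sim"]["cohort_sizes"] = {
                "/".join(k): v for k, v in d["sim"]["cohort_sizes"].items()
            }
        return d

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        cfg = cls()
        if "sim" in raw and raw["sim"] is not None:
            sim = raw["sim"]
            if "cohort_sizes" in sim:
                sim["cohort_sizes"] = {
                    tuple(k.split("/")): v for k, v in sim["cohort_sizes"].items()
                }
            if "tf_by_stage" in sim:
                sim["tf_by_stage"] = {k: tuple(v) for k, v in sim["tf_by_stage"].items()}
            cfg.sim = SimParams(**sim)
        if "thresholds" in raw:
            cfg.thresholds = Thresholds(**raw["thresholds"])
        if "cv" in raw:
            cfg.cv = CVScheme(**raw["cv"])
        if "gbt_methyl" in raw:
            cfg.gbt_methyl = GBTConfig(**raw["gbt_methyl"])
        if "gbt_cnv" in raw:
            cfg.gbt_cnv = GBTConfig(**raw["gbt_cnv"])
        for key in ("out_dir", "seed"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg


@dataclass
class AnalysisResult:
    amf: pd.DataFrame
    sample_features: pd.DataFrame  # per-sample gm/gm_score/tumor_fraction
    markers: pd.DataFrame
    concordance_summary: dict
    cv_search: pd.DataFrame
    best_subset: tuple
    evaluation: dict
    oof_scores: dict = field(repr=False, default_factory=dict)
    folds: list = field(repr=False, default_factory=list)
    state_hash: str = ""


def _labels(sheet: pd.DataFrame, ids) -> np.ndarray:
    cond = sheet.set_index("sample_id").loc[ids, "condition"]
    return (cond == "cancer").astype(int).to_numpy()


def _raw_feature_oof(values: np.ndarray, healthy_mask: np.ndarray, folds: list) -> np.ndarray:
    """Out-of-fold layout for a model-free scalar feature: the raw value,
    with missing entries imputed from the fold's healthy-train median."""
    n = len(values)
    oof = np.full((len(folds), n), np.nan)
    for r, fold_list in enumerate(folds):
        for tr, va in fold_list:
            imp = HealthyMedianImputer().fit(values[tr, None], healthy_mask[tr])
            oof[r, va] = imp.transform(values[va, None])[:, 0]
    return oof


def _state_fingerprint(markers: pd.DataFrame, medians: dict, preds: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(markers.index.to_numpy(dtype=np.int64)).tobytes())
    for name in sorted(medians):
        h.update(np.ascontiguousarray(np.asarray(medians[name], dtype=float)).tobytes())
    h.update(np.ascontiguousarray(np.round(preds, 12)).tobytes())
    return h.hexdigest()


def run_analysis(cohort: SimCohort, config: PipelineConfig | None = None) -> AnalysisResult:
    """Full study on an in-memory cohort: markers from the marker split,
    models by repeated CV on the training split, subset search, final
    retraining, and evaluation on the held-out test split."""
    config = config or PipelineConfig(sim=cohort.params)
    thr = config.thresholds
    sheet = cohort.sample_sheet
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids: marker/train/test splits must be disjoint")

    # --- feature extraction
    amf = cohort.amf_matrix(min_reads=thr.min_window_reads)
    gm_rows = {}
    for sid in amf.index:
        gm, gm_score = global_methylation(amf.loc[sid].to_numpy())
        gm_rows[sid] = {"global_methylation": gm, "gm_score": gm_score}
    feats = pd.DataFrame.from_dict(gm_rows, orient="index")

    # --- marker discovery (marker split only)
    tissue_ids = cohort.subset(split="marker", role="tissue", condition="cancer")
    healthy_marker_ids = cohort.subset(split="marker", role="urine", condition="healthy")
    markers_df = select_markers(
        amf.loc[tissue_ids],
        amf.loc[healthy_marker_ids],
        windows=cohort.windows,
        fdr_max=thr.fdr_max,
        delta_min=thr.delta_min,
        min_healthy=thr.min_healthy_support,
        min_cancer=thr.min_cancer_support,
    )
    marker_ids = markers_df.index

    # --- tissue-urine concordance on matched marker-split pairs
    conc_summary: dict = {}
    matched_urine = cohort.subset(split="marker", role="urine", condition="cancer")
    if matched_urine and tissue_ids:
        tis = sheet.set_index("sample_id").loc[tissue_ids, "patient_id"]
        uri = sheet.set_index("sample_id").loc[matched_urine, "patient_id"]
        pairs = [
            (t, u)
            for t, pt in tis.items()
            for u, pu in uri.items()
            if pt == pu
        ]
        if pairs:
            t_ids, u_ids = zip(*pairs)
            _, conc_summary = summarize_concordance(
                amf.loc[list(t_ids)],
                amf.loc[list(u_ids)],
                amf.loc[healthy_marker_ids],
                marker_ids=marker_ids,
            )

    # --- CNV profiles and tumor fractions (panel of normals = healthy training urine)
    pon_ids = cohort.subset(split="train", role="urine", condition="healthy")
    if not pon_ids:
        pon_ids = healthy_marker_ids
    pon = cohort.cnv_counts.loc[pon_ids].to_numpy()
    log2r = {}
    tf_hat = {}
    for sid in cohort.sample_ids:
        prof = log2_ratio_profile(cohort.cnv_counts.loc[sid].to_numpy(), pon)
        log2r[sid] = prof
        tf_hat[sid] = estimate_tumor_fraction(prof).tf
    log2r = pd.DataFrame.from_dict(log2r, orient="index", columns=cohort.cnv_bins.index)
    feats["tumor_fraction"] = pd.Series(tf_hat)

    # --- modality models under repeated CV (training split only)
    train_ids = cohort.subset(split="train")
    test_ids = cohort.subset(split="test")
    y_train = _labels(sheet, train_ids)
    y_test = _labels(sheet, test_ids)
    healthy_train = y_train == 0

    X_methyl_train = amf.loc[train_ids, marker_ids].to_numpy()
    X_cnv_train = log2r.loc[train_ids].to_numpy()
    scheme = dataclasses.replace(config.cv, seed=derive_seed(config.seed, "cv"))
    folds = make_folds(y_train, scheme)
    cv_methyl = cv_model_scores(
        X_methyl_train, y_train, healthy_train, scheme, config.gbt_methyl, folds=folds
    )
    cv_cnv = cv_model_scores(
        X_cnv_train, y_train, healthy_train, scheme, config.gbt_cnv, folds=folds
    )
    oof = {
        "methyl_score": cv_methyl.oof_scores,
        "cnv_score": cv_cnv.oof_scores,
        "gm_score": _raw_feature_oof(
            feats.loc[train_ids, "gm_score"].to_numpy(), healthy_train, folds
        ),
        "tumor_fraction": _raw_feature_oof(
            feats.loc[train_ids, "tumor_fraction"].to_numpy(), healthy_train, folds
        ),
    }

    # --- exhaustive subset search on out-of-fold scores
    search = subset_search(oof, y_train, folds)
    best = select_best_subset(search)

    # --- final models on the full training split, applied once to the test split
    final_seed = derive_seed(config.seed, "final")
    model_methyl = fit_final_models(
        X_methyl_train, y_train, healthy_train, config.gbt_methyl, seed=final_seed
    )
    model_cnv = fit_final_models(
        X_cnv_train, y_train, healthy_train, config.gbt_cnv, seed=final_seed + 1
    )

    def feature_table(ids) -> pd.DataFrame:
        tbl = pd.DataFrame(index=ids)
        tbl["methyl_score"] = model_methyl.predict_scores(amf.loc[ids, marker_ids].to_numpy())
        tbl["cnv_score"] = model_cnv.predict_scores(log2r.loc[ids].to_numpy())
        raw = feats.loc[ids, ["gm_score", "tumor_fraction"]].to_numpy()
        imp = HealthyMedianImputer().fit(
            feats.loc[train_ids, ["gm_score", "tumor_fraction"]].to_numpy(), healthy_train
        )
        tbl[["gm_score", "tumor_fraction"]] = imp.transform(raw)
        return tbl

    train_features = feature_table(train_ids)
    test_features = feature_table(test_ids)
    train_scores = ensemble_score(train_features, best)
    test_scores = ensemble_score(test_features, best)

    if thr.threshold_source == "test":
        threshold = threshold_at_specificity(
            np.asarray(test_scores)[y_test == 0], thr.target_specificity
        )
    else:
        threshold = threshold_at_specificity(
            np.asarray(train_scores)[healthy_train], thr.target_specificity
        )
    test_calls = np.asarray(test_scores) >= threshold
    auc, roc_points = roc_auc(test_scores, y_test)

    mutation = sheet.set_index("sample_id").loc[test_ids, "mutation_status"].to_numpy()
    comparison = compare_with_mutation(test_calls, mutation, y_test)
    dca = decision_curve(
        np.asarray(test_scores), y_test, pt_grid=np.round(np.arange(0.05, 0.95, 0.05), 3),
        or_calls=mutation == "positive",
    )

    evaluation = {
        "best_subset": list(best),
        "threshold": float(threshold),
        "test_auc": auc,
        "test": comparison["ensemble"],
        "mutation": comparison["mutation"],
        "combined_or": comparison["combined_or"],
        "n_markers": int(len(markers_df)),
        "n_hyper": int((markers_df["direction"] == "hyper").sum()),
        "n_hypo": int((markers_df["direction"] == "hypo").sum()),
        "concordance": conc_summary,
        "roc": roc_points,
        "decision_curve": dca,
        "test_scores": pd.Series(np.asarray(test_scores), index=test_ids),
        "train_scores": pd.Series(np.asarray(train_scores), index=train_ids),
    }

    state_hash = _state_fingerprint(
        markers_df,
        {
            "methyl": model_methyl.imputer.medians_,
            "cnv": model_cnv.imputer.medians_,
        },
        np.asarray(train_scores),
    )
    return AnalysisResult(
        amf=amf,
        sample_features=feats,
        markers=markers_df,
        concordance_summary=conc_summary,
        cv_search=search,
        best_subset=best,
        evaluation=evaluation,
        oof_scores=oof,
        folds=folds,
        state_hash=state_hash,
    )


# ---------------------------------------------------------------------------
# Disk-stage orchestration for the CLI


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{produced_by}' stage first"
        )
    return path


def _out(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_simulate(config: PipelineConfig) -> SimCohort:
    if config.sim is None:
        raise ValueError("config has no simulation parameters")
    params = dataclasses.replace(config.sim, seed=derive_seed(config.seed, "simulate"))
    cohort = simulate_cohort(params)
    write_cohort(cohort, _out(config) / "sim")
    return cohort


def _load_counts(config: PipelineConfig) -> tuple[pd.DataFrame, dict, Path]:
    out = _out(config)
    sim = out / "sim"
    sheet = pd.read_csv(_require(sim / "sample_sheet.tsv", "simulate"), sep="\t")
    tables = {
        sid: read_bedgraph_counts(sim / "counts" / f"{sid}.bedgraph.tsv")
        for sid in sheet["sample_id"]
    }
    return sheet, tables, sim


def stage_qc(config: PipelineConfig) -> pd.DataFrame:
    out = _out(config)
    chh = pd.read_csv(_require(out / "sim" / "chh_counts.tsv", "simulate"), sep="\t")
    rows = []
    for _, r in chh.iterrows():
        try:
            qc = conversion_efficiency(int(r["chh_converted"]), int(r["chh_total"]))
            rows.append(
                {"sample_id": r["sample_id"], "conversion_efficiency": qc.efficiency,
                 "pass": qc.passed}
            )
        except ValueError:
            rows.append(
                {"sample_id": r["sample_id"], "conversion_efficiency": float("nan"),
                 "pass": False}
            )
    qc_df = pd.DataFrame(rows)
    qc_df.to_csv(out / "qc.tsv", sep="\t", index=False)
    return qc_df


def stage_features(config: PipelineConfig) -> pd.DataFrame:
    out = _out(config)
    sheet, tables, sim = _load_counts(config)
    blacklist = None
    bl_path = sim / "blacklist.bed"
    if bl_path.exists() and bl_path.stat().st_size > 0:
        blacklist = read_blacklist(bl_path)
    lengths = {}
    for tbl in tables.values():
        for chrom, sub in tbl.groupby("chrom"):
            end = int(sub["end"].max())
            lengths[chrom] = max(lengths.get(chrom, 0), end)
    window_bp = config.sim.window_bp if config.sim else 300
    lengths = {c: int(np.ceil(l / window_bp) * window_bp) for c, l in lengths.items()}
    windows = tile_windows(lengths, window_bp, blacklist)
    amf = build_amf_matrix(tables, windows, min_reads=config.thresholds.min_window_reads)
    windows.to_csv(out / "windows.bed", sep="\t", header=False)
    amf.to_csv(out / "amf_matrix.tsv", sep="\t", float_format="%.6g")
    gm_rows = []
    for sid in amf.index:
        gm, score = global_methylation(amf.loc[sid].to_numpy())
        gm_rows.append({"sample_id": sid, "global_methylation": gm, "gm_score": score})
    pd.DataFrame(gm_rows).to_csv(out / "global_methylation.tsv", sep="\t", index=False)
    return amf


def _read_amf(out: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    amf = pd.read_csv(_require(out / "amf_matrix.tsv", "features"), sep="\t", index_col=0)
    amf.columns = amf.columns.astype(int)
    windows = pd.read_csv(
        _require(out / "windows.bed", "features"), sep="\t", header=None,
        names=["window_id", "chrom", "start", "end"], index_col=0,
    )
    return amf, windows


def stage_markers(config: PipelineConfig) -> pd.DataFrame:
    out = _out(config)
    amf, windows = _read_amf(out)
    sheet = pd.read_csv(_require(out / "sim" / "sample_sheet.tsv", "simulate"), sep="\t")
    thr = config.thresholds
    tissue = sheet.query("split == 'marker' and role == 'tissue' and condition == 'cancer'")
    healthy = sheet.query("split == 'marker' and role == 'urine' and condition == 'healthy'")
    markers_df = select_markers(
        amf.loc[tissue["sample_id"]],
        amf.loc[healthy["sample_id"]],
        windows=windows,
        fdr_max=thr.fdr_max,
        delta_min=thr.delta_min,
        min_healthy=thr.min_healthy_support,
        min_cancer=thr.min_cancer_support,
    )
    write_marker_bed(markers_df, out / "markers.bed")
    return markers_df


def stage_concordance(config: PipelineConfig) -> dict:
    from .markers import read_marker_bed

    out = _out(config)
    amf, _ = _read_amf(out)
    markers_df = read_marker_bed(_require(out / "markers.bed", "markers"))
    sheet = pd.read_csv(_require(out / "sim" / "sample_sheet.tsv", "simulate"), sep="\t")
    tissue = sheet.query("split == 'marker' and role == 'tissue' and condition == 'cancer'")
    urine = sheet.query("split == 'marker' and role == 'urine' and condition == 'cancer'")
    healthy = sheet.query("split == 'marker' and role == 'urine' and condition == 'healthy'")
    merged = tissue.merge(urine, on="patient_id", suffixes=("_t", "_u"))
    if len(merged) == 0:
        warnings.warn("no matched tissue-urine pairs; concordance skipped")
        return {}
    table, summary = summarize_concordance(
        amf.loc[merged["sample_id_t"]],
        amf.loc[merged["sample_id_u"]],
        amf.loc[healthy["sample_id"]],
        marker_ids=markers_df.index,
    )
    table.to_csv(out / "concordance.tsv", sep="\t")
    (out / "concordance_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def stage_cnv(config: PipelineConfig) -> pd.DataFrame:
    from .cnv import read_cnv_counts

    out = _out(config)
    sim = out / "sim"
    sheet = pd.read_csv(_require(sim / "sample_sheet.tsv", "simulate"), sep="\t")
    counts = {}
    bins = None
    for sid in sheet["sample_id"]:
        df = read_cnv_counts(_require(sim / "cnv" / f"{sid}.cnv.tsv", "simulate"))
        counts[sid] = df["read_count"].to_numpy()
        bins = df[["chrom", "start", "end"]]
    pon_sheet = sheet.query("split == 'train' and condition == 'healthy'")
    pon_ids = list(pon_sheet["sample_id"]) or list(
        sheet.query("condition == 'healthy'")["sample_id"]
    )
    pon = np.vstack([counts[s] for s in pon_ids])
    rows = []
    tf_rows = []
    for sid in sheet["sample_id"]:
        prof = log2_ratio_profile(counts[sid], pon)
        est = estimate_tumor_fraction(prof)
        tf_rows.append({"sample_id": sid, "tumor_fraction": est.tf})
        for i, r in enumerate(prof):
            rows.append(
                {"sample_id": sid, "chrom": bins.iloc[i]["chrom"],
                 "start": bins.iloc[i]["start"], "end": bins.iloc[i]["end"],
                 "log2_ratio": r, "fitted_state": int(est.states[i])}
            )
    pd.DataFrame(rows).to_csv(out / "cnv_profiles.tsv", sep="\t", index=False, float_format="%.6g")
    tf_df = pd.DataFrame(tf_rows)
    tf_df.to_csv(out / "tumor_fractions.tsv", sep="\t", index=False)
    return tf_df


def _analysis_from_disk(config: PipelineConfig) -> AnalysisResult:
    """Rebuild an in-memory cohort from the simulate-stage artifacts and run
    the modeling phases (used by the train/ensemble/evaluate disk stages)."""
    out = _out(config)
    _require(out / "sim" / "sample_sheet.tsv", "simulate")
    _require(out / "amf_matrix.tsv", "features")
    _require(out / "markers.bed", "markers")
    params = dataclasses.replace(config.sim, seed=derive_seed(config.seed, "simulate"))
    cohort = simulate_cohort(params)
    return run_analysis(cohort, config)


def stage_train_ensemble_evaluate(config: PipelineConfig) -> AnalysisResult:
    out = _out(config)
    result = _analysis_from_disk(config)
    cv_rows = []
    for _, row in result.cv_search.iterrows():
        for r, aucval in enumerate(row["repeat_aucs"]):
            cv_rows.append(
                {"subset": "+".join(row["subset"]), "repeat": r, "auc": aucval}
            )
    pd.DataFrame(cv_rows).to_csv(out / "cv_aucs.tsv", sep="\t", index=False, float_format="%.6g")
    search_out = result.cv_search.copy()
    search_out["subset"] = ["+".join(s) for s in search_out["subset"]]
    search_out["repeat_aucs"] = [
        ",".join(f"{a:.6g}" for a in v) for v in search_out["repeat_aucs"]
    ]
    search_out.to_csv(out / "subset_search.tsv", sep="\t", index=False, float_format="%.6g")

    ev = result.evaluation
    ev["roc"].to_csv(out / "roc.tsv", sep="\t", index=False, float_format="%.6g")
    ev["decision_curve"].to_csv(
        out / "decision_curve.tsv", sep="\t", index=False, float_format="%.6g"
    )
    serializable = {
        k: v for k, v in ev.items()
        if k not in ("roc", "decision_curve", "test_scores", "train_scores")
    }
    (out / "evaluation.json").write_text(json.dumps(serializable, indent=1, sort_keys=True))
    ev["test_scores"].rename("ensemble_score").to_csv(out / "test_scores.tsv", sep="\t")
    return result


def write_manifest(config: PipelineConfig, stages_run: list) -> Path:
    out = _out(config)
    cfg = config.to_dict()
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "package": "uromethyl",
        "version": __version__,
        "seed": config.seed,
        "stages": stages_run,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def run(stage: str, config: PipelineConfig):
    """Run one pipeline stage (or 'all'); returns the stage's main artifact."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    dispatch = {
        "simulate": stage_simulate,
        "qc": stage_qc,
        "features": stage_features,
        "markers": stage_markers,
        "concordance": stage_concordance,
        "cnv": stage_cnv,
        "train": stage_train_ensemble_evaluate,
        "ensemble": stage_train_ensemble_evaluate,
        "evaluate": stage_train_ensemble_evaluate,
    }
    if stage == "all":
        order = ["simulate", "qc", "features", "markers", "concordance", "cnv", "evaluate"]
        result = None
        for s in order:
            result = dispatch[s](config)
        write_manifest(config, order)
        return result
    result = dispatch[stage](config)
    write_manifest(config, [stage])
    return result
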