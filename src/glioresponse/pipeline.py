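"""End-to-end orchestration: cohort -> features/sources -> selection ->
classification -> vote fusion -> nosological maps.

Every run is driven by a :class:`RunConfig`; all randomness flows from its
seed through a named generator hierarchy so any stage is reproducible on
its own.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from glioresponse import __version__
from glioresponse.classify import cv_evaluate, svs_vote, train_linear, vvs_vote
from glioresponse.cnmf import (
    fit_convex_nmf,
    project,
    select_tumor_spectra,
    stack_spectra,
)
from glioresponse.datatypes import LABEL_CODE, SliceRecord
from glioresponse.nosomap import ScoreCalibration, build_map, render_map
from glioresponse.radiomics import feature_table as radiomic_feature_table
from glioresponse.selection import (
    FeatureTable,
    hybrid_embedded_then_wrapper,
    ttest_rank,
    wrapper_rfe,
)
from glioresponse.synthetic import CohortSpec, make_cohort, make_sources


@dataclass
class RunConfig:
    modality: str = "both"            # mri | mrsi | both
    model_type_mri: str = "LR"
    model_type_mrsi: str = "SVM"
    scheme_mri: str = "ttest"         # ttest | hybrid
    scheme_mrsi: str = "ttest"        # ttest | wrapper
    sweep_mri: int = 30               # subset sizes 1..30
    sweep_mrsi: int = 20              # subset sizes 1..20
    cv_mri: str | int = "loo"
    cv_mrsi: str | int = 20
    n_sources: int = 20
    paper_mode: bool = False          # fit cNMF on train+holdout jointly
    grouped_cv: bool = True
    seed: int = 0
    # synthetic cohort knobs (used by simulate/benchmark entry points)
    n_control: int = 29
    n_treated: int = 34
    grid_size: int = 10
    image_size: int = 128
    spectrum_length: int = 256
    n_true_sources: int = 3
    noise_sd: float = 0.02

    def sub_seed(self, name: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(h[:4], "big")

    def manifest(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        d["config_hash"] = hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return d


@dataclass
class SweepResult:
    """Accuracy trace over subset sizes, per-sample and per-subject."""

    sizes: list[int]
    cv_accuracy: dict[int, float]
    holdout_sample_accuracy: dict[int, float]
    holdout_subject_accuracy: dict[int, float]
    subsets: dict[int, list[str]]
    decisions: dict[int, list] = field(default_factory=dict)


def simulate_cohort(config: RunConfig):
    """Generate the synthetic cohort implied by the config."""
    sources = make_sources(
        config.n_true_sources, config.spectrum_length,
        seed=config.sub_seed("sources"),
    )
    spec = CohortSpec(
        n_control=config.n_control,
        n_treated=config.n_treated,
        grid_size=config.grid_size,
        image_size=config.image_size,
        spectrum_length=config.spectrum_length,
        noise_sd=config.noise_sd,
        seed=config.sub_seed("cohort"),
    )
    records, truth = make_cohort(spec, sources)
    return records, truth, sources


def _ranked_subsets(table: FeatureTable, scheme: str, model_type: str,
                    cv, m: int, seed: int, grouped: bool) -> dict[int, list[str]]:
    if scheme == "ttest":
        rank = ttest_rank(table)
        return {k: rank.features[:k] for k in range(1, m + 1)}
    if scheme == "wrapper":
        rank = wrapper_rfe(table, model_type, cv, seed, grouped)
        return {k: rank.subsets[k] for k in range(1, m + 1) if k in rank.subsets}
    if scheme == "hybrid":
        rank = hybrid_embedded_then_wrapper(
            table, model_type, k_folds=5, cv=cv, m=m, seed=seed, grouped=grouped
        )
        return {k: rank.subsets[k] for k in range(1, m + 1) if k in rank.subsets}
    raise ValueError(f"unknown selection scheme {scheme!r}")


def _sweep(train: FeatureTable, holdout: FeatureTable, holdout_meta: pd.DataFrame,
           subsets: dict[int, list[str]], model_type: str, cv, seed: int,
           grouped: bool, vote: str) -> SweepResult:
    """Evaluate every subset size: CV on train, per-sample + voted holdout."""
    sizes = sorted(subsets)
    cv_acc, samp_acc, subj_acc, decisions = {}, {}, {}, {}
    for m in sizes:
        feats = subsets[m]
        res = cv_evaluate(train.X[feats], train.labels, model_type, cv,
                          groups=train.subjects if grouped else None, seed=seed)
        cv_acc[m] = res.accuracy
        model = train_linear(train.X[feats], train.labels, model_type, seed)
        pred = model.predict(holdout.X[feats])
        samp_acc[m] = float(np.mean(pred == holdout.labels))
        decs, hits = [], []
        for sid in np.unique(holdout.subjects):
            rows = holdout.subjects == sid
            true = int(np.sign(holdout.labels[rows].mean()) or 1)
            if vote == "svs":
                w = holdout_meta.loc[rows, "mask_pixel_count"].to_numpy(float)
                dec = svs_vote((pred[rows] > 0).astype(float), w, subject_id=sid)
            else:
                dec = vvs_vote(pred[rows], subject_id=sid)
            decs.append(dec)
            hits.append(dec.label == true)
        subj_acc[m] = float(np.mean(hits))
        decisions[m] = decs
    return SweepResult(sizes, cv_acc, samp_acc, subj_acc, subsets, decisions)


def run_mri_pipeline(records: list[SliceRecord], config: RunConfig) -> dict:
    """Radiomics pipeline: 90-feature slice table -> selection sweep -> SVS."""
    df = radiomic_feature_table(records)
    meta_cols = ["subject_id", "slice_index", "label", "split", "mask_pixel_count"]
    feats = [c for c in df.columns if c not in meta_cols]
    y = df["label"].map(LABEL_CODE).to_numpy()
    tr = (df["split"] == "train").to_numpy()
    train = FeatureTable(df.loc[tr, feats], y[tr], df.loc[tr, "subject_id"].to_numpy())
    hold = FeatureTable(df.loc[~tr, feats], y[~tr], df.loc[~tr, "subject_id"].to_numpy())
    m = min(config.sweep_mri, len(feats))
    subsets = _ranked_subsets(train, config.scheme_mri, config.model_type_mri,
                              config.cv_mri, m, config.sub_seed("mri_select"),
                              config.grouped_cv)
    hold_meta = df.loc[~tr, ["mask_pixel_count"]].reset_index(drop=True)
    sweep = _sweep(train, hold, hold_meta,
                   subsets, config.model_type_mri, config.cv_mri,
                   config.sub_seed("mri_cv"), config.grouped_cv, vote="svs")
    return {"table": df, "sweep": sweep}


def _collect_spectra(records: list[SliceRecord]):
    mats, skipped = [], []
    for rec in records:
        if rec.grid is None:
            continue
        sm = select_tumor_spectra(rec)
        if sm.n == 0:
            skipped.append((rec.subject_id, rec.slice_index))
            continue
        mats.append(sm)
    return mats, skipped


def run_mrsi_pipeline(records: list[SliceRecord], config: RunConfig,
                      outdir: str | Path | None = None) -> dict:
    """MRSI pipeline: cNMF sources -> weight features -> sweep -> VVS + maps."""
    import warnings

    label_of = {r.subject_id: r.y for r in records}
    split_of = {r.subject_id: r.split for r in records}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        train_mats, _ = _collect_spectra([r for r in records if r.split == "train"])
        hold_mats, _ = _collect_spectra([r for r in records if r.split != "train"])
    train_sm = stack_spectra(train_mats)
    hold_sm = stack_spectra(hold_mats)

    K = min(config.n_sources, train_sm.n)
    fit_input = stack_spectra([train_sm, hold_sm]) if config.paper_mode else train_sm
    source_set = fit_convex_nmf(fit_input, K=K, seed=config.sub_seed("cnmf"))

    names = [f"source_{k:02d}" for k in range(K)]

    def as_table(sm):
        W = project(sm, source_set)
        X = pd.DataFrame(W, columns=names)
        subj = np.array([rid[0] for rid in sm.row_ids])
        y = np.array([label_of[s] for s in subj])
        return FeatureTable(X, y, subj)

    train = as_table(train_sm)
    hold = as_table(hold_sm)
    m = min(config.sweep_mrsi, K)
    subsets = _ranked_subsets(train, config.scheme_mrsi, config.model_type_mrsi,
                              config.cv_mrsi, m, config.sub_seed("mrsi_select"),
                              config.grouped_cv)
    meta = pd.DataFrame({"mask_pixel_count": np.ones(hold.X.shape[0])})
    sweep = _sweep(train, hold, meta, subsets, config.model_type_mrsi,
                   config.cv_mrsi, config.sub_seed("mrsi_cv"),
                   config.grouped_cv, vote="vvs")

    # pick the smallest subset size maximizing train CV accuracy for the maps
    best_m = min(sweep.sizes, key=lambda s: (-sweep.cv_accuracy[s], s))
    feats = subsets[best_m]
    cvres = cv_evaluate(train.X[feats], train.labels, config.model_type_mrsi,
                        config.cv_mrsi,
                        groups=train.subjects if config.grouped_cv else None,
                        seed=config.sub_seed("mrsi_cv"))
    calibration = ScoreCalibration.from_scores(cvres.scores, train.labels)
    model = train_linear(train.X[feats], train.labels, config.model_type_mrsi,
                         config.sub_seed("mrsi_cv"))
    hold_scores = model.decision_scores(hold.X[feats])
    maps = []
    rec_of = {(r.subject_id, r.slice_index): r for r in records}
    score_by_slice: dict[tuple[str, int], dict[tuple[int, int], float]] = {}
    for rid, s in zip(hold_sm.row_ids, hold_scores):
        sid, sl, r, c = rid
        score_by_slice.setdefault((sid, sl), {})[(r, c)] = float(s)
    for key, scores in sorted(score_by_slice.items()):
        nmap = build_map(rec_of[key], scores, calibration)
        maps.append(nmap)
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            render_map(nmap, rec_of[key].image,
                       outdir / f"map_{key[0]}_s{key[1]}.png")
    return {
        "source_set": source_set,
        "train_table": train,
        "holdout_table": hold,
        "sweep": sweep,
        "best_size": best_m,
        "calibration": calibration,
        "maps": maps,
        "split_of": split_of,
    }


def run_synthetic_benchmark(config: RunConfig,
                            outdir: str | Path | None = None) -> dict:
    """Generate a cohort, run both pipelines, emit a consolidated report."""
    records, truth, sources = simulate_cohort(config)
    report: dict = {"manifest": config.manifest()}
    if config.modality in ("mri", "both"):
        mri = run_mri_pipeline(records, config)
        sweep = mri["sweep"]
        report["mri"] = {
            "cv_accuracy": sweep.cv_accuracy,
            "holdout_slice_accuracy": sweep.holdout_sample_accuracy,
            "holdout_svs_accuracy": sweep.holdout_subject_accuracy,
        }
    if config.modality in ("mrsi", "both"):
        mrsi = run_mrsi_pipeline(records, config, outdir=outdir)
        sweep = mrsi["sweep"]
        report["mrsi"] = {
            "cv_accuracy": sweep.cv_accuracy,
            "holdout_voxel_accuracy": sweep.holdout_sample_accuracy,
            "holdout_vvs_accuracy": sweep.holdout_subject_accuracy,
            "best_size": mrsi["best_size"],
            "n_maps": len(mrsi["maps"]),
            "cnmf_final_error": mrsi["source_set"].final_error,
        }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
        lines = ["# Synthetic benchmark report", ""]
        for mod in ("mri", "mrsi"):
            if mod in report:
                lines.append(f"## {mod.upper()}")
                for k, v in report[mod].items():
                    lines.append(f"- {k}: {v}")
                lines.append("")
        (outdir / "report.md").write_text("\n".join(lines))
    return report
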