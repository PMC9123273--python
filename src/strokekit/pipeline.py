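"""End-to-end orchestration: phantoms → preprocessing → S1 → S2 → mapping.

``run_pipeline`` realizes the full two-stage workflow on a synthetic
cohort and writes every intermediate artifact (SegMaps, class
predictions, metric tables, lesion-distribution reports, and a combined
per-patient JSON report) under one output directory. A single global
seed is fanned out to each stage by hashing the stage name with the
seed, so stages are reproducible independently of one another. Any
stage failure raises :class:`StageError` naming the failing stage;
artifacts written before the failure are preserved.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort_accounting import (CohortManifest, ManifestRow,
                                chronological_split, summarize,
                                write_manifest, write_summary)
from .imageio import AugmentParams, write_mask
from .lesion_mapping import lesion_indices, render_report
from .losses import TverskyParams, FocalParams
from .metrics import (RankedPredictions, auroc, confusion_counts, dice, iou,
                      lesion_volume_ml, pixel_accuracy, segmentation_report)
from .phantom import (PhantomConfig, generate_atlas_phantom, simulate_cohort,
                      write_cases)
from .s1_segmenter import (S1Config, build_s1, predict_segmap, save_s1,
                           train_s1)
from .s2_classifier import (S2Config, predict_class, train_s2)
from .imageio import zscore_normalize

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "derive_seed",
           "load_pipeline_config"]

logger = logging.getLogger(__name__)


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of the stage name mixed with
    the global seed, reduced below 2**31."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """One declarative description of a full pipeline run."""

    output_dir: str
    n_patients: int = 64
    atlas_regions: int = 6
    dev_fraction: float = 0.8
    contrast: float = 5.0
    both_fraction: float = 0.0
    global_seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    s1: S1Config = field(default_factory=S1Config)
    s2: S2Config = field(default_factory=S2Config)
    tasks: tuple[str, ...] = ("size", "territory")

    def __post_init__(self):
        if self.n_patients < 8:
            raise ValueError("n_patients must be >= 8")
        if not 0.0 < self.dev_fraction < 1.0:
            raise ValueError("dev_fraction must lie in (0, 1)")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def load_pipeline_config(path) -> PipelineConfig:
    """Read a declarative YAML config into a PipelineConfig."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if "phantom" in raw:
        raw["phantom"] = PhantomConfig(**raw["phantom"])
    if "s1" in raw:
        s1 = dict(raw["s1"])
        if "loss" in s1:
            s1["loss"] = TverskyParams(**s1["loss"])
        if s1.get("augment_params") is not None and "augment_params" in s1:
            s1["augment_params"] = AugmentParams(**s1["augment_params"])
        raw["s1"] = S1Config(**s1)
    if "s2" in raw:
        s2 = dict(raw["s2"])
        if "loss" in s2:
            s2["loss"] = FocalParams(**s2["loss"])
        raw["s2"] = S2Config(**s2)
    if "tasks" in raw:
        raw["tasks"] = tuple(raw["tasks"])
    return PipelineConfig(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full two-stage workflow; returns a result summary dict.

    Writes under ``config.output_dir``: the phantom cohort with manifest,
    the cohort summary, trained S1 checkpoint, predicted SegMaps,
    segmentation metric tables, per-task classification tables, lesion
    mapping reports, and one combined per-patient ``report.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_log(out / "pipeline.log")
    logger.info("strokekit %s; global seed %d", __version__,
                config.global_seed)

    atlas, cases = _simulate(config, out)
    manifest, dev_ids, test_ids = _split(config, cases, out)
    cases = _preprocess(cases)
    by_id = {c.patient_id: c for c in cases}
    dev_cases = [by_id[i] for i in dev_ids]
    test_cases = [by_id[i] for i in test_ids]

    s1 = _train_s1_stage(config, dev_cases, out)
    segmaps, seg_df = _predict_s1_stage(config, s1, test_cases, out)
    class_results = _classify_stage(config, dev_cases, test_cases,
                                    segmaps, out)
    mapping = _mapping_stage(atlas, test_cases, segmaps, out)
    report = _combined_report(config, test_cases, segmaps, seg_df,
                              class_results, mapping, out)
    logger.info("pipeline complete: %s", out)
    return report


def _setup_log(path: Path) -> None:
    root = logging.getLogger("strokekit")
    root.setLevel(logging.INFO)
    if not any(isinstance(h, logging.FileHandler)
               and getattr(h, "baseFilename", "") == str(path)
               for h in root.handlers):
        root.addHandler(logging.FileHandler(path))


@_stage("simulate")
def _simulate(config: PipelineConfig, out: Path):
    phantom_cfg = dataclasses.replace(
        config.phantom, seed=derive_seed(config.global_seed, "simulate"))
    atlas = generate_atlas_phantom(phantom_cfg, config.atlas_regions)
    cases = simulate_cohort(config.n_patients, phantom_cfg, atlas,
                            seed=derive_seed(config.global_seed, "cohort"),
                            contrast=config.contrast,
                            both_fraction=config.both_fraction)
    write_cases(cases, out / "cohort")
    return atlas, cases


@_stage("split")
def _split(config: PipelineConfig, cases, out: Path):
    # phantoms carry no acquisition dates; assign one day per case in
    # generation order so the chronological rule is exercised end to end
    day0 = date(2020, 1, 1)
    rows = [ManifestRow(patient_id=c.patient_id,
                        acquisition_date=day0 + timedelta(days=i),
                        size_label=c.size_label,
                        territory_label=c.territory_label)
            for i, c in enumerate(cases)]
    manifest = CohortManifest(rows)
    dev_ids, test_ids = chronological_split(manifest, config.dev_fraction)
    write_manifest(manifest, out / "manifest.tsv")
    write_summary(summarize(manifest, (dev_ids, test_ids)),
                  out / "cohort_summary.tsv", out / "cohort_summary.json")
    logger.info("split: %d development / %d test", len(dev_ids),
                len(test_ids))
    return manifest, dev_ids, test_ids


@_stage("preprocess")
def _preprocess(cases):
    out = []
    for c in cases:
        out.append(dataclasses.replace(c, volume=zscore_normalize(c.volume)))
    return out


@_stage("train-s1")
def _train_s1_stage(config: PipelineConfig, dev_cases, out: Path):
    s1_cfg = dataclasses.replace(
        config.s1, seed=derive_seed(config.global_seed, "train-s1"))
    model = build_s1(s1_cfg)
    train_s1(model, dev_cases, s1_cfg)
    save_s1(model, out / "s1_model.npz")
    logger.info("S1 best validation Dice: %.3f", model.best_val_dice)
    return model


@_stage("predict-s1")
def _predict_s1_stage(config: PipelineConfig, s1, test_cases, out: Path):
    seg_dir = out / "segmaps"
    seg_dir.mkdir(exist_ok=True)
    segmaps, rows = {}, []
    for case in test_cases:
        pred = predict_segmap(s1, case.volume)
        segmaps[case.patient_id] = pred
        write_mask(pred, seg_dir / f"{case.patient_id}_segmap.nii.gz")
        row = {"patient_id": case.patient_id,
               "predicted_volume_ml": lesion_volume_ml(
                   int(pred.data.sum()), pred.spacing_mm)}
        try:
            row["dice"] = dice(pred, case.truth_mask)
            row["iou"] = iou(pred, case.truth_mask)
        except ValueError:  # empty prediction and truth
            row["dice"] = row["iou"] = 1.0
        row["pixel_accuracy"] = pixel_accuracy(
            confusion_counts(pred, case.truth_mask))
        rows.append(row)
    df = segmentation_report(rows, out_tsv=out / "segmentation_metrics.tsv",
                             out_json=out / "segmentation_metrics.json")
    return segmaps, df


@_stage("train-s2")
def _classify_stage(config: PipelineConfig, dev_cases, test_cases,
                    segmaps, out: Path):
    results = {}
    for task in config.tasks:
        s2_cfg = dataclasses.replace(
            config.s2, task=task,
            seed=derive_seed(config.global_seed, f"train-s2-{task}"))
        clf = train_s2(dev_cases, [c.truth_mask for c in dev_cases],
                       task, s2_cfg)
        preds, labels, probs = [], [], []
        for case in test_cases:
            pred = predict_class(clf, case.volume, segmaps[case.patient_id])
            truth = (case.size_label if task == "size"
                     else case.territory_label)
            preds.append({"patient_id": case.patient_id,
                          "probability": round(pred.probability, 6),
                          "predicted": pred.predicted_class,
                          "truth": truth,
                          "correct": int(pred.predicted_class == truth)})
            from .s2_classifier import POSITIVE_CLASS
            if truth != "both":
                labels.append(int(truth == POSITIVE_CLASS[task]))
                probs.append(pred.probability)
        import pandas as pd
        pd.DataFrame(preds).to_csv(out / f"classification_{task}.tsv",
                                   sep="\t", index=False)
        scored = [p for p in preds if p["truth"] != "both"]
        acc = (sum(p["correct"] for p in scored) / len(scored)
               if scored else float("nan"))
        try:
            auc = auroc(RankedPredictions(np.array(probs),
                                          np.array(labels)))
        except ValueError:
            auc = float("nan")
        results[task] = {"accuracy": acc, "auroc": auc,
                         "threshold": clf.threshold,
                         "n_excluded_both": clf.n_excluded_both,
                         "predictions": preds}
        logger.info("task %s: accuracy %.3f, AUROC %.3f, %d both-territory "
                    "excluded", task, acc, auc, clf.n_excluded_both)
    return results


@_stage("map-lesion")
def _mapping_stage(atlas, test_cases, segmaps, out: Path):
    reports = {}
    for case in test_cases:
        seg = segmaps[case.patient_id]
        if not seg.data.any():
            logger.info("mapping: %s has empty SegMap, skipped",
                        case.patient_id)
            continue
        rep = lesion_indices(seg, atlas)
        reports[case.patient_id] = rep
    (out / "lesion_mapping.json").write_text(
        render_report(list(reports.values()), format="json"))
    (out / "lesion_mapping.txt").write_text(
        render_report(list(reports.values()), format="text"))
    return reports


@_stage("report")
def _combined_report(config: PipelineConfig, test_cases, segmaps, seg_df,
                     class_results, mapping, out: Path) -> dict:
    per_patient = {}
    seg_rows = seg_df.set_index("patient_id").to_dict("index")
    for case in test_cases:
        pid = case.patient_id
        entry = {
            "labels": {"size": case.size_label,
                       "territory": case.territory_label},
            "segmentation": {k: round(float(v), 6)
                             for k, v in seg_rows[pid].items()},
        }
        for task, res in class_results.items():
            pred = next(p for p in res["predictions"]
                        if p["patient_id"] == pid)
            entry[f"classification_{task}"] = {
                k: v for k, v in pred.items() if k != "patient_id"}
        if pid in mapping:
            entry["lesion_mapping"] = mapping[pid].to_dict()
        per_patient[pid] = entry
    report = {
        "version": __version__,
        "global_seed": config.global_seed,
        "n_patients": config.n_patients,
        "summary": {
            "segmentation_macro_dice": round(float(
                seg_df[seg_df.patient_id == "MACRO_AVERAGE"]["dice"]
                .iloc[0]), 6),
            **{f"{task}_accuracy": round(res["accuracy"], 6)
               for task, res in class_results.items()},
            **{f"{task}_auroc": round(res["auroc"], 6)
               for task, res in class_results.items()},
        },
        "patients": per_patient,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
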