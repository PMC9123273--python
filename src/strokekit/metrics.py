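"""Evaluation metrics.

Segmentation is scored on a pixel basis (confusion counts, pixel accuracy,
IoU, Dice) per patient volume; classification is scored on a patient basis
(AUROC, AUPRC) with the decision threshold chosen by Youden's index.
Voxel counts convert to millilitres through the voxel volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "RankedPredictions",
    "confusion_counts",
    "dice",
    "iou",
    "pixel_accuracy",
    "auroc",
    "auprc",
    "youden_threshold",
    "lesion_volume_ml",
    "segmentation_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class RankedPredictions:
    """Per-patient scores in [0, 1] paired with binary labels."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1D arrays")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be binary")

    def require_both_classes(self):
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present")


def _as_binary(mask) -> np.ndarray:
    data = mask.data if hasattr(mask, "data") else np.asarray(mask)
    return np.asarray(data).astype(bool)


def _check_grids(pred, truth):
    a, b = _as_binary(pred), _as_binary(truth)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if hasattr(pred, "same_grid") and hasattr(truth, "spacing_mm"):
        if not pred.same_grid(truth):
            raise ValueError("grid mismatch: spacing or affine differ")
    return a, b


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Voxelwise TP/FP/TN/FN; the four counts partition the grid."""
    a, b = _check_grids(pred, truth)
    tp = int(np.sum(a & b))
    fp = int(np.sum(a & ~b))
    fn = int(np.sum(~a & b))
    tn = int(a.size - tp - fp - fn)
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def dice(pred, truth) -> float:
    """Dice = 2|A∩B| / (|A|+|B|)."""
    a, b = _check_grids(pred, truth)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        raise ValueError("Dice undefined: both masks empty")
    return 2.0 * float(np.sum(a & b)) / (sa + sb)


def iou(pred, truth) -> float:
    """Intersection over union |A∩B| / |A∪B|."""
    a, b = _check_grids(pred, truth)
    union = int(np.sum(a | b))
    if union == 0:
        raise ValueError("IoU undefined: both masks empty")
    return float(np.sum(a & b)) / union


def pixel_accuracy(counts: ConfusionCounts) -> float:
    """(TP+TN) / all pixels."""
    if counts.total == 0:
        raise ValueError("no pixels")
    return (counts.TP + counts.TN) / counts.total


def auroc(preds: RankedPredictions) -> float:
    """Area under the ROC curve == Mann-Whitney concordance probability."""
    preds.require_both_classes()
    return float(roc_auc_score(preds.labels, preds.scores))


def auprc(preds: RankedPredictions) -> float:
    """Area under the precision-recall curve as step-wise average precision."""
    preds.require_both_classes()
    return float(average_precision_score(preds.labels, preds.scores))


def youden_threshold(preds: RankedPredictions) -> tuple[float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are the unique score values; the prediction rule is
    ``score >= threshold``. Ties in J resolve to the smallest threshold.
    """
    preds.require_both_classes()
    labels = preds.labels
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    best_thr, best_j = None, -np.inf
    for thr in np.unique(preds.scores):
        called_pos = preds.scores >= thr
        sens = np.sum(called_pos & (labels == 1)) / n_pos
        spec = np.sum(~called_pos & (labels == 0)) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_thr = j, float(thr)
    return best_thr, float(best_j)


def lesion_volume_ml(n_voxels: int, spacing_mm) -> float:
    """Voxel count to millilitres: n * prod(spacing) / 1000, 2 dp."""
    if n_voxels < 0:
        raise ValueError("voxel count must be non-negative")
    vol = n_voxels * float(np.prod(np.asarray(spacing_mm, dtype=float))) / 1000.0
    return round(vol, 2)


def segmentation_report(rows: list[dict], out_tsv=None, out_json=None) -> pd.DataFrame:
    """Assemble per-patient metric rows plus a macro-average aggregate row.

    ``rows`` are dicts with at least ``patient_id`` and numeric metric
    columns (dice, iou, pixel_accuracy, ...). The aggregate row is the
    unweighted mean over patients.
    """
    df = pd.DataFrame(rows)
    numeric = df.select_dtypes("number").columns
    agg = {c: df[c].mean() for c in numeric}
    agg["patient_id"] = "MACRO_AVERAGE"
    out = pd.concat([df, pd.DataFrame([agg])], ignore_index=True)
    if out_tsv is not None:
        out.to_csv(out_tsv, sep="\t", index=False, float_format="%.6f")
    if out_json is not None:
        with open(out_json, "w") as fh:
            json.dump(out.to_dict(orient="records"), fh, indent=2, default=float)
    return out
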