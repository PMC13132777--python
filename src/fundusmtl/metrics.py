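"""Evaluation metrics for vessel segmentation and multi-label classification.

Segmentation is scored per image with Dice, pixel accuracy and pixel ROC-AUC;
classification per disease category with precision, recall, F1, specificity
and ROC-AUC, plus subset accuracy (the fraction of samples whose whole
predicted label vector is exact) and the unweighted mean of per-class AUCs.

ROC-AUC is computed as the Mann-Whitney U statistic with half credit for
ties, which equals the trapezoidal area under the ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "dice_coefficient",
           "roc_auc", "classification_report", "segmentation_report"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Container for per-task metrics; serializes with :meth:`to_dict`."""

    segmentation: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return asdict(self)


def _require_binary(arr: np.ndarray, name: str):
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")


def confusion(pred_binary, truth_binary) -> ConfusionCounts:
    """Exhaustive TP/FP/FN/TN counts over two equal-shaped binary arrays."""
    pred = np.asarray(pred_binary)
    truth = np.asarray(truth_binary)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    _require_binary(pred, "pred")
    _require_binary(truth, "truth")
    p = pred.astype(bool).ravel()
    t = truth.astype(bool).ravel()
    return ConfusionCounts(tp=int((p & t).sum()), fp=int((p & ~t).sum()),
                           fn=int((~p & t).sum()), tn=int((~p & ~t).sum()))


def dice_coefficient(counts: ConfusionCounts) -> float:
    """Overlap 2*TP / (2*TP + FP + FN); defined as 1 when all three are 0."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        warnings.warn("dice undefined (no positives in either mask); "
                      "returning 1.0", stacklevel=2)
        return 1.0
    return 2.0 * counts.tp / denom


def _precision(c: ConfusionCounts) -> float:
    if c.tp + c.fp == 0:
        warnings.warn("precision undefined (no positive predictions); "
                      "returning 0.0", stacklevel=3)
        return 0.0
    return c.tp / (c.tp + c.fp)


def _recall(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0


def _specificity(c: ConfusionCounts) -> float:
    return c.tn / (c.tn + c.fp) if c.tn + c.fp else 0.0


def _f1(precision: float, recall: float) -> float:
    return (2 * precision * recall / (precision + recall)
            if precision + recall else 0.0)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) statistic.

    Ties receive half credit, matching the trapezoidal ROC area.  Raises if
    only one class is present.
    """
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel()
    _require_binary(y, "labels")
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(s)                      # average ranks handle ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def classification_report(prob_matrix, target_matrix,
                          threshold: float = 0.5) -> MetricsReport:
    """Per-class and macro metrics for multi-label classification.

    Probabilities are binarized at ``threshold``; per-class AUCs use the raw
    scores.  Classes absent from (or fully saturating) the targets have an
    undefined AUC and are excluded from ``mean_auc`` with a warning.
    """
    probs = np.atleast_2d(np.asarray(prob_matrix, dtype=np.float64))
    targets = np.atleast_2d(np.asarray(target_matrix))
    if probs.shape != targets.shape:
        raise ValueError(f"shape mismatch {probs.shape} vs {targets.shape}")
    _require_binary(targets, "targets")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    preds = (probs >= threshold).astype(int)
    n, c = targets.shape
    per_class = []
    aucs = []
    for j in range(c):
        cc = confusion(preds[:, j], targets[:, j])
        prec, rec = _precision(cc), _recall(cc)
        entry = {"precision": prec, "recall": rec, "f1": _f1(prec, rec),
                 "specificity": _specificity(cc)}
        n_pos = int(targets[:, j].sum())
        if 0 < n_pos < n:
            entry["auc"] = roc_auc(probs[:, j], targets[:, j])
            aucs.append(entry["auc"])
        else:
            warnings.warn(f"class {j} has a single-class target column; "
                          "AUC undefined and excluded from mean_auc",
                          stacklevel=2)
            entry["auc"] = None
        per_class.append(entry)
    macro = {f"macro_{k}": float(np.mean([e[k] for e in per_class]))
             for k in ("precision", "recall", "f1", "specificity")}
    macro["subset_accuracy"] = float((preds == targets).all(axis=1).mean())
    macro["mean_auc"] = float(np.mean(aucs)) if aucs else None
    return MetricsReport(classification={"per_class": per_class, **macro},
                         threshold=threshold)


def segmentation_report(pred_prob_maps, truth_masks, threshold: float = 0.5,
                        aggregate: str = "per_image",
                        fov_masks=None) -> MetricsReport:
    """Dice / accuracy / AUC for a collection of probability maps.

    ``aggregate='per_image'`` scores each image and averages (the default);
    ``'pooled'`` pools all pixels first.  ``fov_masks`` optionally restricts
    scoring to a field-of-view region per image.
    """
    preds = [np.asarray(p, dtype=np.float64) for p in pred_prob_maps]
    truths = [np.asarray(t) for t in truth_masks]
    if len(preds) == 0:
        raise ValueError("empty collection")
    if len(preds) != len(truths):
        raise ValueError("pred/truth collections differ in length")
    if aggregate not in ("per_image", "pooled"):
        raise ValueError("aggregate must be 'per_image' or 'pooled'")
    flat_p, flat_t = [], []
    for i, (p, t) in enumerate(zip(preds, truths)):
        if p.shape != t.shape:
            raise ValueError(f"image {i}: shape mismatch {p.shape} vs {t.shape}")
        _require_binary(t, "truth mask")
        if fov_masks is not None:
            keep = np.asarray(fov_masks[i]).astype(bool).ravel()
            flat_p.append(p.ravel()[keep])
            flat_t.append(t.ravel()[keep])
        else:
            flat_p.append(p.ravel())
            flat_t.append(t.ravel())
    if aggregate == "pooled":
        flat_p = [np.concatenate(flat_p)]
        flat_t = [np.concatenate(flat_t)]
    dices, accs, aucs = [], [], []
    for p, t in zip(flat_p, flat_t):
        cc = confusion((p >= threshold).astype(int), t)
        dices.append(dice_coefficient(cc))
        accs.append((cc.tp + cc.tn) / cc.total)
        if 0 < t.sum() < t.size:
            aucs.append(roc_auc(p, t))
    seg = {"dice": float(np.mean(dices)), "accuracy": float(np.mean(accs)),
           "auc": float(np.mean(aucs)) if aucs else None}
    return MetricsReport(segmentation=seg, threshold=threshold)
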