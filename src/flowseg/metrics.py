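"""Segmentation evaluation: object-level F-score and pixel-level Jaccard.

Detection accuracy is scored object-by-object: predicted and ground-truth
regions are matched one-to-one greedily in descending IoU order, a match
counting as a true positive when its IoU reaches the match threshold
(default 0.5). F1 = TP / (TP + (FN + FP)/2). Segmentation accuracy is the
pixel-level Jaccard index J(T, S) = |T n S| / |T u S|. Across a data set,
counts are pooled (micro-averaged) before scoring.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import ValidationError
from .segment import BinaryMask, LabeledMask

__all__ = [
    "EvalResult",
    "match_objects",
    "f1_score",
    "jaccard_index",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class EvalResult:
    """Pooled detection counts and scores for one prediction/truth data set."""

    tp: int
    fp: int
    fn: int
    f1: float
    jaccard: float
    iou_match_threshold: float = 0.5

    def summary(self) -> str:
        return (
            f"TP={self.tp} FP={self.fp} FN={self.fn}  "
            f"F1={self.f1:.4f}  Jaccard={self.jaccard:.4f}  "
            f"(IoU match >= {self.iou_match_threshold})"
        )

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "f1": self.f1,
            "jaccard": self.jaccard,
            "iou_match_threshold": self.iou_match_threshold,
        }


def _pairwise_iou(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """IoU matrix between labels of two label images (rows: pred)."""
    np_, nt = int(pred.max()), int(truth.max())
    if np_ == 0 or nt == 0:
        return np.zeros((np_, nt))
    # joint histogram of (pred label, truth label) gives all intersections
    joint = np.bincount(
        (pred.astype(np.int64) * (nt + 1) + truth.astype(np.int64)).ravel(),
        minlength=(np_ + 1) * (nt + 1),
    ).reshape(np_ + 1, nt + 1)
    inter = joint[1:, 1:].astype(np.float64)
    pred_areas = np.bincount(pred.ravel(), minlength=np_ + 1)[1:]
    truth_areas = np.bincount(truth.ravel(), minlength=nt + 1)[1:]
    union = pred_areas[:, None] + truth_areas[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def match_objects(
    pred: LabeledMask, truth: LabeledMask, iou_match_threshold: float = 0.5
) -> tuple[int, int, int]:
    """Greedy one-to-one object matching; returns (tp, fp, fn).

    Candidate pairs are taken in descending IoU order; a pair whose IoU is
    at least the threshold is a true positive. Leftover predictions are
    false positives, leftover truth objects false negatives.
    """
    if pred.shape != truth.shape:
        raise ValidationError("prediction and truth dimensions differ")
    if not 0 < iou_match_threshold <= 1:
        raise ValidationError("iou_match_threshold must be in (0, 1]")
    iou = _pairwise_iou(pred.labels, truth.labels)
    n_pred, n_truth = iou.shape
    tp = 0
    used_p: set[int] = set()
    used_t: set[int] = set()
    order = np.argsort(iou, axis=None)[::-1]
    for flat in order:
        i, j = divmod(int(flat), n_truth) if n_truth else (0, 0)
        if iou.size == 0 or iou[i, j] < iou_match_threshold:
            break
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        tp += 1
    fp = n_pred - tp
    fn = n_truth - tp
    return tp, fp, fn


def f1_score(tp: int, fp: int, fn: int) -> float:
    """F1 = TP / (TP + (FN + FP)/2); a perfectly empty scene scores 1."""
    if min(tp, fp, fn) < 0:
        raise ValidationError("counts must be nonnegative")
    denom = tp + 0.5 * (fn + fp)
    if denom == 0:
        return 1.0
    return tp / denom


def jaccard_index(truth: BinaryMask, pred: BinaryMask) -> float:
    """Pixel Jaccard |T n S| / |T u S|; two empty masks score 1."""
    if truth.shape != pred.shape:
        raise ValidationError("mask dimensions differ")
    t = truth.pixels
    s = pred.pixels
    union = np.logical_or(t, s).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(t, s).sum() / union)


def evaluate_dataset(
    preds: list[LabeledMask],
    truths: list[LabeledMask],
    iou_match_threshold: float = 0.5,
) -> EvalResult:
    """Micro-averaged evaluation over paired prediction/truth images.

    TP/FP/FN are summed across images before applying the F-score, and the
    Jaccard index is computed on pooled pixel counts (global intersection
    over global union), so images with few cells are not over-weighted.
    """
    if len(preds) == 0 or len(preds) != len(truths):
        raise ValidationError("need equal-length, nonempty prediction/truth lists")
    tp = fp = fn = 0
    inter = union = 0
    for p, t in zip(preds, truths):
        if p.shape != t.shape:
            raise ValidationError("image dimensions differ within the data set")
        a, b, c = match_objects(p, t, iou_match_threshold)
        tp, fp, fn = tp + a, fp + b, fn + c
        pm = p.labels > 0
        tm = t.labels > 0
        inter += int(np.logical_and(pm, tm).sum())
        union += int(np.logical_or(pm, tm).sum())
    jac = 1.0 if union == 0 else inter / union
    return EvalResult(
        tp=tp, fp=fp, fn=fn,
        f1=f1_score(tp, fp, fn),
        jaccard=jac,
        iou_match_threshold=iou_match_threshold,
    )
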