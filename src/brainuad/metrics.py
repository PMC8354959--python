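"""Segmentation and detection metrics: Dice, precision-recall / AUPRC, slice labels.

Two Dice flavours are reported, following common practice in anomaly
segmentation benchmarks:

* dataset Dice (DICE_D): all voxels of all subjects pooled into one pair of
  sets before applying 2|X∩Y| / (|X|+|Y|);
* subject Dice (DICE_S): the per-subject score, summarized as mean ± std
  (population std) over subjects.

AUPRC uses step-wise average precision, sum (R_k - R_{k-1}) * P_k with
thresholds swept over the unique scores in descending order — no trapezoidal
interpolation, which is optimistic in PR space.  All reported metrics are in
percent.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np


class MetricError(ValueError):
    pass


@dataclass
class MetricsReport:
    dice_dataset: float
    dice_subject_mean: float
    dice_subject_std: float
    auprc_voxel: float
    n_subjects: int
    auprc_slice: float | None = None

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def _as_binary(arr, name):
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1, True, False))):
        raise MetricError(f"{name} must be binary, found values {vals[:5]}")
    return arr.astype(bool)


def dice(pred, truth) -> float:
    """Dice coefficient 2|X∩Y| / (|X|+|Y|); both sets empty -> 1.0."""
    pred = _as_binary(pred, "pred")
    truth = _as_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise MetricError(f"shape mismatch {pred.shape} vs {truth.shape}")
    denom = int(pred.sum()) + int(truth.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(pred, truth).sum()) / denom


def dice_dataset(preds, truths) -> float:
    """Dataset-level Dice in percent: voxels pooled over all subjects."""
    preds, truths = list(preds), list(truths)
    if len(preds) == 0 or len(preds) != len(truths):
        raise MetricError("need equally many, and at least one, pred/truth pairs")
    inter = px = tx = 0
    for p, t in zip(preds, truths):
        p = _as_binary(p, "pred")
        t = _as_binary(t, "truth")
        if p.shape != t.shape:
            raise MetricError("pred/truth shape mismatch")
        inter += int(np.logical_and(p, t).sum())
        px += int(p.sum())
        tx += int(t.sum())
    if px + tx == 0:
        return 100.0
    return 100.0 * 2.0 * inter / (px + tx)


def dice_subjects(preds, truths):
    """Per-subject Dice in percent: (mean, population std, per-subject list)."""
    preds, truths = list(preds), list(truths)
    if len(preds) == 0 or len(preds) != len(truths):
        raise MetricError("need equally many, and at least one, pred/truth pairs")
    scores = [100.0 * dice(p, t) for p, t in zip(preds, truths)]
    return float(np.mean(scores)), float(np.std(scores)), scores


def pr_curve(scores, labels):
    """Precision-recall points, thresholds swept over unique scores descending.

    Returns (recall, precision) arrays; point k corresponds to predicting
    positive for scores >= the k-th largest unique score.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = _as_binary(np.asarray(labels).ravel(), "labels")
    if scores.shape != labels.shape:
        raise MetricError("scores and labels must align")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise MetricError("PR curve undefined without positive labels")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order].astype(np.int64)
    tp = np.cumsum(l)
    fp = np.cumsum(1 - l)
    # keep only the last index of each tied score block (threshold = that score)
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, s.size - 1]
    precision = tp[idx] / (tp[idx] + fp[idx])
    recall = tp[idx] / n_pos
    return recall, precision


def auprc(curve_or_scores, labels=None) -> float:
    """Area under the PR curve in percent (step-wise average precision)."""
    if labels is not None:
        recall, precision = pr_curve(curve_or_scores, labels)
    else:
        recall, precision = curve_or_scores
    recall = np.asarray(recall, dtype=np.float64)
    precision = np.asarray(precision, dtype=np.float64)
    prev = np.r_[0.0, recall[:-1]]
    return float(100.0 * np.sum((recall - prev) * precision))


def label_slices(annotation, axis: int = 2) -> np.ndarray:
    """Per-axial-slice binary labels: 1 iff the slice has any annotated voxel."""
    annotation = _as_binary(annotation, "annotation")
    reduce_axes = tuple(a for a in range(annotation.ndim) if a != axis)
    return annotation.any(axis=reduce_axes).astype(np.uint8)


def score_slices(x, x_hat, mask, axis: int = 2) -> np.ndarray:
    """Per-axial-slice anomaly score: mean |x - x_hat| over in-mask pixels.

    Slices without mask pixels score 0.
    """
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if not (x.shape == x_hat.shape == mask.shape):
        raise MetricError("x, x_hat and mask must share one shape")
    resid = np.abs(x - x_hat) * mask
    reduce_axes = tuple(a for a in range(x.ndim) if a != axis)
    num = resid.sum(axis=reduce_axes)
    den = mask.sum(axis=reduce_axes)
    return np.where(den > 0, num / np.maximum(den, 1), 0.0)


def relative_improvement(baseline: float, improved: float) -> float:
    """Relative change in percent, 100*(improved-baseline)/baseline, 2 decimals."""
    if baseline <= 0:
        raise MetricError("baseline must be positive")
    return round(100.0 * (improved - baseline) / baseline, 2)


def evaluate_segmentation(preds, truths, residuals=None,
                          slice_scores=None, slice_labels=None) -> MetricsReport:
    """Assemble a MetricsReport from aligned per-subject arrays.

    residuals (post-processed) are pooled across subjects for the voxel AUPRC;
    optional pooled slice scores/labels give the slice-wise detection AUPRC.
    """
    d_d = dice_dataset(preds, truths)
    mean_s, std_s, _ = dice_subjects(preds, truths)
    a_vox = float("nan")
    if residuals is not None:
        flat_scores = np.concatenate([np.asarray(r).ravel() for r in residuals])
        flat_labels = np.concatenate(
            [np.asarray(t).ravel().astype(bool) for t in truths]
        )
        a_vox = auprc(flat_scores, flat_labels)
    a_slice = None
    if slice_scores is not None and slice_labels is not None:
        a_slice = auprc(np.asarray(slice_scores).ravel(),
                        np.asarray(slice_labels).ravel())
    return MetricsReport(
        dice_dataset=d_d,
        dice_subject_mean=mean_s,
        dice_subject_std=std_s,
        auprc_voxel=a_vox,
        n_subjects=len(list(preds)),
        auprc_slice=a_slice,
    )
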