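"""Segmentation evaluation and annotation-consistency statistics.

Per-class agreement is measured by IoU (Jaccard) and F1 (Dice); the two are
linked by F1 = 2*IoU / (1 + IoU) for any binary pair. Inter-observer
consistency between two annotations combines IoU, the absolute difference
in positive-pixel totals, and the surface ratio
``1 - min(sum_A, sum_B) / max(sum_A, sum_B)``. Repeat-scan reproducibility
of a volume measurement is summarised by the coefficient of variation
(sample standard deviation over mean, in percent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import BinaryMask, LabelStack
from .postprocess import PostprocessParams, clean_binary_mask

__all__ = [
    "EvaluationResult",
    "InterObserverResult",
    "iou",
    "f1",
    "interobserver",
    "coefficient_of_variation",
    "evaluate_stack",
]


def _binarize(mask) -> np.ndarray:
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask)
    return data.astype(bool)


def _check_shapes(a: np.ndarray, b: np.ndarray):
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def iou(pred, gt) -> float:
    """Intersection over union; two empty masks agree perfectly (1.0)."""
    p, g = _binarize(pred), _binarize(gt)
    _check_shapes(p, g)
    union = np.logical_or(p, g).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, g).sum() / union)


def f1(pred, gt) -> float:
    """Dice / F1 score 2TP / (2TP + FP + FN); two empty masks give 1.0."""
    p, g = _binarize(pred), _binarize(gt)
    _check_shapes(p, g)
    tp = np.logical_and(p, g).sum()
    denom = p.sum() + g.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * tp / denom)


@dataclass(frozen=True)
class InterObserverResult:
    iou: float
    pixel_difference: int
    surface_ratio: float


def interobserver(mask_a, mask_b) -> InterObserverResult:
    """Agreement between two annotations of the same slice or stack."""
    a, b = _binarize(mask_a), _binarize(mask_b)
    _check_shapes(a, b)
    sa, sb = int(a.sum()), int(b.sum())
    if max(sa, sb) == 0:
        ratio = 0.0
    else:
        ratio = 1.0 - min(sa, sb) / max(sa, sb)
    return InterObserverResult(
        iou=iou(a, b), pixel_difference=abs(sa - sb), surface_ratio=ratio
    )


def coefficient_of_variation(values) -> float:
    """Sample-sd coefficient of variation of repeat measurements, in percent."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("mean must be positive")
    return float(100.0 * v.std(ddof=1) / mean)


@dataclass(frozen=True)
class ClassStats:
    """Per-slice aggregate for one class; None when the class never occurs."""

    mean_iou: float | None
    sd_iou: float | None
    mean_f1: float | None
    sd_f1: float | None
    n_slices: int


@dataclass(frozen=True)
class EvaluationResult:
    lung: ClassStats
    metastasis: ClassStats
    per_slice: dict  # class name -> list of (z, iou, f1)

    def to_dict(self) -> dict:
        def enc(s: ClassStats):
            return {
                "mean_iou": s.mean_iou, "sd_iou": s.sd_iou,
                "mean_f1": s.mean_f1, "sd_f1": s.sd_f1, "n_slices": s.n_slices,
            }

        return {"lung": enc(self.lung), "metastasis": enc(self.metastasis)}


def _class_stats(pred3d, gt3d, cls, min_blob, closing_kernel):
    values = []
    for z in range(gt3d.shape[0]):
        p = clean_binary_mask(
            BinaryMask((pred3d[z] == cls).astype(np.uint8)),
            min_blob, closing_kernel, apply_closing=False,
        ).data
        g = clean_binary_mask(
            BinaryMask((gt3d[z] == cls).astype(np.uint8)),
            min_blob, closing_kernel, apply_closing=False,
        ).data
        if p.sum() == 0 and g.sum() == 0:
            continue  # class absent from both: excluded from aggregates
        values.append((z, iou(p, g), f1(p, g)))
    if not values:
        return ClassStats(None, None, None, None, 0), values
    ious = np.array([v[1] for v in values])
    f1s = np.array([v[2] for v in values])
    sd = (lambda a: float(a.std(ddof=1)) if a.size > 1 else 0.0)
    return (
        ClassStats(float(ious.mean()), sd(ious), float(f1s.mean()), sd(f1s), len(values)),
        values,
    )


def evaluate_stack(
    pred: LabelStack,
    gt: LabelStack,
    params: PostprocessParams = PostprocessParams(),
) -> EvaluationResult:
    """Per-class slice-level IoU/F1 between a prediction and ground truth.

    Small blobs are removed from *both* masks with the same per-class
    thresholds before scoring, so unreviewable specks do not bias the
    statistics. Aggregates are means +/- sd over slices where the class
    occurs in either mask; a class occurring in neither is reported as
    missing (``None`` fields), matching the NA convention for metastasis
    scores on control animals.
    """
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    per_slice = {}
    lung_stats, per_slice["lung"] = _class_stats(
        pred.data, gt.data, 1, params.min_blob_lung, params.closing_kernel
    )
    met_stats, per_slice["metastasis"] = _class_stats(
        pred.data, gt.data, 2, params.min_blob_met, params.closing_kernel
    )
    return EvaluationResult(lung=lung_stats, metastasis=met_stats, per_slice=per_slice)
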