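"""Four-step clean-up of raw network predictions.

1. Slices without mouse tissue are identified by scanning from both stack
   ends with a Laplacian-of-Gaussian filter (sigma = 7 px); a slice counts
   as tissue iff the mean absolute scale-normalised LoG response on the
   0-255 intensity scale is >= 1. Masks of non-tissue slices are blanked.
2. The multiclass mask is split into lung and metastasis binary masks.
3. Per slice, blobs smaller than 10 px (lungs) / 3 px (metastases) are
   removed (strict inequality, 8-connectivity), then a 3x3 morphological
   closing bridges 1-px gaps.
4. The two binary masks are recombined into a multiclass mask, metastasis
   taking precedence over lung.

The LoG response is scale-normalised (multiplied by sigma^2, the standard
blob-detection convention); without this the zero-sum kernel's response at
sigma = 7 would be far below 1 for any realistic slice and the threshold
could not discriminate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .core_io import BinaryMask, LabelStack, VolumeStack, split_multiclass

__all__ = [
    "PostprocessParams",
    "log_slice_score",
    "detect_tissue_bounds",
    "blank_nontissue",
    "clean_binary_mask",
    "recombine_masks",
    "postprocess_stack",
]


@dataclass(frozen=True)
class PostprocessParams:
    """Tunables of the clean-up pipeline (defaults as published)."""

    log_sigma: float = 7.0
    tissue_threshold: float = 1.0
    min_blob_lung: int = 10
    min_blob_met: int = 3
    closing_kernel: tuple[int, int] = (3, 3)

    def __post_init__(self):
        if min(self.log_sigma, self.tissue_threshold) <= 0:
            raise ValueError("log_sigma and tissue_threshold must be positive")
        if not 0 < self.min_blob_met <= self.min_blob_lung:
            raise ValueError("need 0 < min_blob_met <= min_blob_lung")


def log_slice_score(slice_8bit: np.ndarray, sigma: float = 7.0) -> float:
    """Mean absolute scale-normalised LoG response of one 2D slice."""
    resp = sigma**2 * ndi.gaussian_laplace(np.asarray(slice_8bit, dtype=np.float64), sigma)
    return float(np.abs(resp).mean())


def detect_tissue_bounds(
    stack: VolumeStack, params: PostprocessParams = PostprocessParams()
) -> tuple[int, int] | None:
    """Scan from both stack ends for the first tissue-bearing slice.

    Returns ``(first_tissue_z, last_tissue_z)`` inclusive, or ``None`` when
    no slice reaches the tissue threshold.
    """
    img = stack.as_8bit()
    Z = img.shape[0]
    scores = {}

    def is_tissue(z: int) -> bool:
        if z not in scores:
            scores[z] = log_slice_score(img[z], params.log_sigma)
        return scores[z] >= params.tissue_threshold

    first = next((z for z in range(Z) if is_tissue(z)), None)
    if first is None:
        return None
    last = next(z for z in range(Z - 1, -1, -1) if is_tissue(z))
    return (first, last)


def blank_nontissue(mask: LabelStack, bounds: tuple[int, int] | None) -> LabelStack:
    """Set slices outside the inclusive tissue bounds to background only."""
    data = mask.data.copy()
    if bounds is None:
        data[:] = 0
    else:
        first, last = bounds
        data[:first] = 0
        data[last + 1 :] = 0
    return LabelStack(data, spacing_mm=mask.spacing_mm)


def clean_binary_mask(
    mask: BinaryMask,
    min_blob: int,
    closing_kernel: tuple[int, int] = (3, 3),
    apply_closing: bool = True,
) -> BinaryMask:
    """Remove blobs with area < min_blob px, then 3x3 morphological closing.

    Blob connectivity is 8-connected (diagonals count), consistent with the
    closing's tendency to bridge diagonal gaps. Removal is strict: a blob of
    exactly ``min_blob`` pixels is kept.
    """
    m = mask.data.astype(bool)
    labeled = measure.label(m, connectivity=2)
    counts = np.bincount(labeled.ravel())
    keep = counts >= min_blob
    keep[0] = False
    m = keep[labeled]
    if apply_closing:
        m = ndi.binary_closing(m, structure=np.ones(closing_kernel, dtype=bool))
    return BinaryMask(m.astype(np.uint8), mask.target_class)


def recombine_masks(lung: BinaryMask, met: BinaryMask) -> np.ndarray:
    """Merge binary masks into a multiclass array; metastasis wins overlaps."""
    if lung.data.shape != met.data.shape:
        raise ValueError(
            f"shape mismatch: lung {lung.data.shape} vs metastasis {met.data.shape}"
        )
    out = np.where(met.data > 0, 2, np.where(lung.data > 0, 1, 0))
    return out.astype(np.int64)


def postprocess_stack(
    raw_pred: LabelStack,
    stack: VolumeStack,
    params: PostprocessParams = PostprocessParams(),
) -> LabelStack:
    """Apply the four clean-up steps to a raw multiclass prediction."""
    if raw_pred.shape != stack.shape:
        raise ValueError(
            f"prediction shape {raw_pred.shape} does not match stack {stack.shape}"
        )
    bounded = blank_nontissue(raw_pred, detect_tissue_bounds(stack, params))
    lung, met = split_multiclass(bounded)
    out = np.zeros_like(bounded.data)
    for z in range(out.shape[0]):
        lung_z = clean_binary_mask(
            BinaryMask(lung.data[z], "lung"), params.min_blob_lung, params.closing_kernel
        )
        met_z = clean_binary_mask(
            BinaryMask(met.data[z], "metastasis"), params.min_blob_met, params.closing_kernel
        )
        out[z] = recombine_masks(lung_z, met_z)
    return LabelStack(out, spacing_mm=raw_pred.spacing_mm)
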