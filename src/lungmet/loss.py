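"""Composite training objective: weighted CE + Lovasz-Softmax + focal loss.

The total loss is ``L = alpha * L_CE + beta * L_L + gamma_mix * L_F`` with
alpha = 0.7, beta = 0.4, gamma_mix = 0.2 and per-class weights (1, 5, 15)
for background, lung and metastasis. The weights deliberately do not sum to
one and are used as-is. The class weights counter the extreme
background/foreground imbalance of thorax slices; the Lovasz-Softmax term
is a convex surrogate of the Jaccard loss (it equals ``1 - IoU`` per class
at hard predictions), and the focal term down-weights easy pixels via the
``(1 - p)^focal_gamma`` modulation (``focal_gamma`` is the focusing
exponent, default 2 — distinct from the mixture weight ``gamma_mix``).

All three components accept either NumPy arrays or autodiff Tensors of
shape (C, H, W) or (N, C, H, W) plus an integer target of matching spatial
shape, and return a scalar Tensor (so they can drive training directly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, clipped_log, gather_class, take_flat

__all__ = [
    "LossConfig",
    "weighted_cross_entropy",
    "lovasz_softmax",
    "focal_loss",
    "combined_loss",
]

LOG_EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Mixture weights and class weights of the composite loss."""

    alpha: float = 0.7
    beta: float = 0.4
    gamma_mix: float = 0.2
    class_weights: tuple[float, ...] = (1.0, 5.0, 15.0)
    focal_gamma: float = 2.0

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma_mix) < 0 or self.focal_gamma < 0:
            raise ValueError("loss weights and focal_gamma must be >= 0")
        if len(self.class_weights) < 2 or min(self.class_weights) <= 0:
            raise ValueError("class_weights must be >= 2 strictly positive values")


def _as_batch(probs, target):
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, dtype=float))
    t = np.asarray(target)
    if p.ndim == 3:
        p = p.reshape(1, *p.shape)
    if t.ndim == 2:
        t = t[None]
    if p.shape[0] != t.shape[0] or p.shape[2:] != t.shape[1:]:
        raise ValueError(f"probs shape {p.shape} does not match target {t.shape}")
    if t.min() < 0 or t.max() >= p.shape[1]:
        raise ValueError("target labels out of range for the probability map")
    return p, t


def _pixel_weights(target: np.ndarray, class_weights) -> np.ndarray:
    return np.asarray(class_weights, dtype=float)[target]


def weighted_cross_entropy(probs, target, class_weights=(1.0, 5.0, 15.0)) -> Tensor:
    """Mean over pixels of ``-w(y) * log p(y)`` with probs clipped to [eps, 1]."""
    p, t = _as_batch(probs, target)
    w = Tensor(_pixel_weights(t, class_weights))
    return -(w * clipped_log(gather_class(p, t), LOG_EPS)).mean()


def focal_loss(probs, target, focal_gamma=2.0, class_weights=(1.0, 5.0, 15.0)) -> Tensor:
    """Mean of ``-w(y) * (1 - p(y))^focal_gamma * log p(y)``.

    Reduces exactly to the weighted cross-entropy at ``focal_gamma = 0``.
    """
    p, t = _as_batch(probs, target)
    w = Tensor(_pixel_weights(t, class_weights))
    py = gather_class(p, t)
    modulation = (1.0 - py) ** float(focal_gamma) if focal_gamma != 0 else 1.0
    return -(w * modulation * clipped_log(py, LOG_EPS)).mean()


def _lovasz_grad(gt_sorted: np.ndarray) -> np.ndarray:
    """Gradient of the Lovasz extension of the Jaccard loss along the sort."""
    gts = gt_sorted.sum()
    intersection = gts - np.cumsum(gt_sorted)
    union = gts + np.cumsum(1.0 - gt_sorted)
    jaccard = 1.0 - intersection / union
    if gt_sorted.size > 1:
        jaccard[1:] = jaccard[1:] - jaccard[:-1]
    return jaccard


def lovasz_softmax(probs, target) -> Tensor:
    """Per-image Lovasz-Softmax over the classes present in the target.

    For each present class c the error vector ``e = |fg_c - p_c|`` (with
    ``fg_c`` the binary ground truth of c) is sorted in decreasing order and
    dotted with the Lovasz-extension gradient of the Jaccard loss; the
    result is averaged over present classes, then over images. The sorting
    permutation and the gradient coefficients are treated as constants of
    the surrogate, as in the original formulation.
    """
    p, t = _as_batch(probs, target)
    N, C, H, W = p.shape
    terms = []
    for n in range(N):
        present = np.unique(t[n])
        class_terms = []
        for c in present:
            fg = (t[n] == c).astype(float)  # (H, W)
            pc_flat_base = n * C * H * W + c * H * W
            idx = pc_flat_base + np.arange(H * W)
            pc = take_flat(p, idx)  # probabilities of class c, flattened
            fgf = fg.ravel()
            errors = Tensor(fgf) + Tensor(1.0 - 2.0 * fgf) * pc  # |fg - p_c|
            order = np.argsort(-errors.data, kind="stable")
            grad = _lovasz_grad(fgf[order])
            class_terms.append((take_flat(errors, order) * Tensor(grad)).sum())
        acc = class_terms[0]
        for ct in class_terms[1:]:
            acc = acc + ct
        terms.append(acc * (1.0 / len(class_terms)))
    total = terms[0]
    for tm in terms[1:]:
        total = total + tm
    return total * (1.0 / N)


def combined_loss(probs, target, config: LossConfig = LossConfig()) -> Tensor:
    """``alpha * L_CE + beta * L_Lovasz + gamma_mix * L_focal``."""
    ce = weighted_cross_entropy(probs, target, config.class_weights)
    lv = lovasz_softmax(probs, target)
    fl = focal_loss(probs, target, config.focal_gamma, config.class_weights)
    return config.alpha * ce + config.beta * lv + config.gamma_mix * fl
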