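"""Evaluate the composite training loss on a toy prediction.

The objective is L = 0.7*CE_w + 0.4*Lovasz + 0.2*Focal with class weights
(1, 5, 15) for background/lung/metastasis: errors on the rare metastasis
class cost 15x more than background errors.
"""

import numpy as np

from lungmet.loss import (
    LossConfig,
    combined_loss,
    focal_loss,
    lovasz_softmax,
    weighted_cross_entropy,
)

rng = np.random.default_rng(0)
target = np.zeros((16, 16), dtype=int)
target[4:12, 4:12] = 1   # a lung patch
target[7:9, 7:9] = 2     # a 4-px metastasis

# a mediocre softmax prediction: mostly right, blurry at boundaries
logits = 2.0 * np.stack([(target == c).astype(float) for c in range(3)])
logits += rng.normal(0, 0.8, logits.shape)
probs = np.exp(logits) / np.exp(logits).sum(axis=0, keepdims=True)

cfg = LossConfig()
ce = weighted_cross_entropy(probs, target, cfg.class_weights).item()
lv = lovasz_softmax(probs, target).item()
fl = focal_loss(probs, target, cfg.focal_gamma, cfg.class_weights).item()
total = combined_loss(probs, target, cfg).item()

print(f"weighted cross-entropy : {ce:.4f}")
print(f"Lovasz-Softmax         : {lv:.4f}")
print(f"focal (gamma=2)        : {fl:.4f}")
print(f"combined 0.7/0.4/0.2   : {total:.4f}")
print(f"check linear combo     : {0.7 * ce + 0.4 * lv + 0.2 * fl:.4f}")
# The Lovasz term approximates the Jaccard loss: at hard predictions it
# equals the mean of (1 - IoU) over the classes present in the target.
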