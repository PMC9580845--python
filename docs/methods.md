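# Methods

This note records the modelling choices behind `lungmet`, the parameters
that matter, what the synthetic phantom does and does not emulate, and the
numerical conventions used where a published description leaves the design
open.

## Problem setting

Input data are 3D self-gated bSSFP MR stacks of the mouse thorax stored as
multipage TIFF, indexed (z, y, x) with the first TIFF page as slice z = 0.
On these images lungs are hypointense inside a brighter body; blood vessels
and pulmonary metastases are both hyperintense, which makes vessels the
canonical false-positive source for metastasis segmentation. Each 2D slice
is segmented independently into {0 background, 1 lung, 2 metastasis};
volumetry then works on the reassembled 3D mask. Voxel spacing is not read
from TIFF tags (the source files carry none) but supplied by configuration;
the default (0.195, 0.156, 0.156) mm gives a voxel volume of
0.00475 mm³ (0.0047 at display precision).

## Network

The segmentation model is a U-Net 3+ variant with:

- encoder depth 5, base width 16, doubling per block: (16, 32, 64, 128, 256);
- blocks of (depthwise-separable 3×3 conv → batch norm → ReLU → dropout) × 2;
  separable = depthwise 3×3 followed by pointwise 1×1, stride 1, zero pad 1;
- 2×2 max pooling between encoder blocks;
- full-scale skip connections: each decoder stage receives one source per
  scale — all shallower encoder outputs, the same-scale deeper feature map,
  and all deeper decoder outputs/the bridge. Sources are rescaled to the
  size of the deeper decoder output (max pooling down, bilinear up),
  projected to 32 channels by a 3×3 conv + BN + ReLU, and concatenated:
  5 × 32 = 160 channels;
- decoder blocks: 2×2/stride-2 transposed convolution (the 2× upsampling)
  followed by the same double separable-conv block; decoder feature maps
  carry 160 channels throughout;
- 1×1 projection to 3 classes and per-pixel softmax. Argmax ties break
  toward the lowest class index (deterministic, biased to background).

Deep supervision and the classification-guided module of the original
U-Net 3+ are omitted. Dropout rate defaults to 0.1. Input slices must have
height/width divisible by 2^(depth−1) = 16. Weight init is He-normal,
seeded; inference uses running batch-norm statistics and no dropout, so
predictions are deterministic for fixed weights.

The whole model runs on `lungmet.autodiff`, a small reverse-mode automatic
differentiation engine over NumPy arrays written for this package. All
convolutions are stride-1 correlations (im2col/einsum); resolution changes
go through pooling, bilinear resizing, or the exact 2×2 transposed
convolution, so every backward pass is itself a stride-1 correlation.
Gradients of every op are verified against central finite differences in
the test suite.

## Loss

`L = α·L_CE + β·L_Lovász + γ·L_F` with α = 0.7, β = 0.4, γ = 0.2 used as
printed (they do not sum to 1; no renormalisation). Class weights
(1, 5, 15) for background/lung/metastasis enter both the cross-entropy and
the focal term (a single class-weight source). The focal focusing exponent
is 2 — the conventional value; note it is distinct from the mixture weight
γ = 0.2. Probabilities are clipped to [1e-7, 1] inside logarithms. The
Lovász-Softmax term is computed per image over the classes present in the
target (per-image variant); the sorting permutation and the
Jaccard-extension coefficients are constants of the surrogate, as in its
original formulation. At hard predictions the term equals the mean of
(1 − IoU) over present classes, which the suite checks to 1e-9.

## Training

Adam (the schedule's peak rate of 0.001 is Adam's conventional scale; no
optimizer was named for the original pipeline), batch size 32 by default,
one cosine annealing cycle without restarts:
`lr(t) = lr_min + ½(lr_max − lr_min)(1 + cos(πt/epochs))`, defaults
lr_max = 0.001, lr_min = 0, 100 epochs. The dataset splits 80/20 at the
slice level with a seeded shuffle (train size = ⌊0.8·N⌋ exactly); an
optional group-aware split assigns whole stacks to one side to avoid
same-animal leakage, at the cost of an approximate ratio. Model selection
keeps the epoch with the best mean foreground validation IoU; when no
validation set is supplied the final weights are returned. A non-finite
loss aborts with a diagnostic rather than continuing.

## Augmentation

The factor-8 expansion is realised as the minimal product reaching exactly
8: {identity, rot90, rot180, rot270} × {plain, elastic}. Right-angle
rotations are exact index permutations. The elastic warp draws a uniform
random field, smooths it with a Gaussian (σ = 10 px), rescales to a maximum
displacement of 3 px ("small deformations"; both configurable), and moves
image (bilinear) and mask (nearest neighbour) with the same field, so label
values are preserved. Fields are drawn per output sample, seeded from
(global seed, sample index).

## Post-processing

Four steps, in order: (1) tissue-bounds detection, (2) split into binary
masks, (3) per-slice blob removal + closing, (4) recombination with
metastasis precedence.

Numerical conventions worth stating:

- The tissue detector computes the **scale-normalised** LoG response
  σ²·∇²G_σ (σ = 7) of each slice on the 0–255 intensity scale and takes
  the mean of absolute values; a slice is tissue iff this score ≥ 1. The
  normalisation matters: the raw LoG of a zero-sum kernel at σ = 7 is far
  below 1 on any realistic slice, so only the σ²-scaled response (the
  standard blob-detection convention) makes a threshold of one
  discriminate. On phantoms, noise-only slices score ≈ 0.15 and
  tissue-bearing slices ≥ 5. Inputs not already 8-bit are mapped to 0–255
  via their dtype range before filtering.
- Scanning proceeds from z = 0 upward and z = Z−1 downward to the first
  tissue slice; everything outside the inclusive bounds is blanked. A stack
  with no tissue slice yields an all-background mask.
- Blob removal uses 8-connectivity in 2D and a strict threshold ("smaller
  than"): a 9-px lung blob is removed, a 10-px blob kept; metastasis cutoff
  3 px. Removal precedes the 3×3 closing.
- Evaluation applies the same per-class blob removal to prediction **and**
  ground truth before scoring, so sub-reviewable specks do not bias the
  statistics.

## Volumetry

Class volume = voxel count × voxel volume (product of the spacing triple;
full precision internally, 4 d.p. for display). Metastasis instances are
maximal 18-connected 3D components (faces and edges adjacent, vertices
not), computed on the post-processed metastasis mask stack and verified
against an independent flood fill. The small/large boundary is 0.4 mm³
(~85 px at the reference resolution) with the boundary value itself
assigned to "large" (the published phrasings conflict at exactly 0.4; this
package reads "under" as strict). Growth tables list per-timepoint lung
volume, total metastasis volume, instance count and a histogram of instance
volumes over configurable bin edges.

## Evaluation metrics

Per-class IoU and F1 are aggregated as mean ± sample sd over slices where
the class occurs in prediction or ground truth; a class occurring in
neither is reported as missing (the NA convention for metastasis rows on
control animals). Two empty masks are defined to agree perfectly
(IoU = F1 = 1). Inter-observer statistics: IoU, absolute positive-pixel
difference, and the surface ratio 1 − min(ΣA, ΣB)/max(ΣA, ΣB) (defined 0
when both masks are empty). The coefficient of variation of repeat
measurements uses the sample (n−1) standard deviation, the convention that
reproduces the published 2.8% for the reference repeat-scan triple
(490.4, 512.1, 486.2 mm³).

## Synthetic phantom

The phantom renders, by voxel-centre rasterization (a voxel belongs to a
primitive iff its centre satisfies the implicit equation — which makes all
counts brute-force checkable): a body ellipsoid on a dark background, two
lung ellipsoids, vessel-like tubes inside the lungs that are hyperintense
but labelled lung (so downstream stages face realistic false-positive
bait), metastasis spheres labelled 2, and pure-noise slices at both stack
ends. Intensities (background 0.03, body 0.55, lung 0.12, vessels and
metastases 0.85 on [0, 1]) keep the ordering lung < body < metastasis and
the vessel/metastasis ambiguity of the real contrast. Noise is additive
Gaussian (σ = 0.02) clipped to [0, 1]; a Rician option exists for
magnitude-image realism but the Gaussian default keeps analytic
expectations simple. Growth series scale metastasis radii so total volume
grows exponentially per imaging interval, rates 0.9 ("fast") vs 0.3
("slow") — values chosen once to separate the two regimes qualitatively,
roughly ×2.5 vs ×1.35 volume per interval.

What the phantom does **not** emulate: banding artifacts, respiratory
motion, partial-volume blur at tissue interfaces, intensity bias fields,
irregular lesion shapes, and anatomy beyond two ellipsoids. Tests passing
on phantoms therefore demonstrate the correctness of the pipeline
machinery (shapes, counts, thresholds, training mechanics), not clinical
segmentation accuracy on real MR data.

## Problem sizes used in the automated suites

The end-to-end learning check trains a reduced network (8 base filters,
8 skip channels per scale) for 10 epochs at peak learning rate 0.003 on the
foreground slices of twenty 32×64×64 phantoms (three metastases each, radii
2.8–4.2 voxels), then requires lung IoU ≥ 0.7 and an exact 3/3 instance
count on a held-out phantom. These sizes were chosen so the whole suite
runs on a single CPU in minutes; the full-scale configuration (16 base
filters, 128³ stacks, 100 epochs) is expressed by the defaults but is not
exercised by the tests.

## Known limitations

- Training on CPU via the NumPy engine is orders of magnitude slower than
  a GPU framework; the package is sized for method development and
  verification, not for large-scale retraining.
- The LoG tissue threshold was calibrated on phantom contrast; real stacks
  with very low contrast may need `tissue_threshold` adjusted.
- The group-aware split trades exact split ratio for leakage safety.
- Per-slice 2D segmentation ignores through-plane context; a metastasis
  visible in a single slice relies entirely on in-plane appearance.
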