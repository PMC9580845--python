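"""Factor-8 training-set augmentation: right-angle rotations x elastic warps.

Each (image, mask) slice pair yields eight pairs: the four grid orientations
(identity, 90, 180, 270 degrees — exact index permutations, no
interpolation) each taken plain and elastically deformed. The elastic warp
draws a random displacement field, smooths it with a Gaussian kernel
(``smoothing_sigma``) and rescales it to a maximum displacement of
``displacement_scale`` pixels; the *same* field moves the image (bilinear
interpolation) and the mask (nearest neighbour), so labels stay in
{0, 1, 2}. Fields are drawn independently per output sample, seeded from
(seed, sample index), so augmentation is reproducible item by item.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

__all__ = ["ElasticParams", "rotate_pair", "elastic_pair", "augment_dataset"]

AUGMENTATION_FACTOR = 8


@dataclass(frozen=True)
class ElasticParams:
    displacement_scale: float = 3.0  # max displacement, px
    smoothing_sigma: float = 10.0  # Gaussian smoothing of the field, px
    seed: int = 0

    def __post_init__(self):
        if self.displacement_scale < 0:
            raise ValueError("displacement_scale must be >= 0")
        if self.smoothing_sigma <= 0:
            raise ValueError("smoothing_sigma must be > 0")


def rotate_pair(image: np.ndarray, mask: np.ndarray, angle: int):
    """Rotate both slices by an exact right angle (90, 180 or 270 degrees)."""
    if angle not in (90, 180, 270):
        raise ValueError(f"angle must be 90, 180 or 270, got {angle}")
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[0] != image.shape[1]:
        raise ValueError("rotation requires square slices")
    k = angle // 90
    return np.rot90(image, k).copy(), np.rot90(mask, k).copy()


def _displacement_field(shape, params: ElasticParams, rng: np.random.Generator):
    field = rng.uniform(-1.0, 1.0, size=(2, *shape))
    field = np.stack([ndi.gaussian_filter(f, params.smoothing_sigma) for f in field])
    peak = np.abs(field).max()
    if peak > 0:
        field *= params.displacement_scale / peak
    return field


def elastic_pair(image: np.ndarray, mask: np.ndarray, params: ElasticParams):
    """Apply one random smooth deformation jointly to image and mask."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if params.displacement_scale == 0:
        return image.copy(), mask.copy()
    rng = np.random.default_rng(params.seed)
    dy, dx = _displacement_field(image.shape, params, rng)
    rows, cols = np.meshgrid(
        np.arange(image.shape[0]), np.arange(image.shape[1]), indexing="ij"
    )
    coords = np.stack([rows + dy, cols + dx])
    warped_img = ndi.map_coordinates(image, coords, order=1, mode="reflect")
    warped_mask = ndi.map_coordinates(mask, coords, order=0, mode="reflect")
    return warped_img, warped_mask.astype(mask.dtype)


def augment_dataset(
    pairs: Sequence[tuple], params: ElasticParams = ElasticParams(), seed: int = 0
) -> list[tuple]:
    """Expand a dataset by exactly 8x: {4 orientations} x {plain, elastic}.

    Output order per input pair: rot0, rot90, rot180, rot270, then the same
    four orientations elastically deformed. An empty input yields an empty
    output.
    """
    out: list[tuple] = []
    sample_index = 0
    for image, mask in pairs:
        image = np.asarray(image)
        mask = np.asarray(mask)
        oriented = [(image.copy(), mask.copy())]
        for angle in (90, 180, 270):
            oriented.append(rotate_pair(image, mask, angle))
        out.extend(oriented)
        for img_r, mask_r in oriented:
            p = replace(params, seed=(seed * 1_000_003 + sample_index) % (2**31))
            out.append(elastic_pair(img_r, mask_r, p))
            sample_index += 1
    return out
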