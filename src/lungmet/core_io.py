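"""Domain types and multipage-TIFF I/O for MR stacks and multiclass masks.

A 3D acquisition is stored as one multipage TIFF whose pages become axial
z-slices in file order; arrays are indexed (z, y, x). Segmentation masks use
the label convention 0 = background, 1 = lung, 2 = metastasis. Voxel spacing
is metadata supplied by configuration (the source TIFFs carry no spacing
tags); the default spacing (0.195, 0.156, 0.156) mm corresponds to the
acquisition resolution the pipeline was designed for, giving a voxel volume
of ~0.0047 mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "DEFAULT_SPACING_MM",
    "BACKGROUND",
    "LUNG",
    "METASTASIS",
    "VolumeStack",
    "LabelStack",
    "BinaryMask",
    "read_stack",
    "write_stack",
    "read_labelstack",
    "write_labelstack",
    "split_multiclass",
]

#: Voxel edge lengths (z, y, x) in millimetres at the reference resolution.
DEFAULT_SPACING_MM: tuple[float, float, float] = (0.195, 0.156, 0.156)

BACKGROUND, LUNG, METASTASIS = 0, 1, 2


class FormatError(ValueError):
    """Raised when a file on disk does not match the expected layout."""


@dataclass
class VolumeStack:
    """A 3D scalar intensity grid with voxel spacing.

    Attributes
    ----------
    data : (Z, Y, X) ndarray
        Intensities as stored in the source file (dtype preserved).
    spacing_mm : (float, float, float)
        Voxel edge lengths along (z, y, x) in mm.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"stack must be 3D with all dims >= 1, got {self.data.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing_mm}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def intensity_range(self) -> tuple[float, float]:
        return float(self.data.min()), float(self.data.max())

    def normalized(self) -> np.ndarray:
        """Intensities mapped to [0, 1] float32 (network input convention).

        Unsigned integer data is divided by its dtype maximum; float data is
        min-max scaled only if it exceeds [0, 1].
        """
        d = self.data
        if np.issubdtype(d.dtype, np.unsignedinteger):
            return (d / np.iinfo(d.dtype).max).astype(np.float32)
        d = d.astype(np.float32)
        lo, hi = float(d.min()), float(d.max())
        if lo >= 0.0 and hi <= 1.0:
            return d
        if hi == lo:
            return np.zeros_like(d)
        return (d - lo) / (hi - lo)

    def as_8bit(self) -> np.ndarray:
        """Intensities on the 0-255 scale used by the LoG tissue filter."""
        if self.data.dtype == np.uint8:
            return self.data
        return np.round(self.normalized() * 255.0).astype(np.float64)


@dataclass
class LabelStack:
    """A 3D multiclass mask over {0 background, 1 lung, 2 metastasis}."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label stack must be 3D, got {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"labels must be integers, got dtype {self.data.dtype}")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 2):
            raise ValueError("labels must lie in {0, 1, 2}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def class_counts(self) -> dict[int, int]:
        return {c: int((self.data == c).sum()) for c in (0, 1, 2)}


@dataclass
class BinaryMask:
    """A 2D or 3D {0,1} mask for one target class (lung or metastasis)."""

    data: np.ndarray
    target_class: str = "lung"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.size and not np.isin(self.data, (0, 1)).all():
            raise ValueError("binary mask values must be in {0, 1}")
        if self.target_class not in ("lung", "metastasis"):
            raise ValueError(f"unknown target class {self.target_class!r}")


def read_stack(path, spacing_mm=DEFAULT_SPACING_MM) -> VolumeStack:
    """Read a multipage TIFF as a VolumeStack (pages -> z-slices, bit-exact)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise FormatError(f"{path}: pages have unequal sizes {sorted(shapes)}")
        data = tf.asarray()
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 2D pages, got array of shape {data.shape}")
    return VolumeStack(data, spacing_mm=spacing_mm)


def write_stack(stack: VolumeStack, path) -> None:
    """Write a VolumeStack as a multipage TIFF, one page per z-slice."""
    tifffile.imwrite(Path(path), stack.data, photometric="minisblack")


def write_labelstack(mask: LabelStack, path) -> None:
    """Write a LabelStack as an 8-bit multipage TIFF with literal {0,1,2}."""
    tifffile.imwrite(Path(path), mask.data.astype(np.uint8), photometric="minisblack")


def read_labelstack(path, spacing_mm=DEFAULT_SPACING_MM) -> LabelStack:
    """Read a multipage TIFF of labels; values are validated to {0,1,2}."""
    vol = read_stack(path, spacing_mm=spacing_mm)
    return LabelStack(vol.data.astype(np.int64), spacing_mm=spacing_mm)


def split_multiclass(mask: LabelStack) -> tuple[BinaryMask, BinaryMask]:
    """Split a multiclass mask into (lung, metastasis) binary masks."""
    lung = BinaryMask((mask.data == LUNG).astype(np.uint8), "lung")
    met = BinaryMask((mask.data == METASTASIS).astype(np.uint8), "metastasis")
    return lung, met
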