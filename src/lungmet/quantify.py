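"""Volumetry: voxel volume, class volumes, per-metastasis instances, series.

Volumes are voxel counts times the voxel volume (product of the three voxel
edge lengths; 0.0047 mm^3 at the reference resolution of 0.195 x 0.156 x
0.156 mm). Individual metastases are maximal 18-connected components of the
3D metastasis mask: face (6) and edge (12) neighbours are adjacent, vertex-
only neighbours are not. A metastasis is "small" below 0.4 mm^3 (~85 pixels
at the reference resolution) and "large" at or above it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core_io import LabelStack

__all__ = [
    "SMALL_LARGE_CUTOFF_MM3",
    "VolumetryReport",
    "voxel_volume",
    "compute_volumes",
    "label_metastasis_instances",
    "classify_metastasis_size",
    "summarize_series",
]

#: Small/large metastasis volume cutoff in mm^3.
SMALL_LARGE_CUTOFF_MM3 = 0.4

#: 3D structuring element for 18-connectivity (faces + edges, no vertices).
STRUCT_18 = ndi.generate_binary_structure(3, 2)


@dataclass
class VolumetryReport:
    """Per-stack volumetry summary."""

    lung_volume_mm3: float
    met_total_volume_mm3: float
    met_count: int
    met_instance_volumes_mm3: list[float]
    voxel_volume_mm3: float

    def __post_init__(self):
        if abs(self.met_total_volume_mm3 - sum(self.met_instance_volumes_mm3)) > 1e-9:
            raise ValueError("instance volumes do not sum to the total")
        if self.met_count != len(self.met_instance_volumes_mm3):
            raise ValueError("met_count does not match the instance list")

    def to_dict(self) -> dict:
        return {
            "lung_volume_mm3": self.lung_volume_mm3,
            "met_total_volume_mm3": self.met_total_volume_mm3,
            "met_count": self.met_count,
            "met_instance_volumes_mm3": list(self.met_instance_volumes_mm3),
            "voxel_volume_mm3": self.voxel_volume_mm3,
        }


def voxel_volume(spacing_mm) -> float:
    """Voxel volume in mm^3 from the three voxel edge lengths in mm."""
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths, got {spacing_mm}")
    return float(np.prod(spacing))


def label_metastasis_instances(met_mask_3d: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Label maximal 18-connected components of a 3D binary metastasis mask.

    Returns the instance label grid (0 = background, instances 1..K) and the
    per-instance voxel counts ordered by instance label.
    """
    m = np.asarray(met_mask_3d)
    if m.ndim != 3:
        raise ValueError(f"expected a 3D mask, got shape {m.shape}")
    labeled, k = ndi.label(m.astype(bool), structure=STRUCT_18)
    counts = np.bincount(labeled.ravel(), minlength=k + 1)[1:]
    return labeled, [int(c) for c in counts]


def compute_volumes(mask: LabelStack, voxel_volume_mm3: float | None = None) -> VolumetryReport:
    """Volumetry of a multiclass mask: class volumes + metastasis instances."""
    v = voxel_volume(mask.spacing_mm) if voxel_volume_mm3 is None else float(voxel_volume_mm3)
    if v <= 0:
        raise ValueError("voxel volume must be positive")
    lung_vox = int((mask.data == 1).sum())
    _, inst_counts = label_metastasis_instances(mask.data == 2)
    instance_volumes = [c * v for c in inst_counts]
    return VolumetryReport(
        lung_volume_mm3=lung_vox * v,
        met_total_volume_mm3=float(sum(instance_volumes)),
        met_count=len(instance_volumes),
        met_instance_volumes_mm3=instance_volumes,
        voxel_volume_mm3=v,
    )


def classify_metastasis_size(volume_mm3: float) -> str:
    """'small' below the 0.4 mm^3 cutoff, 'large' at or above it."""
    if volume_mm3 < 0:
        raise ValueError("volume must be non-negative")
    return "small" if volume_mm3 < SMALL_LARGE_CUTOFF_MM3 else "large"


def summarize_series(
    reports: list[VolumetryReport],
    timepoints=None,
    volume_bins=(0.0, 0.4, 1.0, 5.0, 25.0, np.inf),
) -> pd.DataFrame:
    """Tabulate a longitudinal series of volumetry reports.

    One row per timepoint with lung volume, total metastasis volume and
    count, plus a histogram of instance volumes over ``volume_bins``
    (right-open bins; totals partition ``met_count``).
    """
    if not reports:
        raise ValueError("need at least one report")
    if timepoints is None:
        timepoints = list(range(len(reports)))
    if len(timepoints) != len(reports):
        raise ValueError("timepoints and reports differ in length")
    edges = np.asarray(volume_bins, dtype=float)
    rows = []
    for t, r in zip(timepoints, reports):
        hist, _ = np.histogram(r.met_instance_volumes_mm3, bins=edges)
        row = {
            "timepoint": t,
            "lung_volume_mm3": r.lung_volume_mm3,
            "met_total_volume_mm3": r.met_total_volume_mm3,
            "met_count": r.met_count,
        }
        for i, n in enumerate(hist):
            lo, hi = edges[i], edges[i + 1]
            hi_s = "inf" if np.isinf(hi) else f"{hi:g}"
            row[f"n_mets_{edges[i]:g}_to_{hi_s}_mm3"] = int(n)
        rows.append(row)
    return pd.DataFrame(rows)
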