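"""Overlap, surface-distance, and volume metrics between mask pairs.

Surfaces are foreground voxels with at least one 6-connected background (or
out-of-lattice) neighbor. Directed surface distances are Euclidean distances
in mm between voxel centers, computed with an exact distance transform. The
symmetric metrics pool both directed distance multisets:

    ASD  = mean of the pooled multiset
    HD   = max of the pooled multiset
    HD95 = 95th percentile (linear interpolation) of the pooled multiset

VD (volume difference) is signed positive when the reference (clinical)
contour is larger than the prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mask import SegmentationMask, _require_same_grid
from .ops import volume_cm3

__all__ = [
    "MetricSet",
    "overlap_metrics",
    "surface_distance_metrics",
    "volume_difference",
    "evaluate_pair",
    "surface_voxels",
]


@dataclass(frozen=True)
class MetricSet:
    """All metrics for one (reference, prediction) pair.

    Surface metrics are NaN (missing, never silently zero) when either mask
    is empty.
    """

    dice: float
    iou: float
    asd_mm: float
    hd_mm: float
    hd95_mm: float
    vd_cm3: float

    def as_dict(self) -> dict[str, float]:
        return {
            "dice": self.dice,
            "iou": self.iou,
            "asd_mm": self.asd_mm,
            "hd_mm": self.hd_mm,
            "hd95_mm": self.hd95_mm,
            "vd_cm3": self.vd_cm3,
        }


def overlap_metrics(
    reference: SegmentationMask, prediction: SegmentationMask
) -> tuple[float, float]:
    """Dice and Jaccard (IoU) overlap ratios.

    Two empty masks are in perfect agreement: (1.0, 1.0).
    """
    _require_same_grid(reference, prediction)
    a = reference.voxels
    b = prediction.voxels
    inter = int(np.count_nonzero(a & b))
    na = int(np.count_nonzero(a))
    nb = int(np.count_nonzero(b))
    if na == 0 and nb == 0:
        return 1.0, 1.0
    dice = 2.0 * inter / (na + nb)
    iou = inter / (na + nb - inter)
    return dice, iou


def surface_voxels(fg: np.ndarray) -> np.ndarray:
    """Boolean surface of a foreground array under the 6-connectivity rule.

    A foreground voxel is on the surface if any of its six face neighbors is
    background or lies outside the lattice.
    """
    struct = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(fg, structure=struct, border_value=0)
    return fg & ~eroded


def _directed_distances(
    src_surface: np.ndarray, dst_surface: np.ndarray, spacing: tuple[float, float, float]
) -> np.ndarray:
    # exact EDT of the destination surface, sampled at the source surface
    dt = ndimage.distance_transform_edt(~dst_surface, sampling=spacing)
    return dt[src_surface]


def surface_distance_metrics(
    reference: SegmentationMask, prediction: SegmentationMask
) -> tuple[float, float, float]:
    """Symmetric ASD, HD, and HD95 in mm on the pooled distance multiset."""
    _require_same_grid(reference, prediction)
    if reference.is_empty() or prediction.is_empty():
        raise ValueError("surface undefined for empty mask")
    surf_a = surface_voxels(reference.voxels)
    surf_b = surface_voxels(prediction.voxels)
    spacing = reference.spacing_mm
    d_ab = _directed_distances(surf_a, surf_b, spacing)
    d_ba = _directed_distances(surf_b, surf_a, spacing)
    pooled = np.concatenate([d_ab, d_ba])
    return (
        float(pooled.mean()),
        float(pooled.max()),
        float(np.percentile(pooled, 95)),
    )


def volume_difference(
    reference: SegmentationMask, prediction: SegmentationMask
) -> float:
    """Signed volume difference reference - prediction, in cm^3.

    Positive means the clinical (reference) contour is larger.
    """
    if not np.allclose(reference.spacing_mm, prediction.spacing_mm, atol=1e-6):
        raise ValueError(
            f"spacing mismatch: {reference.spacing_mm} vs {prediction.spacing_mm}"
        )
    return volume_cm3(reference) - volume_cm3(prediction)


def evaluate_pair(
    reference: SegmentationMask, prediction: SegmentationMask
) -> MetricSet:
    """Bundle overlap, surface, and volume metrics for one pair.

    If either mask is empty the surface metrics are reported as NaN rather
    than zero, so an empty prediction is never rewarded.
    """
    dice, iou = overlap_metrics(reference, prediction)
    if reference.is_empty() or prediction.is_empty():
        asd = hd = hd95 = math.nan
    else:
        asd, hd, hd95 = surface_distance_metrics(reference, prediction)
    vd = volume_difference(reference, prediction)
    return MetricSet(dice=dice, iou=iou, asd_mm=asd, hd_mm=hd, hd95_mm=hd95, vd_cm3=vd)
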