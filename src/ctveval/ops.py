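"""Set-algebraic and morphological mask operations.

Connected-component filtering (largest component, small-component removal),
physical volume, and cranio-caudal cropping. Component labeling defaults to
26-connectivity, the usual 3-D clinical convention.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .mask import SegmentationMask

__all__ = [
    "largest_component",
    "remove_small_components",
    "volume_cm3",
    "crop_to_z_range",
]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def largest_component(mask: SegmentationMask, connectivity: int = 26) -> SegmentationMask:
    """Keep only the largest connected foreground component.

    Ties on voxel count are broken deterministically: the component
    containing the lexicographically smallest foreground index (C order over
    (i, j, k)) survives. An empty mask passes through unchanged.
    """
    if mask.is_empty():
        return mask.with_voxels(mask.voxels.copy())
    labeled, n = ndimage.label(mask.voxels, structure=_structure(connectivity))
    if n == 1:
        return mask.with_voxels(mask.voxels.copy())
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0
    max_size = sizes.max()
    flat = labeled.ravel()
    fg_flat = np.flatnonzero(flat)
    # first foreground voxel in C order whose component attains the max size
    winner = 0
    for idx in fg_flat:
        if sizes[flat[idx]] == max_size:
            winner = flat[idx]
            break
    return mask.with_voxels(labeled == winner)


def remove_small_components(
    mask: SegmentationMask, min_voxels: int = 1000, connectivity: int = 26
) -> SegmentationMask:
    """Discard connected components with fewer than ``min_voxels`` voxels.

    The default of 1000 voxels is the scattered-label refinement threshold
    used when cleaning clinician CTV masks before model training.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    if mask.is_empty() or min_voxels == 1:
        return mask.with_voxels(mask.voxels.copy())
    labeled, n = ndimage.label(mask.voxels, structure=_structure(connectivity))
    sizes = np.bincount(labeled.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return mask.with_voxels(keep[labeled])


def volume_cm3(mask: SegmentationMask) -> float:
    """Physical foreground volume: voxel count x voxel volume, in cm^3."""
    return mask.foreground_count() * mask.voxel_volume_mm3 / 1000.0


def crop_to_z_range(mask: SegmentationMask, z_first: int, z_last: int) -> SegmentationMask:
    """Zero all foreground outside slices ``[z_first, z_last]`` (inclusive).

    The lattice shape is unchanged; only the cranio-caudal (k) extent of the
    foreground is restricted.
    """
    nk = mask.shape[2]
    if not (0 <= z_first <= z_last < nk):
        raise ValueError(
            f"invalid z range [{z_first}, {z_last}] for {nk} slices"
        )
    out = mask.voxels.copy()
    out[:, :, :z_first] = False
    out[:, :, z_last + 1 :] = False
    return mask.with_voxels(out)
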