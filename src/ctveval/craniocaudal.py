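"""Cranio-caudal (superior-inferior) extent analysis and harmonization.

The cranio-caudal axis is the third lattice axis ``k``; increasing ``k`` is
cranial. ``z_extent`` scans a mask for its first (caudal-most) and last
(cranial-most) foreground slices; ``cc_differences`` converts end-slice
index differences to cm; ``harmonize_cc`` crops a prediction to the
reference extent, which removes the cranio-caudal component of the error
so the remaining comparison is purely volumetric.

Note: harmonization derives the crop box from the reference (ground-truth)
extent, the same a-priori bounding box a prompted model would receive.  This
leaks the true extent into every prediction and is a deliberate,
documented limitation of the fair-comparison protocol.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .mask import SegmentationMask, _require_same_grid
from .ops import crop_to_z_range

__all__ = ["ZExtent", "z_extent", "cc_differences", "cc_differences_signed", "harmonize_cc"]


class ZExtent(NamedTuple):
    """Inclusive foreground slice range along the cranio-caudal axis."""

    z_first: int  # caudal-most foreground slice
    z_last: int  # cranial-most foreground slice


def z_extent(mask: SegmentationMask) -> ZExtent:
    """First and last slices containing foreground."""
    per_slice = np.any(mask.voxels, axis=(0, 1))
    nz = np.flatnonzero(per_slice)
    if nz.size == 0:
        raise ValueError("z extent undefined for empty mask")
    return ZExtent(int(nz[0]), int(nz[-1]))


def cc_differences_signed(
    reference: SegmentationMask, prediction: SegmentationMask
) -> tuple[float, float]:
    """Signed cranial and caudal end-slice differences, in cm.

    Positive cranial value: the prediction overshoots cranially (extends
    above the reference). Positive caudal value: the prediction overshoots
    caudally (extends below). Useful diagnostically; the reported quantities
    are the absolute versions from :func:`cc_differences`.
    """
    _require_same_grid(reference, prediction)
    ref = z_extent(reference)
    pred = z_extent(prediction)
    dz_cm = reference.spacing_mm[2] / 10.0
    cranial = (pred.z_last - ref.z_last) * dz_cm
    caudal = (ref.z_first - pred.z_first) * dz_cm
    return float(cranial), float(caudal)


def cc_differences(
    reference: SegmentationMask, prediction: SegmentationMask
) -> tuple[float, float]:
    """Absolute cranial and caudal end-slice differences, converted to cm.

    cranial = |z_last(ref) - z_last(pred)| * dz / 10
    caudal  = |z_first(ref) - z_first(pred)| * dz / 10
    """
    cranial, caudal = cc_differences_signed(reference, prediction)
    return abs(cranial), abs(caudal)


def harmonize_cc(
    prediction: SegmentationMask, reference: SegmentationMask
) -> SegmentationMask:
    """Crop a prediction to the reference's cranio-caudal extent.

    Only the prediction is modified (never the reference), so the
    cranio-caudal difference of the cropped prediction is zero wherever it
    still reaches the reference boundary slices.
    """
    ref_extent = z_extent(reference)
    return crop_to_z_range(prediction, ref_extent.z_first, ref_extent.z_last)
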