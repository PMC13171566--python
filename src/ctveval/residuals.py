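"""Under/over-segmentation residuals against an ensemble confidence band.

The residuals compare the clinical contour V_clin with the high-agreement
(100%) and low-agreement (e.g. 25%) isoprobability volumes:

    under(%) = 100 * (|V_100| - |V_clin  ∩ V_100|)   / |V_clin|
    over(%)  = 100 * (|V_clin| - |V_clin ∩ V_lower|) / |V_clin|

Both are pure voxel-count ratios (spacing cancels) and are zero exactly
when the clinical contour lies inside the [100%, lower%] confidence band,
i.e. V_100 ⊆ V_clin ⊆ V_lower.

The under-segmentation formula above is the citable printed definition.
Its verbal gloss — "the portion of the clinical CTV not covered by the
100% consensus" — describes a different quantity,
100 * (|V_clin| - |V_clin ∩ V_100|) / |V_clin|, which is provided as the
companion diagnostic :func:`under_segmentation_residual_coverage`; the
printed formula is primary and the discrepancy is surfaced, not resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mask import SegmentationMask, _require_same_grid

__all__ = [
    "ResidualResult",
    "under_segmentation_residual",
    "under_segmentation_residual_coverage",
    "over_segmentation_residual",
    "compute_residuals",
    "residual_sum",
    "cumulative_curve",
    "crossing_at",
]


@dataclass(frozen=True)
class ResidualResult:
    """Residual percentages for one patient; sum_pct = under + over."""

    under_pct: float
    over_pct: float
    sum_pct: float
    patient_id: str = ""


def _counts(v_clin: SegmentationMask, other: SegmentationMask) -> tuple[int, int, int]:
    _require_same_grid(v_clin, other)
    n_clin = v_clin.foreground_count()
    if n_clin == 0:
        raise ValueError("residuals undefined for empty clinical mask")
    n_other = other.foreground_count()
    n_inter = int(np.count_nonzero(v_clin.voxels & other.voxels))
    return n_clin, n_other, n_inter


def under_segmentation_residual(
    v_clin: SegmentationMask, v100: SegmentationMask
) -> float:
    """100 * (|V100| - |V_clin ∩ V100|) / |V_clin| — the printed formula.

    Zero whenever V100 ⊆ V_clin (the full consensus never strays outside
    the clinical contour).
    """
    n_clin, n_100, n_inter = _counts(v_clin, v100)
    return 100.0 * (n_100 - n_inter) / n_clin


def under_segmentation_residual_coverage(
    v_clin: SegmentationMask, v100: SegmentationMask
) -> float:
    """Diagnostic prose variant: clinical volume missed by the consensus.

    100 * (|V_clin| - |V_clin ∩ V100|) / |V_clin|.
    """
    n_clin, _, n_inter = _counts(v_clin, v100)
    return 100.0 * (n_clin - n_inter) / n_clin


def over_segmentation_residual(
    v_clin: SegmentationMask, v_lower: SegmentationMask
) -> float:
    """100 * (|V_clin| - |V_clin ∩ V_lower|) / |V_clin|.

    Zero whenever V_clin ⊆ V_lower (the broad union covers the clinical
    contour entirely); 100 when they are disjoint.
    """
    n_clin, _, n_inter = _counts(v_clin, v_lower)
    return 100.0 * (n_clin - n_inter) / n_clin


def compute_residuals(
    v_clin: SegmentationMask,
    v100: SegmentationMask,
    v_lower: SegmentationMask,
    patient_id: str = "",
) -> ResidualResult:
    under = under_segmentation_residual(v_clin, v100)
    over = over_segmentation_residual(v_clin, v_lower)
    return ResidualResult(
        under_pct=under,
        over_pct=over,
        sum_pct=under + over,
        patient_id=patient_id or v_clin.patient_id,
    )


def residual_sum(result: ResidualResult) -> float:
    """Combined residual: under + over, in percent."""
    return result.under_pct + result.over_pct


def cumulative_curve(values: list[float] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical cumulative distribution of residual percentages.

    Returns (sorted unique values, cumulative frequencies); frequencies lie
    in (0, 1] and reach 1 at the maximum value.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cumulative curve needs at least one value")
    if not np.isfinite(arr).all():
        raise ValueError("cumulative curve needs finite values")
    uniq, counts = np.unique(arr, return_counts=True)
    freqs = np.cumsum(counts) / arr.size
    return uniq, freqs


def crossing_at(values: list[float] | np.ndarray, freq: float = 0.9) -> float:
    """Residual level at which the cumulative frequency reaches ``freq``.

    Uses the linear-interpolation empirical quantile (the "type 7"
    convention): the 0.9 crossing of a residual distribution is its 90th
    percentile.
    """
    if not (0 < freq < 1):
        raise ValueError("freq must be strictly between 0 and 1")
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("crossing needs at least two values")
    if not np.isfinite(arr).all():
        raise ValueError("crossing needs finite values")
    return float(np.quantile(arr, freq))
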