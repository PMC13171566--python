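"""Ensemble model-agreement probability maps and isoprobability volumes.

Averaging K boolean predictions voxelwise yields an agreement map whose
values are exactly k/K for integer k. Thresholding the integer support
count at ceil(p * K / 100) gives the p% isoprobability volume: for K = 4
the attainable levels are 25/50/75/100%, the 100% volume is the
intersection of all models (most conservative consensus) and the 25%
volume is their union (broadest contouring). Isoprobability volumes are
nested by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mask import SegmentationMask
from .ops import volume_cm3

__all__ = [
    "ProbabilityMap",
    "IsoprobabilitySet",
    "build_probability_map",
    "isoprobability_mask",
    "isoprobability_set",
    "iso_volume_difference",
    "default_levels",
]


@dataclass
class ProbabilityMap:
    """Voxelwise fraction of ensemble models predicting foreground.

    The map stores the integer support count per voxel; ``agreement``
    exposes the fraction count / n_models, guaranteed to be exactly k/K.
    """

    counts: np.ndarray  # integer support counts, 0..n_models
    n_models: int
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise ValueError("a probability map needs at least 2 models")
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ValueError("agreement counts must be a 3-D lattice")
        if counts.min() < 0 or counts.max() > self.n_models:
            raise ValueError("support counts must lie in [0, n_models]")
        self.counts = counts.astype(np.int16)

    @property
    def agreement(self) -> np.ndarray:
        return self.counts / float(self.n_models)


@dataclass
class IsoprobabilitySet:
    """Nested isoprobability masks, one per agreement level (percent)."""

    levels: list[float]
    masks: list[SegmentationMask]


def build_probability_map(predictions: list[SegmentationMask]) -> ProbabilityMap:
    """Average K boolean predictions into an agreement map.

    Predictions are expected already post-processed (largest component kept,
    cranio-caudal extent harmonized) the same way they were evaluated.
    """
    if len(predictions) < 2:
        raise ValueError("need at least 2 predictions to build a probability map")
    first = predictions[0]
    for p in predictions[1:]:
        if p.shape != first.shape:
            raise ValueError(f"lattice shape mismatch: {p.shape} vs {first.shape}")
        if not np.allclose(p.spacing_mm, first.spacing_mm, atol=1e-6):
            raise ValueError(f"spacing mismatch: {p.spacing_mm} vs {first.spacing_mm}")
    counts = np.zeros(first.shape, dtype=np.int16)
    for p in predictions:
        counts += p.voxels
    return ProbabilityMap(
        counts=counts,
        n_models=len(predictions),
        spacing_mm=first.spacing_mm,
        origin_mm=first.origin_mm,
        patient_id=first.patient_id,
    )


def _count_threshold(level_pct: float, n_models: int) -> int:
    # integer count threshold; tiny epsilon guards float noise in levels
    # like 100/3 so that 33.33...% on K=3 maps to count >= 1, not 2
    return max(1, math.ceil(level_pct * n_models / 100.0 - 1e-9))


def isoprobability_mask(pmap: ProbabilityMap, level_pct: float) -> SegmentationMask:
    """Voxels supported by at least ceil(level * K / 100) models.

    Thresholding happens on integer counts, never on floats, so 100% is
    bit-exactly the model intersection and 100/K% the union.
    """
    if not (0 < level_pct <= 100):
        raise ValueError(f"isoprobability level must be in (0, 100], got {level_pct}")
    threshold = _count_threshold(level_pct, pmap.n_models)
    return SegmentationMask(
        voxels=pmap.counts >= threshold,
        spacing_mm=pmap.spacing_mm,
        origin_mm=pmap.origin_mm,
        patient_id=pmap.patient_id,
        label=f"iso{level_pct:g}",
    )


def default_levels(n_models: int) -> list[float]:
    """Attainable agreement levels 100/K, 200/K, ..., 100 percent."""
    return [100.0 * k / n_models for k in range(1, n_models + 1)]


def isoprobability_set(
    pmap: ProbabilityMap, levels: list[float] | None = None
) -> IsoprobabilitySet:
    """Extract the nested family of isoprobability masks."""
    if levels is None:
        levels = default_levels(pmap.n_models)
    levels = sorted(levels)
    return IsoprobabilitySet(
        levels=levels, masks=[isoprobability_mask(pmap, lv) for lv in levels]
    )


def iso_volume_difference(
    pmap: ProbabilityMap, low_pct: float = 25.0, high_pct: float = 100.0
) -> float:
    """Volume (cm^3) between the low- and high-agreement isoprobability volumes.

    volume(low) - volume(high); non-negative by nesting. This is the
    spatial budget of ensemble disagreement — the region contoured by some
    but not all models.
    """
    if not low_pct < high_pct:
        raise ValueError("low_pct must be smaller than high_pct")
    return volume_cm3(isoprobability_mask(pmap, low_pct)) - volume_cm3(
        isoprobability_mask(pmap, high_pct)
    )
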