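"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths (no
scipy.ndimage, no pooled EDT): surfaces come from explicit neighbor
loops, distances from all-pairs Euclidean computation, percentiles from
the explicit order-statistic interpolation formula.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctveval import CohortConfig, SegmentationMask


def make_mask(
    voxels: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    patient_id: str = "T",
    label: str = "",
) -> SegmentationMask:
    return SegmentationMask(
        voxels=np.asarray(voxels, dtype=bool),
        spacing_mm=spacing,
        patient_id=patient_id,
        label=label,
    )


def cube_mask(shape, lo, hi, spacing=(1.0, 1.0, 1.0)) -> SegmentationMask:
    """Solid axis-aligned cube with corners lo (incl.) .. hi (excl.)."""
    vox = np.zeros(shape, dtype=bool)
    vox[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return make_mask(vox, spacing)


def random_mask(
    rng: np.random.Generator, shape=(12, 12, 12), spacing=(1.0, 1.0, 1.0), p=0.3
) -> SegmentationMask:
    """Random nonempty blob-ish mask (noise + a guaranteed seed voxel)."""
    vox = rng.random(shape) < p
    if not vox.any():
        vox[tuple(rng.integers(0, s) for s in shape)] = True
    return make_mask(vox, spacing)


# ---------------------------------------------------------------- oracles


def oracle_surface_voxels(fg: np.ndarray) -> list[tuple[int, int, int]]:
    """Explicit 6-neighbor surface scan (out-of-lattice = background)."""
    ni, nj, nk = fg.shape
    out = []
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                if not fg[i, j, k]:
                    continue
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    a, b, c = i + di, j + dj, k + dk
                    if not (0 <= a < ni and 0 <= b < nj and 0 <= c < nk) or not fg[a, b, c]:
                        out.append((i, j, k))
                        break
    return out


def oracle_percentile(values: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile from sorted order statistics."""
    s = np.sort(np.asarray(values, dtype=float))
    h = (s.size - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, s.size - 1)
    return float(s[lo] + (h - lo) * (s[hi] - s[lo]))


def oracle_surface_distances(
    ref: SegmentationMask, pred: SegmentationMask
) -> tuple[float, float, float]:
    """All-pairs brute-force symmetric ASD / HD / HD95 in mm."""
    spacing = np.asarray(ref.spacing_mm)
    sa = np.array(oracle_surface_voxels(ref.voxels), dtype=float) * spacing
    sb = np.array(oracle_surface_voxels(pred.voxels), dtype=float) * spacing
    d2 = ((sa[:, None, :] - sb[None, :, :]) ** 2).sum(axis=2)
    d = np.sqrt(d2)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return (
        float(pooled.mean()),
        float(pooled.max()),
        oracle_percentile(pooled, 95.0),
    )


def oracle_components(fg: np.ndarray, connectivity: int = 26) -> list[set]:
    """Exhaustive flood-fill connected components as voxel-index sets."""
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [
            (di, dj, dk)
            for di in (-1, 0, 1)
            for dj in (-1, 0, 1)
            for dk in (-1, 0, 1)
            if (di, dj, dk) != (0, 0, 0)
        ]
    shape = fg.shape
    seen = set()
    comps = []
    for start in zip(*np.nonzero(fg)):
        start = tuple(int(v) for v in start)
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        seen.add(start)
        while stack:
            i, j, k = stack.pop()
            for di, dj, dk in offsets:
                nb = (i + di, j + dj, k + dk)
                if (
                    all(0 <= c < s for c, s in zip(nb, shape))
                    and nb not in seen
                    and fg[nb]
                ):
                    seen.add(nb)
                    comp.add(nb)
                    stack.append(nb)
        comps.append(comp)
    return comps


# ---------------------------------------------------------------- fixtures


def small_cohort_config(seed: int = 0, n_patients: int = 6, **kwargs) -> CohortConfig:
    """Scaled-down cohort: same structure, desk-sized lattice."""
    defaults = dict(
        n_patients=n_patients,
        lattice_shape=(48, 48, 32),
        spacing_mm=(2.0, 2.0, 2.5),
        seed=seed,
    )
    defaults.update(kwargs)
    return CohortConfig(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
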