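"""Synthetic breast-like CTV cohort generator.

Real whole-breast CTV masks and their model predictions are private
clinical data, so the pipeline is exercised on a phantom cohort instead.
Each patient's clinical CTV is a half-ellipsoid flattened on the
chest-wall side (posterior plane clip) with smooth random shape
variation, one connected component, configurable laterality, and a
physical volume drawn from a configurable range. Each of K simulated
"models" produces a prediction by perturbing the clinical mask with a
controlled error profile:

* smooth boundary displacement of a given mm scale (surface noise),
* cranial/caudal extent over/under-shoot in whole slices (the dominant
  clinically observed error mode at the superior-inferior borders),
* occasional small disconnected satellite components (spurious islands
  that post-processing is expected to remove).

Randomness is fully deterministic: one master seed, with per-patient,
per-stream substreams derived through ``numpy`` ``SeedSequence`` spawn
keys ``(patient_index, stream)`` where stream 0 drives patient anatomy
and stream 1+m drives model m's perturbation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .mask import SegmentationMask, write_mask
from .ops import largest_component

__all__ = [
    "ModelProfile",
    "CohortConfig",
    "default_profiles",
    "generate_clinical_ctv",
    "perturb_prediction",
    "generate_cohort_masks",
    "generate_cohort",
]

# reference lattice physical volume against which the default clinical
# volume range (200-1500 cm^3) is defined; smaller lattices scale the
# range proportionally so phantoms keep a realistic fill fraction
_REFERENCE_LATTICE_CM3 = 320 * 160 * 80 * 2.5 / 1000.0  # 10240 cm^3


@dataclass(frozen=True)
class ModelProfile:
    """Error profile of one simulated segmentation model.

    Parameters
    ----------
    boundary_noise_mm : float
        Standard deviation of the smooth surface displacement field, mm.
    cc_bias_slices : (float, float)
        Mean and SD of the per-end cranio-caudal shift in slices;
        positive draws extend the extent (overshoot), negative crop it.
    satellite_prob : float
        Probability of adding one small disconnected component.
    satellite_voxels : (int, int)
        Inclusive size range of the satellite component, in voxels.
    """

    name: str
    boundary_noise_mm: float = 0.0
    cc_bias_slices: tuple[float, float] = (0.0, 0.0)
    satellite_prob: float = 0.0
    satellite_voxels: tuple[int, int] = (20, 80)

    def __post_init__(self) -> None:
        if not (0.0 <= self.satellite_prob <= 1.0):
            raise ValueError("satellite_prob must be in [0, 1]")
        if not np.isfinite(self.boundary_noise_mm) or self.boundary_noise_mm < 0:
            raise ValueError("boundary_noise_mm must be finite and >= 0")


def default_profiles() -> list[ModelProfile]:
    """Four model profiles: three statistically exchangeable, one degraded.

    The three good profiles share identical parameters (independent noise
    realizations), emulating models whose performance differences lie
    within inter-observer variability; their 1.5 mm boundary noise yields
    surface distances in the clinically reported ~1.5 mm regime at 1 mm
    in-plane voxels. The degraded profile (coarser boundary noise, larger
    cranio-caudal bias, frequent satellites) emulates the high-outlier
    model a cohort comparison is expected to single out.
    """
    good = dict(boundary_noise_mm=1.5, cc_bias_slices=(0.0, 2.0), satellite_prob=0.05)
    return [
        ModelProfile("modelA", **good),
        ModelProfile("modelB", **good),
        ModelProfile("modelC", **good),
        ModelProfile("modelD", boundary_noise_mm=3.0, cc_bias_slices=(2.0, 3.0), satellite_prob=0.4),
    ]


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation parameters.

    The default spacing is (1, 1, 2.5) mm (in-plane CT resolution with
    2.5 mm slices); the default clinical volume range 200-1500 cm^3 is
    defined at the default lattice and scales with the physical lattice
    volume, so scaled-down lattices produce proportionally smaller
    phantoms with the same fill fraction.
    """

    n_patients: int = 20
    lattice_shape: tuple[int, int, int] = (320, 160, 80)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.5)
    laterality_mix: float = 0.5  # fraction of left-sided cases
    volume_range_cm3: tuple[float, float] = (200.0, 1500.0)
    scale_volume_to_lattice: bool = True
    profiles: tuple[ModelProfile, ...] = field(default_factory=lambda: tuple(default_profiles()))
    clinician_groups: tuple[tuple[str, float], ...] = (
        ("A", 13), ("G", 11), ("I", 27), ("M", 16), ("N", 24),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if len(self.profiles) < 2:
            raise ValueError("need at least 2 model profiles")
        if not (0.0 <= self.laterality_mix <= 1.0):
            raise ValueError("laterality_mix must be in [0, 1]")

    @property
    def lattice_volume_cm3(self) -> float:
        ni, nj, nk = self.lattice_shape
        dx, dy, dz = self.spacing_mm
        return ni * nj * nk * dx * dy * dz / 1000.0

    def effective_volume_range_cm3(self) -> tuple[float, float]:
        lo, hi = self.volume_range_cm3
        if self.scale_volume_to_lattice:
            factor = self.lattice_volume_cm3 / _REFERENCE_LATTICE_CM3
            return lo * factor, hi * factor
        return lo, hi


def _rng(config_seed: int, patient_index: int, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config_seed, spawn_key=(patient_index, stream))
    return np.random.default_rng(ss)


def _model_seed(config_seed: int, patient_index: int, model_index: int) -> int:
    ss = np.random.SeedSequence(entropy=config_seed, spawn_key=(patient_index, 1 + model_index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _smooth_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    correlation_mm: float,
) -> np.ndarray:
    """Unit-variance Gaussian random field with a given correlation length."""
    white = rng.standard_normal(shape)
    sigma_vox = [max(correlation_mm / s, 0.5) for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return smooth / sd


def _mm_grids(
    shape: tuple[int, int, int], spacing: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def generate_clinical_ctv(config: CohortConfig, patient_index: int) -> SegmentationMask:
    """One patient's clinical CTV phantom.

    Deterministic given (config.seed, patient_index). The mask is a single
    connected component; a left-sided case has its centroid in the
    ``i < ni/2`` half of the lattice.
    """
    rng = _rng(config.seed, patient_index, 0)
    shape = tuple(config.lattice_shape)
    spacing = tuple(config.spacing_mm)
    extents = [n * s for n, s in zip(shape, spacing)]  # physical mm
    li, lj, lk = extents

    left_sided = bool(rng.random() < config.laterality_mix)
    lo, hi = config.effective_volume_range_cm3()
    target_mm3 = rng.uniform(lo, hi) * 1000.0

    # half-ellipsoid radii: product constrained by the target volume,
    # per-axis caps keep the phantom inside the lattice and on its side
    product = target_mm3 * 3.0 / (2.0 * np.pi)  # = ra * rb * rc
    caps = np.array([0.23 * li, 0.70 * lj, 0.45 * lk])
    ratios = np.array([1.0, 1.1, 0.95]) * np.exp(rng.normal(0.0, 0.12, size=3))
    radii = ratios * (product / ratios.prod()) ** (1.0 / 3.0)
    locked = np.zeros(3, dtype=bool)
    for _ in range(3):  # clamp oversized radii, push product to free axes
        over = (radii > caps) & ~locked
        if not over.any():
            break
        radii[over] = caps[over]
        locked |= over
        free = ~locked
        if free.any():
            radii[free] *= (product / radii.prod()) ** (1.0 / free.sum())
    if (radii > caps * (1 + 1e-9)).any() or radii.prod() < 0.999 * product:
        raise ValueError(
            f"lattice too small for requested volume {target_mm3 / 1000.0:.0f} cm^3"
        )
    ra, rb, rc = radii

    # center: lateral per laterality, chest wall posterior, mid cranio-caudal
    dx = spacing[0]
    if left_sided:
        ci = 0.25 * li + rng.normal(0.0, 0.02 * li)
        ci = float(np.clip(ci, ra + dx, 0.5 * li - dx))
    else:
        ci = 0.75 * li + rng.normal(0.0, 0.02 * li)
        ci = float(np.clip(ci, 0.5 * li + dx, li - ra - dx))
    wall_j = rng.uniform(0.12, 0.22) * lj
    ck = 0.5 * lk + rng.normal(0.0, 0.04 * lk)
    ck = float(np.clip(ck, rc + spacing[2], lk - rc - spacing[2]))

    ii, jj, kk = _mm_grids(shape, spacing)
    implicit = (
        1.0
        - ((ii - ci) / ra) ** 2
        - ((jj - wall_j) / rb) ** 2
        - ((kk - ck) / rc) ** 2
    )
    # smooth shape variation on the implicit surface (~5% radius warp)
    implicit = implicit + 0.08 * _smooth_field(rng, shape, spacing, correlation_mm=0.15 * max(ra, rc))
    voxels = (implicit > 0.0) & (np.broadcast_to(jj >= wall_j, shape))
    mask = SegmentationMask(
        voxels=voxels,
        spacing_mm=spacing,
        patient_id=f"P{patient_index:03d}",
        label="clinical",
    )
    if mask.is_empty():
        raise ValueError("lattice too small for requested volume (empty phantom)")
    return largest_component(mask)


def _shift_end(voxels: np.ndarray, shift: int, end: str) -> np.ndarray:
    """Extend (shift > 0) or crop (shift < 0) one cranio-caudal end.

    Extension replicates the boundary slice outward, emulating a model
    that keeps contouring beyond the true extent.
    """
    if shift == 0 or not voxels.any():
        return voxels
    out = voxels.copy()
    per_slice = np.any(out, axis=(0, 1))
    nz = np.flatnonzero(per_slice)
    z_first, z_last = int(nz[0]), int(nz[-1])
    nk = out.shape[2]
    if end == "cranial":
        if shift > 0:
            for t in range(1, shift + 1):
                if z_last + t < nk:
                    out[:, :, z_last + t] = out[:, :, z_last]
        else:
            out[:, :, max(z_last + shift + 1, 0):] = False
    else:  # caudal
        if shift > 0:
            for t in range(1, shift + 1):
                if z_first - t >= 0:
                    out[:, :, z_first - t] = out[:, :, z_first]
        else:
            out[:, :, : min(z_first - shift, nk)] = False
    return out


def _add_satellite(
    voxels: np.ndarray,
    spacing: tuple[float, float, float],
    n_target: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Place a small ellipsoidal blob disconnected from the main mask."""
    shape = voxels.shape
    # forbidden zone: main mask dilated by 2 voxels (26-connectivity margin)
    forbidden = ndimage.binary_dilation(
        voxels, structure=ndimage.generate_binary_structure(3, 3), iterations=2
    )
    r_vox = max((3.0 * n_target / (4.0 * np.pi)) ** (1.0 / 3.0), 1.0)
    radii_vox = np.maximum(r_vox / np.array([1.0, 1.0, spacing[2] / spacing[0]]), 1.0)
    margins = np.ceil(radii_vox).astype(int) + 1
    for _ in range(20):
        center = [int(rng.integers(m, s - m)) if s > 2 * m else s // 2 for m, s in zip(margins, shape)]
        ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij", sparse=True)
        blob = (
            ((ii - center[0]) / radii_vox[0]) ** 2
            + ((jj - center[1]) / radii_vox[1]) ** 2
            + ((kk - center[2]) / radii_vox[2]) ** 2
        ) <= 1.0
        if not (blob & forbidden).any() and blob.any():
            return voxels | blob
    return voxels  # no disconnected placement found; leave unchanged


def _signed_distance_mm(
    voxels: np.ndarray, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Negative inside the mask, positive outside, in mm."""
    outside = ndimage.distance_transform_edt(~voxels, sampling=spacing)
    inside = ndimage.distance_transform_edt(voxels, sampling=spacing)
    return outside - inside


def _apply_profile(
    ctv: SegmentationMask,
    profile: ModelProfile,
    rng: np.random.Generator,
    sdist: np.ndarray | None = None,
) -> SegmentationMask:
    voxels = ctv.voxels
    spacing = ctv.spacing_mm
    if profile.boundary_noise_mm > 0:
        noise = profile.boundary_noise_mm * _smooth_field(
            rng, voxels.shape, spacing, correlation_mm=10.0
        )
        if sdist is None:
            sdist = _signed_distance_mm(voxels, spacing)
        voxels = sdist < noise
    mean, sd = profile.cc_bias_slices
    if mean != 0 or sd != 0:
        cranial = int(np.rint(rng.normal(mean, sd)))
        caudal = int(np.rint(rng.normal(mean, sd)))
        voxels = _shift_end(voxels, cranial, "cranial")
        voxels = _shift_end(voxels, caudal, "caudal")
    if profile.satellite_prob > 0 and rng.random() < profile.satellite_prob:
        lo, hi = profile.satellite_voxels
        n_target = int(rng.integers(lo, hi + 1))
        voxels = _add_satellite(voxels, spacing, n_target, rng)
    return ctv.with_voxels(voxels, label=profile.name)


def perturb_prediction(
    ctv: SegmentationMask,
    profile: ModelProfile,
    seed: int,
    *,
    _sdist: np.ndarray | None = None,
) -> SegmentationMask:
    """Simulate one model's prediction for a clinical CTV.

    Deterministic given ``seed``. An all-zero profile returns a mask
    identical to the input. A perturbation that empties the mask is
    resampled once; a second empty draw raises. ``_sdist`` optionally
    carries a precomputed signed distance field of the clinical mask so
    cohort generation computes it once per patient.
    """
    if ctv.is_empty():
        raise ValueError("cannot perturb an empty clinical mask")
    if _sdist is None and profile.boundary_noise_mm > 0:
        _sdist = _signed_distance_mm(ctv.voxels, ctv.spacing_mm)
    rng = np.random.default_rng(seed)
    pred = _apply_profile(ctv, profile, rng, sdist=_sdist)
    if pred.is_empty():
        pred = _apply_profile(ctv, profile, rng, sdist=_sdist)
        if pred.is_empty():
            raise ValueError(
                f"profile {profile.name!r} emptied the mask twice (seed {seed})"
            )
    return pred


def _patient_attributes(config: CohortConfig, patient_index: int) -> dict:
    rng = _rng(config.seed, patient_index, 0)
    left_sided = bool(rng.random() < config.laterality_mix)
    groups = [g for g, _ in config.clinician_groups]
    weights = np.array([w for _, w in config.clinician_groups], dtype=float)
    # independent draw stream for the clinician label
    grp_rng = _rng(config.seed, patient_index, 10_000)
    group = str(grp_rng.choice(groups, p=weights / weights.sum()))
    return {
        "patient_id": f"P{patient_index:03d}",
        "laterality": "left" if left_sided else "right",
        "clinician_group": group,
    }


def generate_cohort_masks(
    config: CohortConfig,
) -> list[dict]:
    """Generate the cohort in memory.

    Returns one record per patient with keys ``patient_id``,
    ``clinician_group``, ``laterality``, ``clinical``
    (:class:`SegmentationMask`) and ``predictions`` (dict model name ->
    mask). Fully deterministic given the config seed.
    """
    records = []
    for idx in range(config.n_patients):
        attrs = _patient_attributes(config, idx)
        clinical = generate_clinical_ctv(config, idx)
        sdist = None
        if any(p.boundary_noise_mm > 0 for p in config.profiles):
            sdist = _signed_distance_mm(clinical.voxels, clinical.spacing_mm)
        predictions = {}
        for m, profile in enumerate(config.profiles):
            seed = _model_seed(config.seed, idx, m)
            predictions[profile.name] = perturb_prediction(
                clinical, profile, seed, _sdist=sdist
            )
        records.append({**attrs, "clinical": clinical, "predictions": predictions})
    return records


def generate_cohort(config: CohortConfig, out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write the cohort as NIfTI masks plus a manifest CSV.

    The manifest has one row per mask file: patient_id, clinician_group,
    laterality, label ("clinical" or a model name), path (relative to the
    manifest), and the substream seed used. Re-running with the same seed
    reproduces identical files and manifest.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for idx in range(config.n_patients):
        attrs = _patient_attributes(config, idx)
        pid = attrs["patient_id"]
        clinical = generate_clinical_ctv(config, idx)
        fname = f"{pid}_clinical.nii.gz"
        write_mask(clinical, os.path.join(out_dir, fname))
        rows.append({**attrs, "label": "clinical", "path": fname, "seed": config.seed})
        sdist = None
        if any(p.boundary_noise_mm > 0 for p in config.profiles):
            sdist = _signed_distance_mm(clinical.voxels, clinical.spacing_mm)
        for m, profile in enumerate(config.profiles):
            seed = _model_seed(config.seed, idx, m)
            pred = perturb_prediction(clinical, profile, seed, _sdist=sdist)
            fname = f"{pid}_{profile.name}.nii.gz"
            write_mask(pred, os.path.join(out_dir, fname))
            rows.append({**attrs, "label": profile.name, "path": fname, "seed": seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
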