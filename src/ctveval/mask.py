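"""Binary segmentation masks on a regular 3-D voxel lattice.

A :class:`SegmentationMask` couples a boolean voxel array with its physical
geometry (voxel spacing and origin in mm).  The third lattice axis ``k`` is
the cranio-caudal (superior-inferior) axis, with increasing ``k`` pointing
cranially; this matches the dominant RAS/superior-positive NIfTI layout.
Voxel centers sit at ``origin + index * spacing`` with 0-based indices.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["SegmentationMask", "read_mask", "write_mask"]


@dataclass
class SegmentationMask:
    """A 3-D binary mask with physical voxel geometry.

    Parameters
    ----------
    voxels : ndarray of bool, shape (ni, nj, nk)
        Foreground lattice. Axis ``k`` (last) is cranio-caudal.
    spacing_mm : tuple of float
        Voxel spacing ``(dx, dy, dz)`` in mm; ``dz`` is the slice thickness
        along the cranio-caudal axis. All components must be positive.
    origin_mm : tuple of float
        Physical position of voxel (0, 0, 0), in mm.
    patient_id, label : str
        Free-form identifiers (e.g. label ``"clinical"`` or a model name).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    patient_id: str = ""
    label: str = field(default="")

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {vox.ndim}-D")
        if min(vox.shape) < 1:
            raise ValueError("lattice must have at least one voxel per axis")
        if vox.dtype != bool:
            uniq = np.unique(vox)
            if uniq.size > 2:
                raise ValueError("mask voxels must be two-valued")
            vox = vox > 0
        self.voxels = vox
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing_mm}")
        self.spacing_mm = spacing
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz

    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def with_voxels(self, voxels: np.ndarray, *, label: str | None = None) -> "SegmentationMask":
        """Copy of this mask with new voxels on the same geometry."""
        out = replace(self, voxels=np.asarray(voxels, dtype=bool))
        if label is not None:
            out.label = label
        return out

    def same_grid(self, other: "SegmentationMask", *, atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing_mm, other.spacing_mm, atol=atol
        )


def _require_same_grid(a: SegmentationMask, b: SegmentationMask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"lattice shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing_mm, b.spacing_mm, atol=1e-6):
        raise ValueError(f"spacing mismatch: {a.spacing_mm} vs {b.spacing_mm}")


def read_mask(path: str | os.PathLike, *, patient_id: str = "", label: str = "") -> SegmentationMask:
    """Load a NIfTI volume as a binary mask.

    Any voxel with value > 0 becomes foreground (tolerant of 0/1 and 0/255
    encodings). Spacing is taken from the header zooms and the origin from
    the affine translation.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D in {path}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel spacing {zooms} in {path}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return SegmentationMask(
        voxels=data > 0,
        spacing_mm=zooms,
        origin_mm=origin,
        patient_id=patient_id,
        label=label,
    )


def write_mask(mask: SegmentationMask, path: str | os.PathLike) -> None:
    """Write a mask as an uint8 NIfTI volume (0 = background, 1 = foreground).

    The affine is diagonal with the voxel spacing and carries the origin, so
    ``read_mask(write_mask(m))`` reproduces voxels, shape, and spacing (the
    latter to NIfTI-1 float32 header precision).
    """
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    affine = np.diag([*mask.spacing_mm, 1.0])
    affine[:3, 3] = mask.origin_mm
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))


def write_float_volume(
    values: np.ndarray,
    spacing_mm: tuple[float, float, float],
    path: str | os.PathLike,
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> None:
    """Write a floating-point 3-D field (e.g. an agreement map) as NIfTI."""
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    affine = np.diag([*spacing_mm, 1.0])
    affine[:3, 3] = origin_mm
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))
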