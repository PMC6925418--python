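"""Core spatial containers: 3D image volumes and binary VOI masks.

Arrays are indexed ``[x, y, z]``; axial slices are ``voxels[:, :, k]``.
Spacing is in millimetres, ordered like the array axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: Canonical delineation-variant tags, in increasing order of volume change.
VARIANTS = ("baseline", "erosion", "smoothing", "dilation3", "dilation5", "dilation7")


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar image with voxel spacing and world origin."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float64)
        if vox.ndim != 3:
            raise ValueError(f"image must be 3D, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("image contains non-finite values")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        return replace(self, voxels=voxels)


@dataclass(frozen=True)
class VoiMask:
    """Binary 3D mask aligned voxel-for-voxel to an :class:`ImageVolume`.

    ``variant`` tags the delineation the mask represents (see :data:`VARIANTS`).
    ``empty_after_perturbation`` flags masks emptied by erosion so downstream
    stages can refuse them explicitly instead of failing obscurely.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    variant: str = "baseline"
    empty_after_perturbation: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {vox.shape}")
        vox = vox.astype(bool)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    def check_aligned(self, image: ImageVolume) -> None:
        if self.shape != image.shape:
            raise ValueError(f"mask shape {self.shape} != image shape {image.shape}")
        if not np.allclose(self.spacing_mm, image.spacing_mm):
            raise ValueError(
                f"mask spacing {self.spacing_mm} != image spacing {image.spacing_mm}"
            )


def _affine(spacing_mm, origin_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def save_image(image: ImageVolume, path: str | Path) -> Path:
    """Write an :class:`ImageVolume` as NIfTI with spacing in the header."""
    path = Path(path)
    img = nib.Nifti1Image(image.voxels.astype(np.float32), _affine(image.spacing_mm, image.origin_mm))
    img.header.set_zooms(image.spacing_mm)
    nib.save(img, str(path))
    return path


def save_mask(mask: VoiMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.spacing_mm))
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))
    return path


def load_image(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(np.asanyarray(img.dataobj).astype(np.float64), spacing, origin)


def load_mask(path: str | Path, variant: str = "baseline") -> VoiMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoiMask(np.asanyarray(img.dataobj) > 0.5, spacing, variant=variant)
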