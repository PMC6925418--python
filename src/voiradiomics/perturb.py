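"""Slice-wise VOI delineation variants and their geometric comparison.

A baseline radiologist mask is perturbed slice by slice (axial planes) to
emulate systematic delineation differences:

- ``erode`` / ``dilate`` with an exact Euclidean disk structuring element
  ``{(dx, dy): dx^2 + dy^2 <= r^2}`` (erosion radius 3; dilation 3, 5 or 7);
- ``smooth`` with a 2D Gaussian correlation filter (sigma 3 px, 7x7 window,
  replicate border) followed by re-binarization at 0.5, so a constant slice
  is a fixed point.

An exact disk is used rather than an octagonal approximation so the result
is oracle-checkable (a single voxel dilated with r=3 has exactly 29 pixels);
toolboxes defaulting to approximated disks will differ slightly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import VoiMask

#: The five standard perturbations, keyed by variant tag.
STANDARD_PERTURBATIONS = {
    "erosion": ("erode", 3),
    "smoothing": ("smooth", 3),
    "dilation3": ("dilate", 3),
    "dilation5": ("dilate", 5),
    "dilation7": ("dilate", 7),
}


@dataclass(frozen=True)
class PerturbationSpec:
    """One morphological operation: erode/dilate radius in pixels, or Gaussian
    smoothing with the given sigma (window size is fixed at 7x7)."""

    operation: str  # {"erode", "dilate", "smooth"}
    radius_px: int = 3
    sigma_px: float = 3.0
    kernel_size: int = 7

    def __post_init__(self) -> None:
        if self.operation not in ("erode", "dilate", "smooth"):
            raise ValueError(f"unknown operation {self.operation!r}")
        if self.operation != "smooth" and self.radius_px < 1:
            raise ValueError("radius must be a positive integer")

    @property
    def variant_tag(self) -> str:
        if self.operation == "erode":
            return "erosion"
        if self.operation == "smooth":
            return "smoothing"
        return f"dilation{self.radius_px}"


def disk_element(radius: int) -> np.ndarray:
    """Exact Euclidean disk: offsets with dx^2 + dy^2 <= r^2."""
    r = int(radius)
    dx, dy = np.mgrid[-r : r + 1, -r : r + 1]
    return (dx**2 + dy**2) <= r**2


def gaussian_kernel_2d(sigma: float, size: int) -> np.ndarray:
    """Normalized 2D Gaussian kernel on a size x size window (MATLAB
    ``fspecial('gaussian')`` convention)."""
    half = (size - 1) / 2.0
    ax = np.arange(size) - half
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma**2))
    return g / g.sum()


def perturb_mask(mask: VoiMask, spec: PerturbationSpec) -> VoiMask:
    """Apply one perturbation independently to every axial slice.

    Slices with empty baseline foreground stay empty.  If erosion empties
    every slice the returned mask carries ``empty_after_perturbation=True``;
    downstream stages must refuse such masks explicitly.
    """
    if mask.is_empty:
        raise ValueError("baseline mask is empty")
    vox = mask.voxels

    if spec.operation in ("erode", "dilate"):
        # one 3D call with a flat (in z) footprint == independent slice-wise 2D op
        selem = disk_element(spec.radius_px)[:, :, None]
        if spec.operation == "dilate":
            out = ndimage.binary_dilation(vox, structure=selem)
        else:
            out = ndimage.binary_erosion(vox, structure=selem)
    else:
        kernel = gaussian_kernel_2d(spec.sigma_px, spec.kernel_size)[:, :, None]
        smoothed = ndimage.correlate(vox.astype(np.float64), kernel, mode="nearest")
        out = smoothed >= 0.5

    # guard: slice-wise ops must not create foreground on originally empty slices
    empty_slices = ~np.any(vox, axis=(0, 1))
    out[:, :, empty_slices] = False

    return VoiMask(
        out,
        mask.spacing_mm,
        variant=spec.variant_tag,
        empty_after_perturbation=not out.any(),
    )


def make_variants(baseline: VoiMask, perturbations=None) -> dict[str, VoiMask]:
    """Baseline plus the five standard delineation variants (or a subset)."""
    perturbations = perturbations or list(STANDARD_PERTURBATIONS)
    out = {"baseline": baseline}
    for tag in perturbations:
        op, radius = STANDARD_PERTURBATIONS[tag]
        spec = PerturbationSpec(operation=op, radius_px=radius)
        out[tag] = perturb_mask(baseline, spec)
    return out


def volume_ratio(perturbed: VoiMask, baseline: VoiMask) -> float:
    """Foreground voxel count of the perturbed mask over the baseline's."""
    if perturbed.shape != baseline.shape:
        raise ValueError("masks must share a voxel grid")
    n_base = baseline.voxel_count
    if n_base == 0:
        raise ValueError("baseline mask is empty")
    return perturbed.voxel_count / n_base


def _slice_bbox(sl: np.ndarray) -> tuple[int, int, int, int]:
    xs, ys = np.nonzero(sl)
    return xs.min(), xs.max(), ys.min(), ys.max()


def margin_distances(mask_a: VoiMask, mask_b: VoiMask) -> list[tuple[int, int, int, int]]:
    """Per-slice bounding-rectangle margin distances between two delineations.

    For every axial slice where both masks have foreground, fit each mask's
    smallest axis-aligned rectangle and return the absolute differences of
    the four edges as ``(up, down, left, right)`` in pixels (up/down = low/high
    edge along the second array axis, left/right along the first).  Values are
    pooled across slices for histogram/heatmap reporting.
    """
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share a voxel grid")
    occ_a = np.any(mask_a.voxels, axis=(0, 1))
    occ_b = np.any(mask_b.voxels, axis=(0, 1))
    common = np.nonzero(occ_a & occ_b)[0]
    if common.size == 0:
        raise ValueError("no slice where both masks have foreground")
    out = []
    for z in common:
        ax0, ax1, ay0, ay1 = _slice_bbox(mask_a.voxels[:, :, z])
        bx0, bx1, by0, by1 = _slice_bbox(mask_b.voxels[:, :, z])
        up, down = abs(int(ay0 - by0)), abs(int(ay1 - by1))
        left, right = abs(int(ax0 - bx0)), abs(int(ax1 - bx1))
        out.append((up, down, left, right))
    return out
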