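"""Synthetic two-class 3D lesion cohorts.

Generates grayscale volumes plus binary VOI masks in which the two classes
(non-metastasizing, NM = 0; metastasizing, TM = 1) differ in intra-lesion
texture correlation length and/or mean intensity, at configurable effect
size.  Lesions are star-convex blobs delineated per axial slice with a
smoothly varying radial profile, mimicking slice-wise manual segmentation;
voxel spacing is anisotropic by default (thicker slices than in-plane).

The generator is fully deterministic given ``CohortSpec.seed``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, VoiMask, save_image, save_mask

#: margin (voxels) reserved around the lesion so a radius-7 dilation never clips
PERTURBATION_MARGIN = 7


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-class cohort.

    ``texture_effect`` is the class difference in intra-lesion correlation
    length (voxels); ``intensity_effect`` the class difference in mean lesion
    intensity in units of ``noise_sd``.  With both at zero the classes are
    exchangeable and any downstream classifier is at chance.
    """

    n_per_class: int = 30
    image_shape: tuple[int, int, int] = (64, 64, 28)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    lesion_radius_range_vox: tuple[float, float] = (7.0, 11.0)
    boundary_irregularity: float = 0.25
    texture_effect: float = 0.0
    intensity_effect: float = 0.0
    noise_sd: float = 1.0
    base_correlation_length_vox: float = 1.0
    lesion_contrast: float = 4.0
    background_level: float = 10.0
    texture_sd: float = 2.0
    validation_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing components must be positive")
        lo, hi = self.lesion_radius_range_vox
        if not (0 < lo <= hi):
            raise ValueError("lesion_radius_range_vox must be a positive interval")
        if self.boundary_irregularity < 0 or self.noise_sd < 0:
            raise ValueError("irregularity and noise_sd must be non-negative")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must lie in (0, 1)")
        margin = hi * (1.0 + self.boundary_irregularity) + PERTURBATION_MARGIN + 1
        nx, ny, _ = self.image_shape
        if 2 * margin >= min(nx, ny):
            raise ValueError(
                f"lesion (max radius {hi}, irregularity {self.boundary_irregularity}) "
                f"cannot fit inside image shape {self.image_shape} with the required "
                f"margin of {PERTURBATION_MARGIN} voxels for perturbation"
            )


@dataclass(frozen=True)
class SyntheticCase:
    subject_id: str
    class_label: int  # 0 = NM, 1 = TM
    image: ImageVolume
    mask: VoiMask
    split: str  # "training" | "validation"


def _star_convex_mask(shape, center, base_radius, half_height_slices, irregularity, rng):
    """Per-slice star-convex lesion with a smooth radial perturbation.

    The radial function at slice z is ``r_z * (1 + irregularity * f(theta, z))``
    where ``r_z`` traces an ellipsoidal profile across slices and ``f`` is a
    band-limited Fourier series whose coefficients drift smoothly with z, so
    the mask is connected in 3D and each occupied slice is star-convex.
    """
    nx, ny, nz = shape
    cx, cy, cz = center
    mask = np.zeros(shape, dtype=bool)

    n_modes = 4  # low-order angular modes: smooth, clearly non-circular outlines
    amp = rng.normal(size=(2, n_modes, 2))  # (cos/sin, mode, z-endpoint)
    norm = np.sqrt((amp**2).sum(axis=(0, 1), keepdims=True) / 2.0)
    amp = amp / np.maximum(norm, 1e-12)

    xs = np.arange(nx)[:, None] - cx
    ys = np.arange(ny)[None, :] - cy
    rho = np.hypot(xs, ys)
    theta = np.arctan2(ys, xs)
    modes = np.arange(1, n_modes + 1)

    z0, z1 = int(np.floor(cz - half_height_slices)), int(np.ceil(cz + half_height_slices))
    for z in range(max(z0, 0), min(z1 + 1, nz)):
        frac = 1.0 - ((z - cz) / half_height_slices) ** 2
        if frac <= 0:
            continue
        r_z = base_radius * np.sqrt(frac)
        if r_z < 1.5:  # too thin to hold a voxel reliably: stop the lesion here
            continue
        t = (z - z0) / max(z1 - z0, 1)
        a = amp[..., 0] * (1 - t) + amp[..., 1] * t
        f = np.zeros_like(theta)
        for k, m in enumerate(modes):
            f += a[0, k] * np.cos(m * theta) + a[1, k] * np.sin(m * theta)
        f /= np.sqrt(n_modes)  # unit-variance angular perturbation
        radius = r_z * np.clip(1.0 + irregularity * f, 0.2, None)
        mask[:, :, z] = rho <= radius
    return mask


def _correlated_field(shape, correlation_length, rng):
    """Zero-mean unit-variance Gaussian random field with the given
    correlation length (voxels): white noise smoothed by a Gaussian kernel."""
    white = rng.standard_normal(shape)
    if correlation_length <= 0:
        return white
    f = ndimage.gaussian_filter(white, sigma=correlation_length, mode="wrap")
    sd = f.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _make_case(spec: CohortSpec, label: int, idx: int, rng: np.random.Generator) -> tuple:
    nx, ny, nz = spec.image_shape
    lo, hi = spec.lesion_radius_range_vox
    base_radius = rng.uniform(lo, hi)
    margin = hi * (1.0 + spec.boundary_irregularity) + PERTURBATION_MARGIN + 1

    cx = rng.uniform(margin, nx - margin)
    cy = rng.uniform(margin, ny - margin)
    # through-plane half-height: physical half-height ~ in-plane radius
    half_height = max(base_radius * spec.spacing_mm[0] / spec.spacing_mm[2], 1.5)
    cz = rng.uniform(half_height + 1, nz - half_height - 2)

    mask_vox = _star_convex_mask(
        spec.image_shape, (cx, cy, cz), base_radius, half_height,
        spec.boundary_irregularity, rng,
    )
    if not mask_vox.any():
        raise RuntimeError("generated lesion is empty; spec radii too small")

    corr_len = spec.base_correlation_length_vox + label * spec.texture_effect
    lesion_mean = (
        spec.background_level
        + spec.lesion_contrast * spec.noise_sd
        + label * spec.intensity_effect * spec.noise_sd
    )
    field3d = _correlated_field(spec.image_shape, corr_len, rng)
    image = np.full(spec.image_shape, spec.background_level, dtype=np.float64)
    image[mask_vox] = lesion_mean + spec.texture_sd * spec.noise_sd * field3d[mask_vox]
    image += spec.noise_sd * rng.standard_normal(spec.image_shape)
    return image, mask_vox


def generate_cohort(spec: CohortSpec) -> list[SyntheticCase]:
    """Generate ``2 * n_per_class`` cases with a stratified training/validation
    split at ``spec.validation_fraction`` (validation share per class)."""
    ss = np.random.SeedSequence(spec.seed)
    case_seeds = ss.spawn(2 * spec.n_per_class + 1)
    split_rng = np.random.default_rng(case_seeds[-1])

    cases: list[SyntheticCase] = []
    for label in (0, 1):
        n_val = int(round(spec.validation_fraction * spec.n_per_class))
        n_val = min(max(n_val, 1), spec.n_per_class - 1) if spec.n_per_class > 1 else 0
        order = split_rng.permutation(spec.n_per_class)
        val_idx = set(order[:n_val].tolist())
        for i in range(spec.n_per_class):
            rng = np.random.default_rng(case_seeds[label * spec.n_per_class + i])
            image, mask_vox = _make_case(spec, label, i, rng)
            subject = f"{'NM' if label == 0 else 'TM'}{i:03d}"
            cases.append(
                SyntheticCase(
                    subject_id=subject,
                    class_label=label,
                    image=ImageVolume(image, spec.spacing_mm),
                    mask=VoiMask(mask_vox, spec.spacing_mm, variant="baseline"),
                    split="validation" if i in val_idx else "training",
                )
            )
    return cases


def write_cohort(cases: list[SyntheticCase], out_dir: str | Path) -> Path:
    """Write one NIfTI image + mask per case plus a CSV manifest.

    Returns the manifest path.  Layout: ``<subject>_image.nii.gz`` and
    ``<subject>_mask_baseline.nii.gz`` under ``out_dir``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {out_dir}: {exc}") from exc

    manifest = out_dir / "manifest.csv"
    rows = []
    for case in cases:
        img_path = out_dir / f"{case.subject_id}_image.nii.gz"
        mask_path = out_dir / f"{case.subject_id}_mask_baseline.nii.gz"
        try:
            save_image(case.image, img_path)
            save_mask(case.mask, mask_path)
        except OSError as exc:
            raise OSError(f"failed writing case {case.subject_id} to {out_dir}: {exc}") from exc
        rows.append(
            dict(subject_id=case.subject_id, label=case.class_label,
                 split=case.split, image=img_path.name, mask=mask_path.name)
        )
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["subject_id", "label", "split", "image", "mask"])
        writer.writeheader()
        writer.writerows(rows)
    return manifest
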