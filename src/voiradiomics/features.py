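"""Radiomics feature extraction: 4 geometric + 43 texture features per
extraction-parameter combination.

The default grid crosses 4 isotropic voxel sizes (1, 2, 3, 4 mm), 3 gray-level
quantization algorithms (equal-frequency, uniform-width, Lloyd-Max) and 4
gray-level counts (8, 16, 32, 64): 48 combinations x 43 texture features
= 2064 texture features, plus geometry = a 2068-long vector per VOI.

Feature names follow ``<family>.<feature>.s<scale>.<algo>.g<Ng>`` for texture
and ``geometry.<feature>`` for the four shape features; the order is
deterministic (geometry first, then scale-major grid order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import convex_hull_image

from .texture import (GLCM_FEATURES, GLOBAL_FEATURES, GLRLM_FEATURES, GLSZM_FEATURES,
                      N_TEXTURE_FEATURES, NGTDM_FEATURES, build_texture_matrices,
                      quantize, texture_features)
from .volume import ImageVolume, VoiMask

GEOMETRY_FEATURES = ("volume_mm3", "size_mm", "solidity", "eccentricity")


@dataclass(frozen=True)
class ExtractionGrid:
    """The three extraction parameters crossed into a full grid."""

    scales_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    quant_algorithms: tuple[str, ...] = ("equal", "uniform", "lloyd")
    gray_levels: tuple[int, ...] = (8, 16, 32, 64)

    def __post_init__(self) -> None:
        if not (self.scales_mm and self.quant_algorithms and self.gray_levels):
            raise ValueError("grid axes must be nonempty")
        if any(s <= 0 for s in self.scales_mm):
            raise ValueError("scales must be positive")
        if any(g < 2 for g in self.gray_levels):
            raise ValueError("gray levels must be >= 2")

    @property
    def n_combinations(self) -> int:
        return len(self.scales_mm) * len(self.quant_algorithms) * len(self.gray_levels)

    @property
    def n_features(self) -> int:
        return len(GEOMETRY_FEATURES) + self.n_combinations * N_TEXTURE_FEATURES

    def combinations(self):
        for scale in self.scales_mm:
            for algo in self.quant_algorithms:
                for ng in self.gray_levels:
                    yield scale, algo, ng

    def feature_names(self) -> list[str]:
        names = [f"geometry.{f}" for f in GEOMETRY_FEATURES]
        for scale, algo, ng in self.combinations():
            suffix = f"s{scale:g}.{algo}.g{ng}"
            for fam, feats in (
                ("global", GLOBAL_FEATURES), ("glcm", GLCM_FEATURES),
                ("glrlm", GLRLM_FEATURES), ("glszm", GLSZM_FEATURES),
                ("ngtdm", NGTDM_FEATURES),
            ):
                names.extend(f"{fam}.{f}.{suffix}" for f in feats)
        return names


def geometric_features(mask: VoiMask) -> dict[str, float]:
    """Tumor volume (mm^3), size (longest ellipsoid axis, mm), solidity and
    eccentricity from the native-resolution mask.

    Size and eccentricity come from the PCA-fitted inertia ellipsoid of the
    voxel-center point cloud in physical coordinates (for a uniform ellipsoid
    the covariance eigenvalue is ``a^2/5`` for semi-axis ``a``, so the full
    longest axis is ``2 * sqrt(5 * lambda_max)``).  Solidity is mask volume
    over the voxelized 3D convex-hull volume; with fewer than 4 non-coplanar
    voxels the hull is undefined and solidity is reported as 1 with a warning.
    """
    if mask.is_empty:
        raise ValueError("empty mask")
    coords = np.argwhere(mask.voxels).astype(np.float64)
    coords_mm = coords * np.asarray(mask.spacing_mm)
    n = coords.shape[0]
    voxvol = float(np.prod(mask.spacing_mm))
    volume = n * voxvol

    if n >= 2:
        cov = np.cov(coords_mm, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(cov))
        lam_min, lam_max = max(eigvals[0], 0.0), max(eigvals[-1], 0.0)
    else:
        lam_min = lam_max = 0.0
    size = 2.0 * np.sqrt(5.0 * lam_max)
    eccentricity = float(np.sqrt(1.0 - lam_min / lam_max)) if lam_max > 0 else 0.0

    solidity = 1.0
    rank = np.linalg.matrix_rank(coords - coords.mean(axis=0), tol=1e-9) if n >= 4 else 0
    if rank >= 3:
        # hull of voxel centers (no half-voxel offsets): a convex digital
        # shape then has solidity ~= 1 instead of being penalized at the rim
        hull = convex_hull_image(mask.voxels, offset_coordinates=False)
        solidity = n / max(int(hull.sum()), n)
    else:
        warnings.warn("mask has < 4 non-coplanar voxels; convex hull undefined, solidity = 1")

    return {
        "volume_mm3": volume,
        "size_mm": float(size),
        "solidity": float(solidity),
        "eccentricity": eccentricity,
    }


def resample_isotropic(image: ImageVolume, mask: VoiMask, scale_mm: float):
    """Resample image (trilinear) and mask (thresholded-linear at 0.5) onto an
    isotropic grid at ``scale_mm`` covering the mask's bounding box with a
    1-voxel pad.  Returns ``(values, mask_bool)`` arrays on the new grid.

    Raises ``ValueError`` if the resampled mask is empty (scale too coarse
    for the lesion).
    """
    if scale_mm <= 0:
        raise ValueError("scale must be positive")
    mask.check_aligned(image)
    idx = np.argwhere(mask.voxels)
    if idx.size == 0:
        raise ValueError("empty mask")
    spacing = np.asarray(image.spacing_mm)
    lo_mm = idx.min(axis=0) * spacing - scale_mm
    hi_mm = idx.max(axis=0) * spacing + scale_mm
    n_out = np.floor((hi_mm - lo_mm) / scale_mm).astype(int) + 1

    grids = [lo_mm[a] + np.arange(n_out[a]) * scale_mm for a in range(3)]
    coords = np.meshgrid(*[g / spacing[a] for a, g in enumerate(grids)], indexing="ij")
    coords = np.stack(coords)

    values = ndimage.map_coordinates(image.voxels, coords, order=1, mode="nearest")
    mask_f = ndimage.map_coordinates(mask.voxels.astype(np.float64), coords, order=1, mode="constant")
    mask_out = mask_f >= 0.5
    if not mask_out.any():
        raise ValueError(f"resampled mask empty at scale {scale_mm} mm")
    return values, mask_out


def extract_features(image: ImageVolume, mask: VoiMask,
                     grid: ExtractionGrid | None = None) -> pd.Series:
    """The full radiomics vector for one (image, VOI) pair.

    Geometry is computed once from the native-resolution mask; for each grid
    combination the VOI is resampled, quantized and summarized into the
    43-feature texture block.  Deterministic; any failing combination aborts
    with the combination named.
    """
    grid = grid or ExtractionGrid()
    if mask.empty_after_perturbation or mask.is_empty:
        raise ValueError(f"mask (variant {mask.variant!r}) is empty")
    mask.check_aligned(image)

    out: dict[str, float] = {}
    for name, val in geometric_features(mask).items():
        out[f"geometry.{name}"] = val

    resampled: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for scale, algo, ng in grid.combinations():
        try:
            if scale not in resampled:
                resampled[scale] = resample_isotropic(image, mask, scale)
            values, rmask = resampled[scale]
            q = quantize(values, rmask, algo, ng, scale_mm=scale)
            m = build_texture_matrices(q)
            block = texture_features(m, values[rmask])
        except ValueError as exc:
            raise ValueError(
                f"extraction failed at scale={scale} mm, algo={algo}, Ng={ng}: {exc}"
            ) from exc
        suffix = f"s{scale:g}.{algo}.g{ng}"
        for fname, val in block.items():
            out[f"{fname}.{suffix}"] = val

    series = pd.Series(out, dtype=np.float64)
    assert len(series) == grid.n_features
    return series


def extract_cohort_table(cases, grid: ExtractionGrid | None = None,
                         masks: dict[str, VoiMask] | None = None) -> pd.DataFrame:
    """Feature table for a cohort: rows = subjects, columns = features plus
    ``label`` and ``split``.

    ``masks`` optionally substitutes each subject's mask (e.g. a perturbed
    delineation variant) keyed by subject id; by default each case's own
    (baseline) mask is used.
    """
    grid = grid or ExtractionGrid()
    rows, meta = {}, {}
    for case in cases:
        mask = masks[case.subject_id] if masks is not None else case.mask
        rows[case.subject_id] = extract_features(case.image, mask, grid)
        meta[case.subject_id] = (case.class_label, case.split)
    table = pd.DataFrame(rows).T
    table["label"] = [meta[s][0] for s in table.index]
    table["split"] = [meta[s][1] for s in table.index]
    table.index.name = "subject_id"
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature column names of a cohort table (everything but label/split)."""
    return [c for c in table.columns if c not in ("label", "split")]
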