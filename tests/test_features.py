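"""Geometric features, resampling and the assembled feature vector."""

import numpy as np
import pytest

import voiradiomics as vr
from voiradiomics.features import GEOMETRY_FEATURES, resample_isotropic


def cube_mask(side=10, spacing=(1, 1, 1), pad=3):
    n = side + 2 * pad
    vox = np.zeros((n, n, n), dtype=bool)
    vox[pad : pad + side, pad : pad + side, pad : pad + side] = True
    return vr.VoiMask(vox, spacing)


def ball_mask(radius=12, spacing=(1, 1, 1), pad=3):
    n = 2 * (radius + pad) + 1
    c = radius + pad
    xx, yy, zz = np.mgrid[:n, :n, :n]
    vox = (xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= radius**2
    return vr.VoiMask(vox, spacing)


class TestGeometricFeatures:
    def test_cube_volume_scales_with_spacing(self):
        g1 = vr.geometric_features(cube_mask(10, spacing=(1, 1, 1)))
        g2 = vr.geometric_features(cube_mask(10, spacing=(2, 1, 1)))
        assert g1["volume_mm3"] == pytest.approx(1000.0)
        assert g2["volume_mm3"] == pytest.approx(2000.0)

    def test_digital_ball_is_solid_and_round(self):
        g = vr.geometric_features(ball_mask(12))
        assert 0.95 <= g["solidity"] <= 1.0
        assert 0.0 <= g["eccentricity"] <= 0.15
        # PCA longest axis of a ball ~ its diameter (digitization tolerance)
        assert g["size_mm"] == pytest.approx(24.0, rel=0.08)

    def test_elongated_mask_is_eccentric(self):
        vox = np.zeros((30, 8, 8), dtype=bool)
        vox[2:28, 2:5, 2:5] = True
        g = vr.geometric_features(vr.VoiMask(vox, (1, 1, 1)))
        assert g["eccentricity"] > 0.9

    def test_coplanar_voxels_solidity_one_with_warning(self):
        vox = np.zeros((6, 6, 3), dtype=bool)
        vox[1:5, 1:5, 1] = True  # all in one plane: 3D hull undefined
        with pytest.warns(UserWarning, match="convex hull undefined"):
            g = vr.geometric_features(vr.VoiMask(vox, (1, 1, 1)))
        assert g["solidity"] == 1.0


class TestResampling:
    def test_identity_scale_preserves_values(self, small_case):
        img = vr.ImageVolume(small_case.image.voxels, (1.0, 1.0, 1.0))
        mask = vr.VoiMask(small_case.mask.voxels, (1.0, 1.0, 1.0))
        values, rmask = resample_isotropic(img, mask, 1.0)
        # the target grid lands on source voxel centers: in-mask values match
        idx = np.argwhere(mask.voxels)
        lo = idx.min(axis=0) - 1
        sub = img.voxels[lo[0] : lo[0] + values.shape[0],
                         lo[1] : lo[1] + values.shape[1],
                         lo[2] : lo[2] + values.shape[2]]
        np.testing.assert_allclose(values, sub, atol=1e-9)

    def test_coarser_scale_halves_bounding_box(self):
        mask = cube_mask(16, spacing=(1, 1, 1))
        img = vr.ImageVolume(np.zeros(mask.shape), (1, 1, 1))
        _, m1 = resample_isotropic(img, mask, 1.0)
        _, m2 = resample_isotropic(img, mask, 2.0)
        ext1 = np.ptp(np.argwhere(m1), axis=0) + 1
        ext2 = np.ptp(np.argwhere(m2), axis=0) + 1
        assert np.all(np.abs(ext1 / 2 - ext2) <= 1)

    def test_constant_lesion_stays_constant(self):
        mask = cube_mask(8)
        img = vr.ImageVolume(np.full(mask.shape, 7.0), (1, 1, 1))
        values, rmask = resample_isotropic(img, mask, 1.7)
        np.testing.assert_allclose(values[rmask], 7.0)

    def test_coarse_scale_keeps_anchored_mask_nonempty(self):
        """The target grid is anchored on the mask's min corner voxel, so
        even a single-voxel mask survives very coarse resampling."""
        vox = np.zeros((8, 8, 8), dtype=bool)
        vox[4, 4, 4] = True
        mask = vr.VoiMask(vox, (1, 1, 1))
        img = vr.ImageVolume(np.zeros(mask.shape), (1, 1, 1))
        _, rmask = resample_isotropic(img, mask, 25.0)
        assert rmask.sum() == 1


class TestExtractFeatures:
    def test_default_grid_vector_length(self, small_case):
        fv = vr.extract_features(small_case.image, small_case.mask)
        assert len(fv) == 2068

    def test_minimal_grid_vector_length(self, small_case):
        grid = vr.ExtractionGrid(scales_mm=(2.0,), quant_algorithms=("uniform",),
                                 gray_levels=(16,))
        fv = vr.extract_features(small_case.image, small_case.mask, grid)
        assert len(fv) == 47  # 4 geometry + 43 texture

    def test_name_order_matches_grid_schema(self, small_case):
        grid = vr.ExtractionGrid(scales_mm=(2.0,), quant_algorithms=("uniform",),
                                 gray_levels=(8,))
        fv = vr.extract_features(small_case.image, small_case.mask, grid)
        assert list(fv.index) == grid.feature_names()
        assert list(fv.index[:4]) == [f"geometry.{f}" for f in GEOMETRY_FEATURES]
        assert fv.index[4] == "global.variance.s2.uniform.g8"

    def test_extraction_is_deterministic(self, small_case, tiny_cohort):
        grid = vr.ExtractionGrid(scales_mm=(2.0,), quant_algorithms=("lloyd",),
                                 gray_levels=(8,))
        a = vr.extract_features(small_case.image, small_case.mask, grid)
        b = vr.extract_features(small_case.image, small_case.mask, grid)
        assert (a == b).all()

    def test_translation_invariance(self, small_case):
        """Shifting image and mask by whole voxels changes no feature."""
        grid = vr.ExtractionGrid(scales_mm=(1.0, 2.0), quant_algorithms=("uniform", "equal"),
                                 gray_levels=(8,))
        shift = (2, -3, 1)
        img2 = vr.ImageVolume(np.roll(small_case.image.voxels, shift, axis=(0, 1, 2)),
                              small_case.image.spacing_mm)
        mask2 = vr.VoiMask(np.roll(small_case.mask.voxels, shift, axis=(0, 1, 2)),
                           small_case.mask.spacing_mm)
        a = vr.extract_features(small_case.image, small_case.mask, grid)
        b = vr.extract_features(img2, mask2, grid)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-9, atol=1e-9)

    def test_empty_mask_rejected(self, small_case):
        empty = vr.VoiMask(np.zeros(small_case.mask.shape, dtype=bool),
                           small_case.mask.spacing_mm)
        with pytest.raises(ValueError, match="empty"):
            vr.extract_features(small_case.image, empty)
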