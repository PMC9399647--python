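import numpy as np
import pytest
from skimage.draw import disk

from conftest import raster_ellipse
from ladgcn.cell_features import (
    SHAPE_FEATURE_NAMES,
    FeatureNormalizer,
    featurize_tile,
    patch_descriptor,
    shape_features,
    texture_features,
)
from ladgcn.synthetic_tiles import TileSpec, generate_tile

IDX = {name: i for i, name in enumerate(SHAPE_FEATURE_NAMES)}


class TestShapeFeatures:
    def test_disk_matches_analytic_circle(self):
        mask = np.zeros((64, 64), bool)
        rr, cc = disk((32, 32), 20)
        mask[rr, cc] = True
        f = shape_features(mask)
        assert f[IDX["roundness"]] >= 0.95
        assert f[IDX["solidity"]] >= 0.98
        assert f[IDX["eccentricity"]] <= 0.1
        assert f[IDX["area"]] == pytest.approx(np.pi * 20**2, rel=0.02)

    def test_ellipse_axis_ratio_and_eccentricity(self):
        f = shape_features(raster_ellipse(10, 5))
        ratio = f[IDX["major_axis_length"]] / f[IDX["minor_axis_length"]]
        assert ratio == pytest.approx(2.0, rel=0.05)
        assert f[IDX["eccentricity"]] == pytest.approx(np.sqrt(1 - 25 / 100), abs=0.05)

    def test_single_pixel_degenerate_mask(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        f = shape_features(mask)
        assert f[IDX["area"]] == 1
        assert f[IDX["solidity"]] == 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            shape_features(np.zeros((4, 4), bool))

    def test_rotation_by_90_degrees_preserves_invariant_features(self):
        mask = raster_ellipse(12, 6, theta=0.3)
        rot = np.rot90(mask)
        f, g = shape_features(mask), shape_features(rot)
        for name in ("area", "solidity", "eccentricity", "roundness"):
            assert g[IDX[name]] == pytest.approx(f[IDX[name]], rel=0.02)
        delta = (g[IDX["orientation"]] - f[IDX["orientation"]]) % np.pi
        assert min(abs(delta - np.pi / 2), abs(delta - np.pi / 2 - np.pi)) < 0.05

    def test_solidity_never_exceeds_one(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            mask = raster_ellipse(rng.uniform(4, 15), rng.uniform(3, 10), rng.uniform(0, np.pi))
            assert shape_features(mask)[IDX["solidity"]] <= 1.0


class TestTextureFeatures:
    def test_constant_patch_is_perfectly_homogeneous(self):
        img = np.full((20, 20), 57.0)
        mask = np.zeros((20, 20), bool)
        mask[4:16, 4:16] = True
        assert np.allclose(texture_features(img, mask), [0.0, 1.0, 1.0, 1.0])

    def test_energy_is_sqrt_of_asm(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            img = rng.uniform(0, 255, (16, 16))
            mask = np.ones((16, 16), bool)
            d, h, asm, energy = texture_features(img, mask)
            assert energy**2 == pytest.approx(asm, abs=1e-12)

    def test_checkerboard_horizontal_dissimilarity(self):
        img = np.array([[0.0, 31.0], [31.0, 0.0]])
        mask = np.ones((2, 2), bool)
        d, h, asm, energy = texture_features(img, mask, angles=(0.0,))
        # both horizontal pairs co-occur at |i-j| = 31
        assert d == pytest.approx(31.0)
        assert h == pytest.approx(1.0 / (1.0 + 31**2), rel=1e-6)

    def test_invariant_to_constant_intensity_shift(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(10, 200, (12, 12))
        mask = np.ones((12, 12), bool)
        assert np.allclose(texture_features(img, mask), texture_features(img + 37.0, mask))

    def test_degenerate_bounding_box_rejected(self):
        img = np.zeros((8, 8))
        mask = np.zeros((8, 8), bool)
        mask[3, 2:6] = True  # 1-pixel-tall box
        with pytest.raises(ValueError):
            texture_features(img, mask)


class TestPatchDescriptor:
    def test_uniform_patch_has_zero_std(self):
        img = np.full((128, 128, 3), 99, dtype=np.uint8)
        desc = patch_descriptor(img, (64, 64))
        assert np.allclose(desc[3:6], 0.0)

    def test_corner_centroid_is_zero_padded_not_an_error(self):
        img = np.full((128, 128, 3), 200, dtype=np.uint8)
        desc = patch_descriptor(img, (0, 0))
        assert desc.shape == (12,)
        assert np.all(np.isfinite(desc))
        # three quarters of the window are padding, so the mean drops
        assert desc[0] < 200 / 255

    def test_identical_patches_give_identical_descriptors(self):
        rng = np.random.default_rng(0)
        block = rng.integers(0, 255, (64, 64, 3)).astype(np.uint8)
        img = np.zeros((200, 200, 3), dtype=np.uint8)
        img[10:74, 10:74] = block
        img[100:164, 120:184] = block
        d1 = patch_descriptor(img, (42, 42))
        d2 = patch_descriptor(img, (132, 152))
        assert np.allclose(d1, d2)


class TestFeaturizeTile:
    def test_feature_matrix_shape_and_row_order(self):
        tile = generate_tile(TileSpec(class_label="scattered", n_nuclei=12, seed=8))
        feats, centroids = featurize_tile(tile.image, tile.instance_mask)
        n = tile.instance_mask.max()
        assert feats.shape == (n, 24)
        assert centroids.shape == (n, 2)
        # row k corresponds to label k+1
        rr, cc = np.nonzero(tile.instance_mask == 1)
        assert np.allclose(centroids[0], (rr.mean(), cc.mean()))

    def test_zero_instances_give_empty_matrix_with_column_count(self):
        img = np.full((64, 64, 3), 150, dtype=np.uint8)
        feats, centroids = featurize_tile(img, np.zeros((64, 64), dtype=np.int32))
        assert feats.shape == (0, 24)
        assert centroids.shape == (0, 2)


def test_normalizer_roundtrip_and_persistence(tmp_path):
    rng = np.random.default_rng(2)
    X = rng.normal(5, 3, (40, 24))
    norm = FeatureNormalizer().fit(X)
    Z = norm.transform(X)
    assert np.allclose(Z.mean(axis=0), 0, atol=1e-12)
    assert np.allclose(norm.inverse_transform(Z), X, atol=1e-9)
    norm.to_json(tmp_path / "norm.json")
    back = FeatureNormalizer.from_json(tmp_path / "norm.json")
    assert np.allclose(back.transform(X), Z)
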