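import numpy as np
import pytest

import strokevol as sv
from strokevol.seg import (
    Flip90,
    dice_loss_grad,
    draw_transform,
    normalize_volume,
)
from strokevol.unet import UNetConfig


class TestTriplets:
    def test_one_triplet_per_slice_with_edge_replication(self, sphere_phantom):
        study, _ = sphere_phantom
        triplets = sv.make_triplets(study)
        assert len(triplets) == study.n_slices
        np.testing.assert_array_equal(triplets[0].channels[0], study.voxels[0])
        np.testing.assert_array_equal(triplets[0].channels[1], study.voxels[0])
        np.testing.assert_array_equal(triplets[-1].channels[2], study.voxels[-1])

    def test_middle_triplet_channels_are_adjacent_slices(self, sphere_phantom):
        study, _ = sphere_phantom
        k = study.n_slices // 2
        t = sv.make_triplets(study)[k]
        np.testing.assert_array_equal(t.channels[0], study.voxels[k - 1])
        np.testing.assert_array_equal(t.channels[1], study.voxels[k])
        np.testing.assert_array_equal(t.channels[2], study.voxels[k + 1])

    def test_single_slice_volume_replicates_three_times(self):
        vol = np.arange(16 * 16, dtype=np.float32).reshape(1, 16, 16)
        (t,) = sv.make_triplets(vol)
        np.testing.assert_array_equal(t.channels[0], t.channels[1])
        np.testing.assert_array_equal(t.channels[1], t.channels[2])


class TestAugmentation:
    def test_identity_draw_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(3, 16, 16))
        t = Flip90(hflip=False, vflip=False, k_rot=0)
        np.testing.assert_array_equal(t.apply(img), img)

    def test_misaligned_shapes_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="aligned"):
            sv.augment(rng.normal(size=(16, 16)), np.zeros((8, 8)), rng)

    def test_transforms_preserve_foreground_count_and_binarity(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            img = rng.normal(size=(3, 16, 16))
            mask = (rng.random((1, 16, 16)) < 0.3).astype(np.uint8)
            aug_img, aug_mask = sv.augment(img, mask, rng)
            assert aug_mask.sum() == mask.sum()
            assert set(np.unique(aug_mask)) <= {0, 1}
            assert aug_img.shape == img.shape

    def test_inverse_transform_restores_original(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            t = draw_transform(rng)
            arr = rng.normal(size=(3, 12, 12))
            np.testing.assert_array_equal(t.inverse().apply(t.apply(arr)), arr)

    def test_same_transform_applied_to_image_and_mask(self):
        # encode position in both arrays; augmented pair must stay aligned
        rng = np.random.default_rng(4)
        base = np.zeros((1, 8, 8))
        base[0, 2, 5] = 1.0
        for _ in range(20):
            img, mask = sv.augment(base.copy(), base.astype(np.uint8).copy(), rng)
            np.testing.assert_array_equal(img[0] != 0, mask[0] != 0)


class TestPatches:
    def test_patch_equal_to_volume_is_single_patch(self):
        vol = np.random.default_rng(5).random((8, 16, 16)).astype(np.float32)
        patches = sv.extract_patches(vol, (8, 16, 16), (8, 16, 16))
        assert len(patches) == 1
        np.testing.assert_array_equal(patches[0].voxels, vol)

    def test_stitch_extract_identity_on_constant_field(self):
        vol = np.full((12, 32, 32), 0.7, dtype=np.float32)
        patches = sv.extract_patches(vol, (8, 16, 16), (4, 8, 8))
        out = sv.stitch_patches(patches, vol.shape)
        np.testing.assert_array_equal(out, np.full(vol.shape, np.float32(0.7)))

    def test_half_overlap_covers_every_voxel(self):
        shape = (32, 32, 32)
        patches = sv.extract_patches(np.zeros(shape), (16, 16, 16), (8, 8, 8))
        coverage = np.zeros(shape, dtype=int)
        for p in patches:
            sl = tuple(slice(o, o + s) for o, s in zip(p.origin, p.voxels.shape))
            coverage[sl] += 1
        assert (coverage >= 1).all()

    def test_small_volume_is_zero_padded_then_cropped(self):
        vol = np.random.default_rng(6).random((5, 16, 16)).astype(np.float32)
        patches = sv.extract_patches(vol, (8, 16, 16), (8, 16, 16))
        assert patches[0].voxels.shape == (8, 16, 16)
        np.testing.assert_array_equal(patches[0].voxels[:5], vol)
        assert (patches[0].voxels[5:] == 0).all()
        out = sv.stitch_patches(patches, vol.shape)
        assert out.shape == vol.shape

    def test_zero_stride_rejected(self):
        with pytest.raises(ValueError, match="stride"):
            sv.extract_patches(np.zeros((8, 16, 16)), (8, 16, 16), (0, 8, 8))

    def test_stride_exceeding_patch_rejected(self):
        with pytest.raises(ValueError, match="stride"):
            sv.extract_patches(np.zeros((8, 16, 16)), (4, 16, 16), (8, 16, 16))


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self):
        y = (np.random.default_rng(7).random((2, 1, 8, 8)) < 0.4).astype(np.float64)
        assert sv.dice_loss(y, y, eps=0.0) == 0.0

    def test_disjoint_masks_give_one(self):
        y = np.zeros((1, 1, 4, 4))
        p = np.zeros_like(y)
        y[..., :2] = 1.0
        p[..., 2:] = 1.0
        assert sv.dice_loss(p, y, eps=0.0) == 1.0

    def test_half_probability_worked_example(self):
        """8 pixels, 4 positive labels, uniform prediction 0.5:
        1 - 2*(0.5*4) / (4 + 8*0.25) = 1/3."""
        y = np.array([[1, 1, 1, 1, 0, 0, 0, 0]], dtype=np.float64)
        p = np.full_like(y, 0.5)
        assert sv.dice_loss(p, y, eps=0.0) == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_loss_is_bounded_for_probability_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.random((3, 1, 6, 6))
            y = (rng.random((3, 1, 6, 6)) < 0.5).astype(np.float64)
            loss = sv.dice_loss(p, y)
            assert 0.0 <= loss <= 1.0

    def test_batch_reduction_averages_items(self):
        y = np.zeros((2, 1, 2, 2))
        y[0] = 1.0
        p = y.copy()  # item 0 perfect, item 1 empty-vs-empty (loss 0 by convention)
        assert sv.dice_loss(p, y, eps=0.0) == 0.0

    def test_gradient_matches_numerical(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.1, 0.9, size=(2, 1, 4, 4))
        y = (rng.random((2, 1, 4, 4)) < 0.5).astype(np.float64)
        grad = dice_loss_grad(p, y, eps=1e-6)
        eps = 1e-6
        for idx in [(0, 0, 1, 2), (1, 0, 3, 3), (0, 0, 0, 0)]:
            pp, pm = p.copy(), p.copy()
            pp[idx] += eps
            pm[idx] -= eps
            numeric = (sv.dice_loss(pp, y) - sv.dice_loss(pm, y)) / (2 * eps)
            assert grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sv.dice_loss(np.zeros((1, 4)), np.zeros((1, 5)))


class TestSplit:
    def test_ten_patients_split_8_1_1(self):
        tr, va, te = sv.split_cohort(10, (0.8, 0.1, 0.1), seed=0)
        assert (len(tr), len(va), len(te)) == (8, 1, 1)
        assert sorted(tr + va + te) == list(range(10))

    def test_forty_patients_split_32_4_4(self):
        tr, va, te = sv.split_cohort(40, (0.8, 0.1, 0.1), seed=0)
        assert (len(tr), len(va), len(te)) == (32, 4, 4)

    def test_same_seed_same_membership(self):
        assert sv.split_cohort(25, seed=3) == sv.split_cohort(25, seed=3)
        assert sv.split_cohort(25, seed=3) != sv.split_cohort(25, seed=4)

    def test_impossible_split_rejected(self):
        with pytest.raises(ValueError):
            sv.split_cohort(2)
        with pytest.raises(ValueError):
            sv.split_cohort(4, (0.05, 0.05, 0.9), seed=0)


class TestNormalization:
    def test_zscore_and_constant_volume(self):
        rng = np.random.default_rng(10)
        v = rng.normal(50.0, 7.0, size=(4, 16, 16))
        z = normalize_volume(v)
        assert abs(float(z.mean())) < 1e-4
        assert abs(float(z.std()) - 1.0) < 1e-4
        flat = normalize_volume(np.full((2, 8, 8), 3.0))
        assert (flat == 0).all()


class _StubModel:
    """Model double emitting a constant probability everywhere."""

    def __init__(self, dimensionality, value):
        self.config = UNetConfig(dimensionality=dimensionality, depth=2,
                                 base_channels=4,
                                 input_channels=3 if dimensionality == 2 else 1)
        self.value = value

    def forward(self, x, train=False):
        return np.full(x.shape[:1] + (1,) + x.shape[2:], self.value, dtype=np.float32)


class TestPrediction:
    def test_zero_probability_model_gives_empty_mask(self, sphere_phantom):
        study, _ = sphere_phantom
        mask = sv.predict_indirect(_StubModel(2, 0.0), study, threshold=0.5)
        assert mask.voxels.sum() == 0
        assert mask.voxels.shape == study.voxels.shape

    def test_indirect_mask_has_one_slice_per_study_slice(self, sphere_phantom):
        study, _ = sphere_phantom
        mask = sv.predict_indirect(_StubModel(2, 0.9), study)
        assert mask.voxels.shape[0] == study.n_slices
        assert (mask.voxels == 1).all()

    def test_direct_prediction_covers_study_shape(self, sphere_phantom):
        study, _ = sphere_phantom
        mask = sv.predict_direct(_StubModel(3, 0.7), study,
                                 patch_shape=(16, 32, 32), patch_stride=(8, 16, 16))
        assert mask.voxels.shape == study.voxels.shape
        assert (mask.voxels == 1).all()  # 0.7 >= threshold everywhere

    def test_dimensionality_mismatch_rejected(self, sphere_phantom):
        study, _ = sphere_phantom
        with pytest.raises(ValueError, match="2D"):
            sv.predict_indirect(_StubModel(3, 0.5), study)
        with pytest.raises(ValueError, match="3D"):
            sv.predict_direct(_StubModel(2, 0.5), study)
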