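"""Segmentation: augmentation, splitting, IoU, U-Net training, threshold."""

import numpy as np
import pytest
from skimage.draw import disk

from sensillum3d._unet import UNet, bce_with_logits
from sensillum3d.geometry import ImageStack, LabelStack, VoxelGeometry
from sensillum3d.segment import (TrainConfig, augment_pair, iou, predict_masks,
                                 split_dataset, threshold_segment, train_unet)


def _disc_mask(shape=(64, 64), radius=18):
    mask = np.zeros(shape, dtype=np.uint8)
    rr, cc = disk((shape[0] // 2, shape[1] // 2), radius)
    mask[rr, cc] = 1
    return mask


class TestAugmentPair:
    def test_exactly_four_variants(self):
        img = np.random.default_rng(0).random((32, 32))
        out = augment_pair(img, (img > 0.5).astype(np.uint8))
        assert len(out) == 4

    def test_vertical_flip_is_involution(self):
        img = np.random.default_rng(1).random((16, 16))
        lab = (img > 0.5).astype(np.uint8)
        flipped_img, flipped_lab = augment_pair(img, lab)[0]
        img2, lab2 = augment_pair(flipped_img, flipped_lab)[0]
        np.testing.assert_array_equal(img2, img)
        np.testing.assert_array_equal(lab2, lab)

    def test_rotation_preserves_centered_disc_area(self):
        mask = _disc_mask()
        rotated = augment_pair(mask.astype(float), mask)[2][1]  # 45 degrees
        assert int(rotated.sum()) == pytest.approx(int(mask.sum()), rel=0.02)

    def test_canvas_size_and_binary_labels_preserved(self):
        img = np.random.default_rng(2).random((40, 40))
        lab = _disc_mask((40, 40), 10)
        for im_a, lb_a in augment_pair(img, lab):
            assert im_a.shape == img.shape and lb_a.shape == lab.shape
            assert set(np.unique(lb_a)) <= {0, 1}

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            augment_pair(np.zeros((4, 4)), np.zeros((5, 5)))


class TestSplitDataset:
    def test_labelled_image_count_splits_largest_remainder(self):
        # 337 images at 90:5:5 -> (303, 17, 17) by largest-remainder rounding
        parts = split_dataset(list(range(337)), (0.90, 0.05, 0.05), seed=0)
        assert tuple(len(p) for p in parts) == (303, 17, 17)

    def test_round_sizes(self):
        parts = split_dataset(list(range(100)), (0.90, 0.05, 0.05), seed=1)
        assert tuple(len(p) for p in parts) == (90, 5, 5)

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_disjoint_and_exhaustive(self, seed):
        items = list(range(53))
        parts = split_dataset(items, (0.6, 0.25, 0.15), seed=seed)
        merged = sorted(x for p in parts for x in p)
        assert merged == items
        assert sum(len(p) for p in parts) == len(items)

    def test_same_seed_same_partition(self):
        a = split_dataset(list(range(30)), (0.5, 0.5), seed=5)
        b = split_dataset(list(range(30)), (0.5, 0.5), seed=5)
        assert a == b

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2], (0.4, 0.3, 0.3), seed=0)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(10)), (0.5, 0.2), seed=0)


class TestIoU:
    def test_identical_nonempty_is_one(self):
        m = _disc_mask()
        assert iou(m, m) == 1.0

    def test_disjoint_nonempty_is_zero(self):
        a = np.zeros((8, 8)); a[:4] = 1
        b = np.zeros((8, 8)); b[4:] = 1
        assert iou(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((8, 8)); a[:, :4] = 1
        b = np.ones((8, 8))
        assert iou(a, b) == 0.5

    def test_symmetric_and_empty_convention(self):
        a = _disc_mask((16, 16), 4)
        b = np.roll(a, 3, axis=0)
        assert iou(a, b) == iou(b, a)
        assert iou(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0


class TestThresholdSegment:
    def test_reproduces_ground_truth_on_noise_free_phantom(self, phantom_pair):
        (images, labels), _ = phantom_pair
        masks = threshold_segment(images, 125.0)
        np.testing.assert_array_equal(masks.sections, labels.sections)

    def test_extreme_levels(self, phantom_pair):
        (images, _), _ = phantom_pair
        assert threshold_segment(images, 255.0).sections.sum() == 0
        full = threshold_segment(images, 0.0)
        assert (full.sections == 1).all()

    def test_level_out_of_range_rejected(self, phantom_pair):
        (images, _), _ = phantom_pair
        with pytest.raises(ValueError):
            threshold_segment(images, 300.0)


class TestUNetCore:
    def test_gradients_match_finite_differences(self, monkeypatch):
        import sensillum3d._unet as unet_mod
        monkeypatch.setattr(unet_mod, "_DTYPE", np.float64)
        rng = np.random.default_rng(0)
        net = UNet(depth=2, base_filters=2, seed=1)
        for conv in net._convs():
            conv.b = conv.b + 0.3  # keep pre-activations off the ReLU kink
        x = rng.normal(size=(2, 1, 8, 8))
        y = (rng.random((2, 8, 8)) > 0.5).astype(float)
        _, dl = bce_with_logits(net.forward(x), y)
        net.backward(dl)
        grads = [g.copy() for g in net.gradients()]
        params = net.parameters()
        probe = np.random.default_rng(2)
        for p, g in zip(params, grads):
            flat, gflat = p.reshape(-1), g.reshape(-1)
            for idx in probe.choice(flat.size, size=min(3, flat.size), replace=False):
                eps, old = 1e-6, flat[idx]
                flat[idx] = old + eps
                l1, _ = bce_with_logits(net.forward(x), y)
                flat[idx] = old - eps
                l2, _ = bce_with_logits(net.forward(x), y)
                flat[idx] = old
                num = (l1 - l2) / (2 * eps)
                assert num == pytest.approx(gflat[idx], rel=1e-3, abs=1e-7)

    def test_input_size_must_match_depth(self):
        net = UNet(depth=3, base_filters=2)
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 1, 20, 20)))


class TestTrainPredict:
    def test_degenerate_labels_rejected(self, demo_geometry):
        images = ImageStack(sections=np.random.default_rng(0).random((12, 16, 16)),
                            geometry=demo_geometry)
        labels = LabelStack(sections=np.zeros((12, 16, 16), dtype=np.uint8),
                            geometry=demo_geometry)
        with pytest.raises(ValueError, match="degenerate labels"):
            train_unet(images, labels, TrainConfig(input_size=16, depth=2,
                                                   base_filters=2, epochs=1))

    def test_training_is_deterministic_for_fixed_seed(self, training_phantom):
        images, labels = training_phantom
        cfg = TrainConfig(input_size=64, depth=2, base_filters=4, epochs=2,
                          batch_size=8, lr=2e-3, seed=3, augment=False)
        _, m1 = train_unet(images, labels, cfg)
        _, m2 = train_unet(images, labels, cfg)
        assert m1.iou == m2.iou
        assert m1.val_loss == m2.val_loss

    def test_threshold_one_empties_prediction(self, training_phantom):
        images, labels = training_phantom
        cfg = TrainConfig(input_size=64, depth=2, base_filters=4, epochs=1,
                          batch_size=8, seed=0, augment=False)
        model, _ = train_unet(images, labels, cfg)
        masks = predict_masks(model, images, threshold=1.0)
        assert masks.sections.sum() == 0

    def test_prediction_geometry_rescaled_to_model_resolution(self, demo_geometry):
        rng = np.random.default_rng(0)
        images = ImageStack(sections=rng.random((20, 128, 128)) * 255,
                            geometry=demo_geometry)
        labels = LabelStack(sections=np.tile(_disc_mask((128, 128), 30), (20, 1, 1)),
                            geometry=demo_geometry)
        cfg = TrainConfig(input_size=64, depth=2, base_filters=2, epochs=1,
                          batch_size=8, seed=0, augment=False)
        model, _ = train_unet(images, labels, cfg)
        masks = predict_masks(model, images)
        assert masks.section_shape == (64, 64)
        assert masks.geometry.pixel_x == pytest.approx(demo_geometry.pixel_x * 2)
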