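"""U-Net contracts, soft Dice loss, pseudo-label generation."""

import numpy as np
import pytest

from cineflow.containers import N_CLASSES
from cineflow.unet import (TINY_PROFILE, UNet, UnetConfig,
                           generate_pseudo_labels, normalize_image, segment,
                           soft_dice_loss)


@pytest.fixture(scope="module")
def tiny_unet():
    return UNet(UnetConfig(seed=0, **TINY_PROFILE))


class TestArchitecture:
    def test_four_output_channels_and_shape(self, tiny_unet):
        x = np.random.default_rng(0).standard_normal((2, 1, 32, 32))
        out = tiny_unet(x.astype(np.float32))
        assert out.shape == (2, N_CLASSES, 32, 32)

    def test_probabilities_sum_to_one(self, tiny_unet):
        x = np.random.default_rng(1).standard_normal((1, 1, 32, 32))
        out = tiny_unet(x.astype(np.float32))
        np.testing.assert_allclose(out.data.sum(axis=1), 1.0, atol=1e-5)

    def test_non_divisible_input_padded_internally(self, tiny_unet):
        x = np.random.default_rng(2).standard_normal((1, 1, 34, 33))
        out = tiny_unet(x.astype(np.float32))
        assert out.shape == (1, N_CLASSES, 34, 33)

    def test_default_profile_widths(self):
        cfg = UnetConfig()
        assert cfg.widths() == [32, 64, 128, 256, 512]
        assert sum(cfg.encoder_blocks) == 8


class TestSegment:
    def test_deterministic_per_frame(self, tiny_unet, phantom32):
        masks = segment(phantom32.images.frames[:2], tiny_unet)
        again = segment(phantom32.images.frames[:2], tiny_unet)
        np.testing.assert_array_equal(masks[0].labels, again[0].labels)
        duplicated = segment(
            np.stack([phantom32.images.frames[0]] * 2), tiny_unet)
        np.testing.assert_array_equal(duplicated[0].labels,
                                      duplicated[1].labels)

    def test_all_zero_image_valid(self, tiny_unet):
        masks = segment(np.zeros((1, 32, 32)), tiny_unet)
        assert masks[0].labels.shape == (32, 32)

    def test_nonfinite_rejected(self, tiny_unet):
        bad = np.full((1, 32, 32), np.nan)
        with pytest.raises(ValueError):
            segment(bad, tiny_unet)


class TestSoftDice:
    def test_perfect_prediction_near_zero(self):
        target = np.zeros((1, 4, 8, 8), dtype=np.float32)
        target[0, 1, :4] = 1
        target[0, 0, 4:] = 1
        loss = soft_dice_loss(target, target)
        assert float(loss.data) < 1e-4

    def test_uniform_prediction_in_unit_interval(self):
        probs = np.full((1, 4, 8, 8), 0.25, dtype=np.float32)
        target = np.zeros_like(probs)
        target[0, 2] = 1
        loss = float(soft_dice_loss(probs, target).data)
        assert 0 < loss < 1

    def test_disjoint_hard_prediction_near_one(self):
        # every class populated but predicted and target supports disjoint
        probs = np.zeros((1, 4, 8, 8), dtype=np.float32)
        probs[0, 0, :4] = 1
        probs[0, 1, 4:] = 1
        target = np.zeros_like(probs)
        target[0, 2, :4] = 1
        target[0, 3, 4:] = 1
        assert float(soft_dice_loss(probs, target).data) > 0.95

    def test_class_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet(np.ones(4), size=(8, 8)).transpose(2, 0, 1)
        probs = probs[None].astype(np.float32)
        target = np.zeros_like(probs)
        target[0, 1, :4] = 1
        target[0, 3, 4:] = 1
        target[0, 0] = 1 - target[0].sum(axis=0).clip(0, 1)
        perm = [2, 0, 3, 1]
        a = float(soft_dice_loss(probs, target).data)
        b = float(soft_dice_loss(probs[:, perm], target[:, perm]).data)
        assert a == pytest.approx(b, abs=1e-6)

    def test_joint_spatial_permutation_invariance(self):
        rng = np.random.default_rng(4)
        probs = rng.dirichlet(np.ones(4), size=(6, 6)).transpose(2, 0, 1)
        probs = probs[None].astype(np.float32)
        target = (probs == probs.max(axis=1, keepdims=True)).astype(np.float32)
        a = float(soft_dice_loss(probs, target).data)
        b = float(soft_dice_loss(probs[..., ::-1], target[..., ::-1]).data)
        assert a == pytest.approx(b, abs=1e-6)


class TestPseudoLabels:
    def test_identity_flow_copies_mask(self, phantom64):
        from cineflow.mopnet import FlowTable

        gt = phantom64
        table = FlowTable(gt.images.n_frames)
        table.add(5, 0, np.zeros((64, 64, 2), dtype=np.float32))
        out = generate_pseudo_labels(gt.labels[0], table, 0, [0, 5])
        np.testing.assert_array_equal(out[0], gt.labels[0])
        np.testing.assert_array_equal(out[5], gt.labels[0])

    def test_truth_flow_propagation_accuracy(self, phantom64):
        from cineflow.containers import LABEL_LV_POOL
        from cineflow.metrics import dice
        from cineflow.mopnet import FlowTable

        gt = phantom64
        es = gt.es_frame
        table = FlowTable(gt.images.n_frames)
        table.add(es, 0, gt.true_flow(es, 0))
        out = generate_pseudo_labels(gt.labels[0], table, 0, [es])
        assert dice(out[es], gt.labels[es], LABEL_LV_POOL) > 0.9
        # truth-flow propagation beats no-motion propagation
        zero_dsc = dice(gt.labels[0], gt.labels[es], LABEL_LV_POOL)
        assert dice(out[es], gt.labels[es], LABEL_LV_POOL) > zero_dsc

    def test_label_value_set_preserved(self, phantom64):
        from cineflow.mopnet import FlowTable

        gt = phantom64
        es = gt.es_frame
        table = FlowTable(gt.images.n_frames)
        table.add(es, 0, gt.true_flow(es, 0))
        out = generate_pseudo_labels(gt.labels[0], table, 0, [es])
        assert set(np.unique(out[es])) <= set(np.unique(gt.labels[0]))


def test_normalize_image_range():
    rng = np.random.default_rng(5)
    img = rng.uniform(3, 9, (16, 16))
    out = normalize_image(img)
    assert out.min() == pytest.approx(-1)
    assert out.max() == pytest.approx(1)
    assert np.abs(normalize_image(np.full((4, 4), 2.0))).max() == 0
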