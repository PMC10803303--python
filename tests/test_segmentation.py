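"""U-Net construction, deep supervision, training and feature extraction."""

from __future__ import annotations

import numpy as np
import pytest

from mlnet.evalstats import dice
from mlnet.nn import Tensor, bce_with_logits, soft_dice_loss
from mlnet.segmentation import (
    UNetConfig,
    build_unet,
    case_input,
    crossval_segmentation,
    deep_supervision_loss,
    downsample_targets,
    extract_features,
    load_checkpoint,
    predict_mask,
    save_checkpoint,
    train_segmenter,
    default_ds_weights,
)


class TestConfig:
    def test_default_ds_weights(self):
        w = default_ds_weights(4)
        assert np.allclose(w, np.array([8, 4, 2, 1]) / 15)
        assert w.sum() == pytest.approx(1.0)

    def test_stage_channels_doubling(self):
        cfg = UNetConfig(n_stages=4, base_channels=8)
        assert cfg.stage_channels == (8, 16, 32, 64)

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            UNetConfig(ds_weights=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            UNetConfig(n_stages=1)


class TestBuildUnet:
    def test_stage_spatial_dims(self):
        model = build_unet(UNetConfig(seed=0))
        x = Tensor(np.random.default_rng(0).random((1, 1, 32, 32, 32)).astype(np.float32))
        logits, features = model(x)
        assert [f.shape[2:] for f in features] == [
            (32, 32, 32), (16, 16, 16), (8, 8, 8), (4, 4, 4)
        ]
        assert [f.shape[1] for f in features] == [8, 16, 32, 64]
        assert all(lg.shape[1] == 1 for lg in logits)

    def test_seeded_init_identical(self):
        a = build_unet(UNetConfig(seed=42))
        b = build_unet(UNetConfig(seed=42))
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            assert np.array_equal(pa.data, pb.data)

    def test_input_too_small(self):
        model = build_unet(UNetConfig(n_stages=4))
        with pytest.raises(ValueError, match="too small"):
            model(Tensor(np.zeros((1, 1, 4, 4, 4), np.float32)))

    def test_channel_mismatch(self):
        model = build_unet(UNetConfig(input_channels=1))
        with pytest.raises(ValueError, match="channels"):
            model(Tensor(np.zeros((1, 2, 16, 16, 16), np.float32)))


class TestDownsampleTargets:
    def test_single_level_identity(self):
        mask = (np.random.default_rng(1).random((8, 8, 8)) > 0.5).astype(np.uint8)
        levels = downsample_targets(mask, 1)
        assert len(levels) == 1
        assert np.array_equal(levels[0], mask.astype(np.float32))

    def test_all_ones(self):
        levels = downsample_targets(np.ones((8, 8, 8), np.uint8), 3)
        for lv in levels:
            assert np.allclose(lv, 1.0)

    def test_values_in_unit_interval(self):
        mask = (np.random.default_rng(2).random((16, 16, 16)) > 0.6).astype(np.uint8)
        for lv in downsample_targets(mask, 4):
            assert lv.min() >= 0.0 and lv.max() <= 1.0

    def test_hand_computed_half_scale(self):
        # 4^3 mask filled only on the first x-slab; centre-aligned trilinear
        # sampling puts target voxel j at source coordinate 2j + 0.5, so the
        # expected values along x are interp(0.5 -> 0.5) and interp(2.5 -> 0)
        mask = np.zeros((4, 4, 4), np.float32)
        mask[0] = 1.0
        level2 = downsample_targets(mask, 2)[1]
        assert level2.shape == (2, 2, 2)
        assert np.allclose(level2[0], 0.5)
        assert np.allclose(level2[1], 0.0)

    def test_invalid_levels(self):
        with pytest.raises(ValueError):
            downsample_targets(np.ones((4, 4, 4)), 0)


class TestDeepSupervisionLoss:
    def _fake(self, rng, shape):
        return Tensor(rng.normal(size=shape).astype(np.float32))

    def test_one_hot_weights(self):
        rng = np.random.default_rng(3)
        preds = [self._fake(rng, (1, 1, 8, 8, 8)), self._fake(rng, (1, 1, 4, 4, 4))]
        targets = [
            (rng.random((1, 1, 8, 8, 8)) > 0.5).astype(np.float32),
            (rng.random((1, 1, 4, 4, 4)) > 0.5).astype(np.float32),
        ]
        full = deep_supervision_loss(preds, targets, (1.0, 0.0))
        single = soft_dice_loss(preds[0], targets[0]) + bce_with_logits(preds[0], targets[0])
        assert full.item() == pytest.approx(single.item(), rel=1e-6)

    def test_near_minimum_at_perfect_prediction(self):
        target = (np.random.default_rng(4).random((1, 1, 8, 8, 8)) > 0.5).astype(np.float32)
        logits = Tensor((target * 2 - 1) * 20.0)  # saturated correct logits
        loss = deep_supervision_loss([logits], [target], (1.0,))
        assert loss.item() < 1e-3

    def test_decomposes_into_per_stage_terms(self):
        rng = np.random.default_rng(5)
        shapes = [(1, 1, 8, 8, 8), (1, 1, 4, 4, 4), (1, 1, 2, 2, 2)]
        preds = [self._fake(rng, s) for s in shapes]
        targets = [(rng.random(s) > 0.5).astype(np.float32) for s in shapes]
        w = (0.5, 0.3, 0.2)
        combined = deep_supervision_loss(preds, targets, w)
        manual = sum(
            wi * (soft_dice_loss(p, t).item() + bce_with_logits(p, t).item())
            for wi, p, t in zip(w, preds, targets)
        )
        assert combined.item() == pytest.approx(manual, rel=1e-5)
        assert combined.item() >= 0.0

    def test_shape_mismatch(self):
        p = Tensor(np.zeros((1, 1, 4, 4, 4), np.float32))
        with pytest.raises(ValueError):
            deep_supervision_loss([p], [np.zeros((1, 1, 8, 8, 8), np.float32)], (1.0,))


@pytest.fixture(scope="module")
def trained_small(small_cohort):
    cfg = UNetConfig(seed=3)
    model, log = train_segmenter(
        small_cohort[:16], cfg, epochs=5, val_cases=small_cohort[16:20], lr=5e-3
    )
    return model, log


class TestTraining:
    def test_loss_decreases(self, trained_small):
        _, log = trained_small
        losses = log.train_losses()
        assert losses[-1] < losses[0]

    def test_seeded_reproducibility(self, small_cohort):
        cfg = UNetConfig(seed=9)
        _, log1 = train_segmenter(small_cohort[:8], cfg, epochs=2,
                                  val_cases=small_cohort[8:10], lr=3e-3)
        _, log2 = train_segmenter(small_cohort[:8], cfg, epochs=2,
                                  val_cases=small_cohort[8:10], lr=3e-3)
        assert log1.epochs == log2.epochs
        assert log1.checkpoint_epoch == log2.checkpoint_epoch

    def test_checkpoint_is_best_val_dice(self, trained_small):
        _, log = trained_small
        dices = log.val_dices()
        assert dices[log.checkpoint_epoch - 1] == max(dices)

    def test_empty_training_set(self, small_cohort):
        with pytest.raises(ValueError):
            train_segmenter([], UNetConfig(), epochs=1, val_cases=small_cohort[:2])


class TestPredictAndFeatures:
    def test_mask_contract(self, trained_small, small_cohort):
        model, _ = trained_small
        mask = predict_mask(model, small_cohort[20].image)
        assert set(np.unique(mask.data)) <= {0, 1}
        assert mask.grid_shape == small_cohort[20].image.grid_shape

    def test_heldout_dice(self, trained_small, small_cohort):
        model, _ = trained_small
        ds = [dice(predict_mask(model, c.image), c.mask) for c in small_cohort[20:]]
        assert np.mean(ds) >= 0.7

    def test_zero_volume_no_failure(self, trained_small):
        model, _ = trained_small
        from mlnet.phantom import VolumeImage

        vol = VolumeImage(np.zeros((1, 16, 16, 16), np.float32), ("DWI",))
        mask = predict_mask(model, vol)
        assert set(np.unique(mask.data)) <= {0, 1}

    def test_feature_shapes_and_determinism(self, trained_small, small_cohort):
        model, _ = trained_small
        a = extract_features(model, small_cohort[21].image)
        b = extract_features(model, small_cohort[21].image)
        shapes = [f.shape[1:] for f in a.stages]
        assert shapes == [(16, 16, 16), (8, 8, 8), (4, 4, 4), (2, 2, 2)]
        for fa, fb in zip(a.stages, b.stages):
            assert np.array_equal(fa, fb)

    def test_distinct_inputs_distinct_pyramids(self, trained_small, small_cohort):
        model, _ = trained_small
        a = extract_features(model, small_cohort[0].image)
        b = extract_features(model, small_cohort[1].image)
        assert any(not np.array_equal(fa, fb) for fa, fb in zip(a.stages, b.stages))

    def test_checkpoint_round_trip(self, trained_small, small_cohort, tmp_path):
        model, _ = trained_small
        save_checkpoint(model, tmp_path / "seg.npz")
        back = load_checkpoint(tmp_path / "seg.npz")
        m1 = predict_mask(model, small_cohort[22].image)
        m2 = predict_mask(back, small_cohort[22].image)
        assert np.array_equal(m1.data, m2.data)


class TestTwoChannelArm:
    def test_dual_channel_supported(self, small_cohort):
        cfg = UNetConfig(input_channels=2, seed=5)
        model, _ = train_segmenter(small_cohort[:6], cfg, epochs=1,
                                   val_cases=small_cohort[6:8], lr=3e-3)
        mask = predict_mask(model, small_cohort[8].image)
        assert mask.grid_shape == small_cohort[8].image.grid_shape

    def test_case_input_channel_limit(self, small_case):
        with pytest.raises(ValueError):
            case_input(small_case.image, 3)


class TestCrossval:
    def test_partition_and_balance(self, small_cohort):
        cfg = UNetConfig(seed=1)
        res = crossval_segmentation(small_cohort[:10], cfg, k=5, epochs=1, lr=3e-3)
        ids = sorted(res.per_case)
        assert ids == sorted(c.patient_id for c in small_cohort[:10])
        sizes = [len(f) for f in res.fold_dices]
        assert max(sizes) - min(sizes) <= 1
        assert len(res.fold_dices) == 5

    def test_k_validation(self, small_cohort):
        with pytest.raises(ValueError):
            crossval_segmentation(small_cohort[:4], UNetConfig(), k=1)
        with pytest.raises(ValueError):
            crossval_segmentation(small_cohort[:3], UNetConfig(), k=4)

    def test_crossval_dice_on_easy_phantoms(self, small_cohort, quiet_centre, small_spec):
        from mlnet.phantom import generate_case

        extra = [
            generate_case(small_spec, quiet_centre, s % 2, 0, seed=900 + s)
            for s in range(36)
        ]
        cfg = UNetConfig(seed=2)
        res = crossval_segmentation(extra, cfg, k=4, epochs=4, lr=5e-3)
        assert res.mean_dice >= 0.7
        assert len(res.all_dices) == 36
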