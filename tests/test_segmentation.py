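import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mapchange.segmentation import (AugmentParams, TrainConfig, augment_tile,
                                    build_model, evaluate_segmentation,
                                    focal_loss, predict_sheet, train_model)
from mapchange.segmentation.losses import focal_loss_with_logits
from mapchange.segmentation.train import desk_scale_config
from mapchange.tiling import DatasetSplit, build_tile_grid, extract_tiles
from mapchange.georaster import GeoRaster, GeoTransform


def _random_probs(rng, shape, n_classes):
    raw = rng.random((*shape, n_classes)) + 1e-3
    return raw / raw.sum(axis=-1, keepdims=True)


class TestFocalLoss:
    def test_gamma_zero_equals_cross_entropy(self):
        rng = np.random.default_rng(0)
        probs = _random_probs(rng, (17, 13), 6)
        target = rng.integers(0, 6, size=(17, 13))
        got = focal_loss(probs, target, gamma=0.0)
        p_t = np.take_along_axis(probs, target[..., None], axis=-1)[..., 0]
        ce = float(-np.log(p_t).mean())
        assert got == pytest.approx(ce, abs=1e-12)

    def test_perfect_prediction_is_zero(self):
        probs = np.zeros((4, 4, 6))
        target = np.full((4, 4), 2)
        probs[..., 2] = 1.0
        assert focal_loss(probs, target, gamma=2.0) == pytest.approx(0.0, abs=1e-9)

    def test_single_pixel_hand_value(self):
        probs = np.zeros((1, 6))
        probs[0] = [0.02, 0.9, 0.02, 0.02, 0.02, 0.02]
        loss = focal_loss(probs, np.array([1]), gamma=2.0)
        assert loss == pytest.approx(0.01 * -np.log(0.9), rel=1e-6)

    def test_unnormalized_rejected(self):
        probs = np.full((2, 2, 6), 0.5)
        with pytest.raises(ValueError):
            focal_loss(probs, np.zeros((2, 2), int))

    def test_logits_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(1, 6, 3, 3)).astype(np.float64)
        target = rng.integers(0, 6, size=(1, 3, 3))
        _, grad = focal_loss_with_logits(logits, target, gamma=2.0)
        eps = 1e-5
        for idx in [(0, 0, 0, 0), (0, 3, 1, 2), (0, 5, 2, 1)]:
            up, down = logits.copy(), logits.copy()
            up[idx] += eps
            down[idx] -= eps
            lu, _ = focal_loss_with_logits(up, target, gamma=2.0)
            ld, _ = focal_loss_with_logits(down, target, gamma=2.0)
            assert grad[idx] == pytest.approx((lu - ld) / (2 * eps), abs=1e-6)


class TestMetrics:
    def test_perfect_prediction(self):
        labels = np.tile(np.arange(6, dtype=np.uint8), (10, 10))
        m = evaluate_segmentation(labels, labels)
        assert m.macro_f1 == 1.0 and m.macro_iou == 1.0

    def test_disjoint_masks_zero(self):
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a[:2] = 1
        b[2:] = 1
        row = evaluate_segmentation(a, b).per_class.loc["fields"]
        assert tuple(row) == (0.0, 0.0, 0.0, 0.0)

    def test_partial_overlap_hand_counts(self):
        pred = np.zeros((4, 4), np.uint8)
        target = np.zeros((4, 4), np.uint8)
        pred[0, :4] = 1             # 4 px predicted
        target[0, 2:] = 1
        target[1, :2] = 1           # 4 px true, overlap 2
        row = evaluate_segmentation(pred, target).per_class.loc["fields"]
        assert row["precision"] == pytest.approx(0.5)
        assert row["recall"] == pytest.approx(0.5)
        assert row["f1"] == pytest.approx(0.5)
        assert row["iou"] == pytest.approx(1 / 3, abs=1e-4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_segmentation(np.zeros((2, 2)), np.zeros((3, 3)))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_f1_iou_identity(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.integers(0, 6, size=(16, 16))
        target = rng.integers(0, 6, size=(16, 16))
        m = evaluate_segmentation(pred, target)
        for _, row in m.per_class.iterrows():
            assert row["f1"] == pytest.approx(
                2 * row["iou"] / (1 + row["iou"]), abs=1e-12
            )
            assert row["iou"] <= row["f1"] + 1e-12

    def test_swap_symmetry_of_f1_iou(self):
        rng = np.random.default_rng(5)
        pred = rng.integers(0, 6, size=(20, 20))
        target = rng.integers(0, 6, size=(20, 20))
        a = evaluate_segmentation(pred, target).per_class
        b = evaluate_segmentation(target, pred).per_class
        assert np.allclose(a["f1"], b["f1"])
        assert np.allclose(a["iou"], b["iou"])


class TestAugment:
    def _tile(self, size=32):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(size, size, 3), dtype=np.uint8)
        lab = rng.integers(0, 6, size=(size, size)).astype(np.uint8)
        return img, lab

    def test_zero_probabilities_identity(self):
        img, lab = self._tile()
        out_img, out_lab = augment_tile(img, lab, 3, AugmentParams.identity())
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_lab, lab)

    def test_flip_mirrors_labels(self):
        img, lab = self._tile()
        params = AugmentParams(p_flip=1.0, p_color=0, p_rotate=0, p_erase=0)
        _, out_lab = augment_tile(img, lab, 0, params)
        assert np.array_equal(out_lab, lab[:, ::-1])
        _, back = augment_tile(img[:, ::-1], out_lab, 0, params)
        assert np.array_equal(back, lab)

    def test_erase_fraction(self):
        img, lab = self._tile(64)
        params = AugmentParams(p_flip=0, p_color=0, p_rotate=0, p_erase=1.0,
                               erase_fraction=0.1)
        out_img, out_lab = augment_tile(img, lab, 5, params)
        changed = (out_img != img).any(axis=2).mean()
        assert 0.08 <= changed <= 0.12
        assert np.array_equal(out_lab, lab)

    def test_deterministic_under_seed(self):
        img, lab = self._tile()
        a = augment_tile(img, lab, 9)
        b = augment_tile(img, lab, 9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def _toy_dataset(n=20, size=32, seed=0):
    """Color-coded blobs: class = dominant color, learnable in 2 epochs."""
    rng = np.random.default_rng(seed)
    colors = np.array([[246, 243, 232], [250, 240, 170], [140, 140, 140],
                       [205, 50, 40], [60, 120, 230], [110, 160, 205]])
    imgs = np.zeros((n, size, size, 3), np.uint8)
    labs = np.zeros((n, size, size), np.uint8)
    for i in range(n):
        lab = np.zeros((size, size), np.uint8)
        for _ in range(3):
            cls = rng.integers(1, 6)
            r, c = rng.integers(0, size, 2)
            s = int(rng.integers(6, 16))
            lab[r : r + s, c : c + s] = cls
        labs[i] = lab
        img = colors[lab] + rng.normal(0, 4, size=(size, size, 3))
        imgs[i] = np.clip(img, 0, 255)
    return imgs, labs


def _toy_split(n=20):
    idx = tuple(range(n))
    return DatasetSplit(train=idx[: n - 8], val=idx[n - 8 : n - 4],
                        test=idx[n - 4 :])


class TestTraining:
    def test_loss_decreases(self):
        imgs, labs = _toy_dataset()
        cfg = TrainConfig(backbone="unet8", epochs_frozen=1, epochs_unfrozen=2,
                          max_lr=5e-3, augment=None, seed=0)
        model, log = train_model(cfg, _toy_split(), imgs, labs)
        assert log["train_loss"].iloc[-1] < log["train_loss"].iloc[0]
        assert list(log["phase"]) == ["frozen", "unfrozen", "unfrozen"]

    def test_zero_epochs_returns_untrained_model(self):
        imgs, labs = _toy_dataset()
        cfg = TrainConfig(epochs_frozen=0, epochs_unfrozen=0, augment=None)
        reference = build_model(cfg.backbone, seed=cfg.seed)
        model, log = train_model(cfg, _toy_split(), imgs, labs)
        assert log.empty
        for p, q in zip(model.params(), reference.params()):
            assert np.array_equal(p.value, q.value)

    def test_deterministic_under_seed(self):
        imgs, labs = _toy_dataset(n=12)
        cfg = TrainConfig(backbone="unet8", epochs_frozen=0, epochs_unfrozen=1,
                          max_lr=1e-3, augment=None, seed=4)
        split = _toy_split(12)
        _, log_a = train_model(cfg, split, imgs, labs)
        _, log_b = train_model(cfg, split, imgs, labs)
        assert log_a["train_loss"].iloc[-1] == log_b["train_loss"].iloc[-1]

    def test_frozen_phase_keeps_encoder_weights(self):
        imgs, labs = _toy_dataset(n=12)
        cfg = TrainConfig(backbone="unet8", epochs_frozen=1, epochs_unfrozen=0,
                          max_lr=5e-3, augment=None, seed=1)
        reference = build_model(cfg.backbone, seed=cfg.seed)
        model, _ = train_model(cfg, _toy_split(12), imgs, labs)
        for p, q in zip(model.encoder_params(), reference.encoder_params()):
            assert np.array_equal(p.value, q.value)
        changed = any(
            not np.array_equal(p.value, q.value)
            for p, q in zip(model.decoder_params(), reference.decoder_params())
        )
        assert changed

    def test_empty_split_rejected(self):
        imgs, labs = _toy_dataset(n=4)
        with pytest.raises(ValueError):
            train_model(
                TrainConfig(),
                DatasetSplit(train=(), val=(0,), test=(1,)),
                imgs, labs,
            )


class TestPredictSheet:
    def test_output_georeference_and_shape(self):
        model = build_model("unet8", seed=0)
        data = np.zeros((300, 340, 3), np.uint8)
        sheet = GeoRaster(data, GeoTransform(0, 300 * 1.7, 1.7))
        grid = build_tile_grid(sheet.shape, 64, 32, 48)
        out = predict_sheet(model, sheet, grid)
        assert out.shape == sheet.shape
        assert out.transform == sheet.transform

    def test_constant_sheet_constant_labels(self):
        model = build_model("unet8", seed=2)
        data = np.full((128, 128, 3), 180, np.uint8)
        sheet = GeoRaster(data, GeoTransform(0, 128 * 1.7, 1.7))
        grid = build_tile_grid(sheet.shape, 64, 64)
        out = predict_sheet(model, sheet, grid)
        # away from tile edges the prediction is translation invariant
        core = out.data[16:48, 16:48]
        assert (core == core[0, 0]).all()

    def test_sheet_smaller_than_tile_rejected(self):
        model = build_model("unet8", seed=0)
        sheet = GeoRaster(np.zeros((32, 32, 3), np.uint8),
                          GeoTransform(0, 32 * 1.7, 1.7))
        with pytest.raises(ValueError):
            predict_sheet(model, sheet)
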