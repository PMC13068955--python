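"""DCS model: losses, augmentation, architecture geometry, trained behavior."""

import numpy as np
import pytest

from fontanflow import dcs
from fontanflow.flowquant import dice
from fontanflow.nn import Tensor
from fontanflow.prep import EncodedDescription, PreparedSample


def _probs(arr):
    return Tensor(np.asarray(arr, dtype=np.float32))


class TestFocalTversky:
    def test_perfect_prediction_is_zero(self):
        truth = np.zeros((1, 2, 1, 2, 2), np.float32)
        truth[0, 0, 0, 0, 0] = 1
        truth[0, 1] = 1 - truth[0, 0]
        loss = dcs.focal_tversky_loss(_probs(truth), truth)
        assert loss.item() == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("gamma", [1.0, 4.0 / 3.0, 2.0])
    def test_disjoint_class_costs_one(self, gamma):
        truth = np.zeros((1, 2, 1, 2, 2), np.float32)
        truth[0, 0, 0, 0, 0] = 1   # foreground voxel
        pred = np.zeros_like(truth)
        pred[0, 0, 0, 1, 1] = 1    # disjoint prediction for class 0
        pred[0, 1] = truth[0, 1]   # class 1 perfect
        loss = dcs.focal_tversky_loss(_probs(pred), truth, gamma=gamma)
        assert loss.item() == pytest.approx(1.0, abs=1e-4)

    def test_hand_counted_example(self):
        # single class, 3x3 frame: TP=2, FN=1, FP=1
        truth = np.zeros((1, 1, 1, 3, 3), np.float32)
        truth[0, 0, 0, 0, :] = 1                    # 3 truth voxels
        pred = np.zeros_like(truth)
        pred[0, 0, 0, 0, 0] = pred[0, 0, 0, 0, 1] = 1  # 2 hits
        pred[0, 0, 0, 2, 2] = 1                        # 1 false positive
        alpha, beta, gamma = 0.7, 0.3, 4.0 / 3.0
        ti = 2.0 / (2.0 + alpha * 1 + beta * 1)
        expected = (1.0 - ti) ** gamma
        loss = dcs.focal_tversky_loss(_probs(pred), truth, alpha, beta, gamma)
        assert loss.item() == pytest.approx(expected, rel=1e-4)

    def test_empty_tensor_rejected(self):
        with pytest.raises(ValueError):
            dcs.focal_tversky_loss(_probs(np.zeros((0, 1, 1, 1, 1))),
                                   np.zeros((0, 1, 1, 1, 1)))


class TestCombinedLoss:
    def _setup(self, cfg):
        shape = (1, cfg.n_classes, cfg.input_frames, cfg.input_size,
                 cfg.input_size)
        truth = np.zeros(shape, np.float32)
        truth[0, 0, :, :2, :2] = 1
        truth[0, -1] = 1 - truth[0, 0]
        cls = np.zeros((1, cfg.n_classes), np.float32)
        cls[0, 0] = 1
        return truth, cls

    def test_perfect_seg_leaves_weighted_cgm_term(self):
        cfg = dcs.DCSConfig.test_profile()
        truth, cls = self._setup(cfg)
        heads = [_probs(truth)] * 5
        cgm = _probs([[0.5, 0.1, 0.1, 0.1, 0.1, 0.1]])
        total, ft, ce = dcs.combined_loss(heads, cgm, truth, cls, cfg)
        expected = sum(cfg.ds_weights) * cfg.cgm_weight * (-np.log(0.5))
        assert total.item() == pytest.approx(expected, rel=1e-4)
        # perfect classification too -> zero loss
        total0, _, _ = dcs.combined_loss(heads, _probs(cls), truth, cls, cfg)
        assert total0.item() == pytest.approx(0.0, abs=1e-5)

    def test_single_head_weighted_arithmetic(self):
        cfg = dcs.DCSConfig.test_profile()
        cfg.ds_weights = (1.0,)
        truth, cls = self._setup(cfg)
        pred = np.full_like(truth, 1.0 / cfg.n_classes)
        cgm = _probs([[0.2, 0.2, 0.2, 0.1, 0.1, 0.2]])
        ft = dcs.focal_tversky_loss(_probs(pred), truth, cfg.tversky_alpha,
                                    cfg.tversky_beta, cfg.tversky_gamma)
        ce = -np.log(0.2)
        total, _, _ = dcs.combined_loss([_probs(pred)], cgm, truth, cls, cfg)
        assert total.item() == pytest.approx(
            cfg.seg_weight * ft.item() + cfg.cgm_weight * ce, rel=1e-4)

    def test_cgm_weight_scales_classification_term(self):
        cfg = dcs.DCSConfig.test_profile()
        truth, cls = self._setup(cfg)
        heads = [_probs(truth)] * 5
        cgm = _probs([[0.5, 0.1, 0.1, 0.1, 0.1, 0.1]])
        t1, _, _ = dcs.combined_loss(heads, cgm, truth, cls, cfg)
        cfg.cgm_weight *= 2
        t2, _, _ = dcs.combined_loss(heads, cgm, truth, cls, cfg)
        assert t2.item() == pytest.approx(2 * t1.item(), rel=1e-5)

    def test_missing_head_rejected(self):
        cfg = dcs.DCSConfig.test_profile()
        truth, cls = self._setup(cfg)
        with pytest.raises(ValueError):
            dcs.combined_loss([_probs(truth)] * 4, _probs(cls), truth, cls, cfg)


def _tiny_sample(rng, size=8, frames=2):
    ch = rng.random((2, frames, size, size)).astype(np.float32)
    onehot = np.zeros(6, np.float32)
    onehot[0] = 1
    mask = rng.random((frames, size, size)) > 0.8
    return PreparedSample(channels=ch, encoded=EncodedDescription(onehot),
                          geometry=None, truth_mask=mask, truth_class=0)


class TestAugment:
    def test_identity_draw_leaves_sample_unchanged(self):
        cfg = dcs.DCSConfig.test_profile(augment_intensity=False,
                                         scramble_prob=0.0)
        rng = np.random.default_rng(0)
        s = _tiny_sample(rng)
        out = dcs.augment(s, rng, cfg, flip_sign=False)
        np.testing.assert_array_equal(out.channels, s.channels)
        np.testing.assert_array_equal(out.encoded.onehot, s.encoded.onehot)

    def test_sign_flip_preserves_magnitude_channel(self):
        cfg = dcs.DCSConfig.test_profile(augment_intensity=False,
                                         scramble_prob=0.0)
        rng = np.random.default_rng(1)
        s = _tiny_sample(rng)
        out = dcs.augment(s, rng, cfg, flip_sign=True)
        np.testing.assert_array_equal(out.channels[0], s.channels[0])
        np.testing.assert_array_equal(out.channels[1], -s.channels[1])

    def test_scramble_rate_matches_five_percent(self):
        cfg = dcs.DCSConfig.test_profile(augment_intensity=False)
        rng = np.random.default_rng(2)
        s = _tiny_sample(rng, size=4, frames=1)
        n = 10_000
        scrambled = 0
        for _ in range(n):
            out = dcs.augment(s, rng, cfg, flip_sign=False)
            scrambled += not np.array_equal(out.encoded.onehot,
                                            s.encoded.onehot)
        # replacement draws the original slot 1/6 of the time
        rate = scrambled / n / (5.0 / 6.0)
        assert 0.04 <= rate <= 0.06

    def test_geometric_transform_moves_mask_and_channels_together(self):
        cfg = dcs.DCSConfig.test_profile(augment_geometric=True,
                                         augment_intensity=False,
                                         scramble_prob=0.0)
        rng = np.random.default_rng(3)
        ch = np.zeros((2, 2, 16, 16), np.float32)
        ch[:, :, 6:10, 6:10] = 1.0
        mask = ch[0] > 0.5
        s = PreparedSample(channels=ch, encoded=EncodedDescription(
            np.eye(6, dtype=np.float32)[0]), geometry=None,
            truth_mask=mask, truth_class=0)
        out = dcs.augment(s, rng, cfg)
        inside = out.channels[0][out.truth_mask].mean()
        outside = out.channels[0][~out.truth_mask].mean()
        assert inside > 0.5 > outside


class TestModelStructure:
    def test_smoke_forward_on_reduced_profile(self):
        cfg = dcs.DCSConfig.test_profile(input_size=64, input_frames=8)
        model = dcs.DeepClassSeg(cfg)
        x = Tensor(np.random.default_rng(0).random(
            (1, 2, 8, 64, 64)).astype(np.float32))
        tun = Tensor(np.eye(6, dtype=np.float32)[:1])
        seg, cgm = model.network(x, tun)
        assert len(seg) == 5
        for head in seg:
            assert head.shape == (1, 6, 8, 64, 64)
            np.testing.assert_allclose(head.data.sum(axis=1), 1.0, atol=1e-5)
        np.testing.assert_allclose(cgm.data.sum(axis=1), 1.0, atol=1e-6)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError):
            dcs.DCSConfig(input_size=100)

    def test_zero_epoch_training_leaves_weights_unchanged(self):
        cfg = dcs.DCSConfig.test_profile()
        model = dcs.DeepClassSeg(cfg)
        before = [p.data.copy() for p in model.network.parameters()]
        rng = np.random.default_rng(0)
        model.fit([_tiny_sample(rng, size=cfg.input_size,
                                frames=cfg.input_frames)], epochs=0)
        for b, p in zip(before, model.network.parameters()):
            np.testing.assert_array_equal(b, p.data)

    def test_save_load_roundtrip(self, tmp_path):
        cfg = dcs.DCSConfig.test_profile()
        model = dcs.DeepClassSeg(cfg)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = dcs.DeepClassSeg.load(path)
        rng = np.random.default_rng(1)
        s = _tiny_sample(rng, size=cfg.input_size, frames=cfg.input_frames)
        c1, m1, conf1 = model.predict(s)
        c2, m2, conf2 = loaded.predict(s)
        assert c1 == c2 and conf1 == pytest.approx(conf2)
        np.testing.assert_array_equal(m1, m2)


class TestTrainedModel:
    """Behavioral contracts of the session-trained test-profile model."""

    def test_heldout_classification_and_segmentation(self, trained_dcs):
        best = trained_dcs["best"]
        assert best["classification_acc"] >= 0.8
        assert best["median_dice"] > 0.5  # the >= 0.85 bar is the acceptance test

    def test_training_reduces_focal_tversky(self, trained_dcs):
        h = trained_dcs["runs"][0]["history"]
        assert h["focal_tversky"].iloc[-1] < h["focal_tversky"].iloc[0]

    def test_sign_flip_invariance(self, trained_dcs):
        model = trained_dcs["model"]
        dices = []
        for s in trained_dcs["best"]["test_samples"][:5]:
            _, mask, _ = model.predict(s)
            flipped = PreparedSample(
                channels=np.stack([s.channels[0], -s.channels[1]]),
                encoded=s.encoded, geometry=s.geometry,
                truth_mask=s.truth_mask, truth_class=s.truth_class)
            _, mask_f, _ = model.predict(flipped)
            dices.append(dice(mask, mask_f))
        assert np.median(dices) >= 0.95

    def test_inference_without_description_does_not_crash(self, trained_dcs):
        model = trained_dcs["model"]
        s = trained_dcs["best"]["test_samples"][0]
        other = np.zeros(6, np.float32)
        other[-1] = 1.0
        blank = PreparedSample(channels=s.channels,
                               encoded=EncodedDescription(other),
                               geometry=s.geometry)
        cls, mask, conf = model.predict(blank)
        assert cls in dcs.CLASSES
        assert 0.0 <= conf <= 1.0

    def test_background_prediction_yields_empty_mask(self, trained_dcs):
        model = trained_dcs["model"]
        s = trained_dcs["best"]["test_samples"][0]
        bias = model.network.cgm.b.data.copy()
        try:
            model.network.cgm.b.data = bias + np.array(
                [0, 0, 0, 0, 0, 100.0], dtype=bias.dtype)
            cls, mask, conf = model.predict(s)
            assert cls == "background"
            assert not mask.any()
        finally:
            model.network.cgm.b.data = bias
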