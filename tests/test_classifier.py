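"""CNN architecture shapes, gradients, training determinism, predictions."""

import numpy as np
import pytest

import pmat.nn as nn
from pmat.classifier import (CLASSES, EXPECTED_SHAPES, HeartbeatClassifier,
                             ModelConfig, build_classifier_head,
                             build_feature_extractor, encode_labels)


def tiny_dataset(n=48, seed=0):
    rng = np.random.default_rng(seed)
    images = rng.random((n, 120, 120), dtype=np.float32)
    feats = rng.random((n, 4)).astype(np.float32)
    labels = rng.choice(CLASSES, n)
    return images, feats, labels


class TestArchitecture:
    def test_shape_chain_matches_design(self):
        extractor = build_feature_extractor()
        shape = (1, 120, 120)
        for (name, expected), layer in zip(EXPECTED_SHAPES, extractor.layers):
            shape = layer.output_shape(shape)
            assert tuple(shape) == expected, name
        assert EXPECTED_SHAPES[0][1] == (32, 116, 116)  # first conv side 116

    def test_forward_produces_128_features(self):
        extractor = build_feature_extractor()
        out = extractor.forward(np.zeros((2, 1, 120, 120), np.float32), False)
        assert out.shape == (2, 128)
        assert np.all(np.isfinite(out))

    def test_wrong_input_shape_raises_at_build(self):
        conv = nn.Conv2D(1, 32, 5, np.random.default_rng(0))
        with pytest.raises(ValueError, match="channels"):
            conv.output_shape((3, 120, 120))

    @pytest.mark.parametrize("kwargs, expected", [
        ({}, 132),
        ({"use_handcrafted": False}, 128),   # image-only ablation
        ({"use_image_branch": False}, 4),    # features-only ablation
    ])
    def test_fused_input_lengths(self, kwargs, expected):
        assert ModelConfig(**kwargs).fused_input_length == expected

    def test_head_layer_sizes(self):
        head = build_classifier_head(ModelConfig())
        dense = [l for l in head.layers if isinstance(l, nn.Dense)]
        sizes = [(d.W.value.shape[0], d.W.value.shape[1]) for d in dense]
        assert sizes == [(132, 128), (128, 64), (64, 3)]

    def test_optional_fourth_dense_layer(self):
        head = build_classifier_head(ModelConfig(extra_dense_128=True))
        dense = [l for l in head.layers if isinstance(l, nn.Dense)]
        assert [d.W.value.shape[1] for d in dense] == [128, 128, 64, 3]

    def test_config_validation(self):
        with pytest.raises(ValueError, match="at least one branch"):
            ModelConfig(use_image_branch=False, use_handcrafted=False)
        with pytest.raises(ValueError, match="end in 3"):
            ModelConfig(dense_sizes=(128, 64))

    def test_ablations_differ_only_by_branch_masking(self):
        full = ModelConfig()
        img_only = ModelConfig(use_handcrafted=False)
        assert {k: v for k, v in vars(full).items()
                if k != "use_handcrafted"} == \
               {k: v for k, v in vars(img_only).items()
                if k != "use_handcrafted"}


class TestGradients:
    """Finite-difference checks of every layer's backward pass."""

    @staticmethod
    def check(seq, x, y, spots, tol=1e-4):
        def loss_of(xx):
            l, _, _ = nn.softmax_cross_entropy(seq.forward(xx, True), y)
            return l

        logits = seq.forward(x, True)
        _, dlogits, _ = nn.softmax_cross_entropy(logits, y)
        dx = seq.backward(dlogits)
        eps = 1e-6
        for idx in spots:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            numeric = (loss_of(xp) - loss_of(xm)) / (2 * eps)
            assert abs(numeric - dx[idx]) < tol, idx

    def test_conv_bn_pool_dense_chain(self):
        rng = np.random.default_rng(1)
        seq = nn.Sequential([
            nn.Conv2D(2, 3, 3, rng), nn.BatchNorm2d(3), nn.ReLU(),
            nn.MaxPool2d(2), nn.GlobalMaxPool(), nn.Dense(3, 4, rng)])
        x = rng.standard_normal((5, 2, 9, 9))
        y = rng.integers(0, 4, 5)
        self.check(seq, x, y,
                   [(0, 0, 2, 3), (3, 1, 5, 5), (4, 0, 0, 0), (2, 1, 8, 8)])

    def test_weight_gradients(self):
        rng = np.random.default_rng(2)
        conv = nn.Conv2D(1, 2, 3, rng)
        seq = nn.Sequential([conv, nn.GlobalMaxPool(), nn.Dense(2, 3, rng)])
        x = rng.standard_normal((4, 1, 7, 7))
        y = rng.integers(0, 3, 4)

        def loss_of():
            l, _, _ = nn.softmax_cross_entropy(seq.forward(x, True), y)
            return l

        _, dlogits, _ = nn.softmax_cross_entropy(seq.forward(x, True), y)
        seq.backward(dlogits)
        eps, i = 1e-5, (1, 0, 1, 2)
        grad = conv.W.grad.copy()
        conv.W.value[i] += eps
        lp = loss_of()
        conv.W.value[i] -= 2 * eps
        lm = loss_of()
        conv.W.value[i] += eps
        assert abs((lp - lm) / (2 * eps) - grad[i]) < 1e-3

    def test_batchnorm_running_stats_used_in_eval(self):
        bn = nn.BatchNorm2d(2)
        rng = np.random.default_rng(3)
        x = rng.standard_normal((8, 2, 4, 4)).astype(np.float32)
        for _ in range(50):
            bn.forward(x, True)
        train_out = bn.forward(x, True)
        eval_out = bn.forward(x, False)
        np.testing.assert_allclose(eval_out, train_out, atol=0.2)


class TestTrainingAndPrediction:
    def test_seed_reproducibility(self):
        losses = []
        for _ in range(2):
            images, feats, labels = tiny_dataset()
            model = HeartbeatClassifier(ModelConfig(epochs=2, batch_size=16,
                                                    seed=42))
            history = model.fit(images, feats, labels)
            losses.append(history["loss"][-1])
        assert abs(losses[0] - losses[1]) < 1e-6

    def test_training_loss_decreases_on_separable_data(self, e2e_study):
        loss = e2e_study["full_model"].history["loss"]
        assert loss[0] > loss[1] > loss[2]

    def test_probabilities_sum_to_one_and_predictions_pure(self):
        images, feats, labels = tiny_dataset(n=8)
        model = HeartbeatClassifier(ModelConfig(epochs=1, batch_size=8))
        model.fit(images, feats, labels)
        probs = model.predict_proba(images, feats)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        dup = model.predict(images[[0, 0]], feats[[0, 0]])
        assert dup[0] == dup[1]

    def test_wrong_image_shape_rejected(self):
        model = HeartbeatClassifier(ModelConfig())
        with pytest.raises(ValueError, match="120x120"):
            model.predict_proba(np.zeros((1, 64, 64)), np.zeros((1, 4)))

    def test_missing_class_warns_but_trains(self):
        images, feats, _ = tiny_dataset(n=12)
        labels = np.array(["N"] * 6 + ["V"] * 6)
        model = HeartbeatClassifier(ModelConfig(
            use_image_branch=False, epochs=1, batch_size=4))
        with pytest.warns(UserWarning, match="lacks classes"):
            model.fit(None, feats, labels)

    def test_label_encoding(self):
        np.testing.assert_array_equal(encode_labels(["N", "V", "S"]),
                                      [0, 2, 1])
        with pytest.raises(ValueError, match="unknown class"):
            encode_labels(["N", "X"])

    def test_save_load_round_trip(self, tmp_path):
        images, feats, labels = tiny_dataset(n=8)
        model = HeartbeatClassifier(ModelConfig(epochs=1, batch_size=8,
                                                seed=5))
        model.fit(images, feats, labels)
        model.save(tmp_path / "model")
        restored = HeartbeatClassifier.load(tmp_path / "model")
        np.testing.assert_allclose(restored.predict_proba(images, feats),
                                   model.predict_proba(images, feats),
                                   atol=1e-7)

    def test_features_only_model_trains_fast_and_predicts(self):
        rng = np.random.default_rng(7)
        n = 300
        feats = rng.random((n, 4)).astype(np.float32)
        labels = np.where(feats[:, 3] < 0.5, "S", "N")
        model = HeartbeatClassifier(ModelConfig(use_image_branch=False,
                                                epochs=40, batch_size=32,
                                                seed=1))
        model.fit(None, feats, labels)
        preds = model.predict(None, feats)
        assert (preds == labels).mean() > 0.9
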