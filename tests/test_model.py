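"""Classifier architecture contracts and the focal loss."""

import time

import numpy as np
import pytest
from sklearn.metrics import log_loss

from ioda.model import (
    FocalLossParams,
    InsideOutsideSequenceClassifier,
    ModelConfig,
    class_vocabulary,
    focal_loss,
    focal_loss_grad,
    forward,
    predict_labels,
)
from ioda import nn


def _toy_fitted(num_classes=2, trainable=("fc", "recurrent", "head"), epochs=2, seed=0, n=6, L=8):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, L, nn.TINY_CONV_FEATURE_DIM))
    y = rng.integers(0, num_classes, (n, L))
    clf = InsideOutsideSequenceClassifier(
        num_classes=num_classes, trainable=trainable, epochs=epochs, random_state=seed
    )
    return clf.fit(X, y), X, y


class TestFocalLoss:
    def test_gamma_zero_unit_alpha_is_cross_entropy(self):
        assert focal_loss(np.array([[0.5, 0.5]]), [0], FocalLossParams(0.0, None)) == pytest.approx(
            np.log(2), abs=1e-12
        )
        rng = np.random.default_rng(0)
        raw = rng.random((1000, 5)) + 1e-3
        probs = raw / raw.sum(axis=1, keepdims=True)
        targets = rng.integers(0, 5, 1000)
        ours = focal_loss(probs, targets, FocalLossParams(0.0, None))
        reference = log_loss(targets, probs, labels=list(range(5)))
        assert ours == pytest.approx(reference, abs=1e-9)

    def test_certain_prediction_has_zero_loss_for_any_gamma(self):
        probs = np.array([[1.0, 0.0]])
        for gamma in (0.0, 0.5, 2.0, 5.0):
            assert focal_loss(probs, [0], FocalLossParams(gamma, None)) == 0.0

    def test_hand_computed_gamma_two_case(self):
        # p_true = 0.9, gamma = 2: 0.01 * (-ln 0.9)
        loss = focal_loss(np.array([[0.9, 0.1]]), [0], FocalLossParams(2.0, None))
        assert loss == pytest.approx(0.01 * -np.log(0.9), abs=1e-9)
        assert loss == pytest.approx(1.0536e-3, abs=1e-6)

    def test_zero_probability_is_clamped_finite(self):
        loss = focal_loss(np.array([[0.0, 1.0]]), [0], FocalLossParams(2.0, None))
        assert np.isfinite(loss)

    def test_monotone_decreasing_in_true_class_probability(self):
        ps = np.linspace(0.01, 0.99, 50)
        losses = [
            focal_loss(np.array([[p, 1 - p]]), [0], FocalLossParams(2.0, None)) for p in ps
        ]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_focal_bounded_by_cross_entropy_elementwise(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            p = rng.uniform(0.01, 0.99)
            probs = np.array([[p, 1 - p]])
            assert focal_loss(probs, [0], FocalLossParams(2.0, None)) <= focal_loss(
                probs, [0], FocalLossParams(0.0, None)
            )

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        logits = rng.standard_normal((2, 3, 5))
        targets = rng.integers(0, 5, (2, 3))
        params = FocalLossParams(2.0, tuple(rng.uniform(0.5, 1.5, 5)))
        _, grad = focal_loss_grad(logits, targets, params)
        eps = 1e-6
        for idx in [(0, 0, 0), (1, 2, 4), (0, 1, 2), (1, 0, 3)]:
            lp, lm = logits.copy(), logits.copy()
            lp[idx] += eps
            lm[idx] -= eps
            num = (
                focal_loss_grad(lp, targets, params)[0]
                - focal_loss_grad(lm, targets, params)[0]
            ) / (2 * eps)
            assert grad[idx] == pytest.approx(num, abs=1e-7)

    def test_negative_gamma_and_alpha_rejected(self):
        with pytest.raises(ValueError):
            FocalLossParams(-1.0, None)
        with pytest.raises(ValueError):
            FocalLossParams(2.0, (1.0, -0.5))


class TestForward:
    def test_output_shape_and_probability_rows(self):
        clf, X, _ = _toy_fitted(num_classes=5, L=32)
        scores, probs = forward(clf, X[0])
        assert scores.shape == (32, 5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_is_deterministic(self):
        clf, X, _ = _toy_fitted()
        a, _ = forward(clf, X[0])
        b, _ = forward(clf, X[0])
        assert np.array_equal(a, b)

    def test_stateless_across_sequences(self):
        # output for a sequence is independent of what was processed before
        clf, X, _ = _toy_fitted()
        first, _ = forward(clf, X[0])
        for other in X[1:]:
            forward(clf, other)
        again, _ = forward(clf, X[0])
        assert np.array_equal(first, again)

    def test_single_frame_sequence(self):
        clf, _, _ = _toy_fitted()
        scores, _ = forward(clf, np.zeros((1, nn.TINY_CONV_FEATURE_DIM)))
        assert scores.shape == (1, 2)

    def test_wrong_frame_shape_rejected(self):
        clf, _, _ = _toy_fitted()
        with pytest.raises(ValueError):
            forward(clf, np.zeros((4, 100, 100, 3)))

    def test_tiny_conv_sequence_under_one_second(self):
        clf = InsideOutsideSequenceClassifier()
        frames = np.random.default_rng(0).random((32, 224, 224, 3)).astype(np.float32)
        start = time.perf_counter()
        feats = clf.extract_features(frames)
        elapsed = time.perf_counter() - start
        assert feats.shape == (32, nn.TINY_CONV_FEATURE_DIM)
        assert elapsed < 1.0


class TestPredictLabels:
    def test_unique_maxima_are_argmax(self):
        scores = np.array([[0.1, 0.9], [0.8, 0.2]])
        assert predict_labels(scores) == ["OUTSIDE", "INSIDE"]

    def test_exact_tie_goes_outside(self):
        scores = np.array([[0.5, 0.5]])
        assert predict_labels(scores) == ["OUTSIDE"]

    def test_five_class_tie_prefers_lowest_outside_index(self):
        vocab = class_vocabulary(5)
        scores = np.zeros((1, 5))
        assert predict_labels(scores, vocabulary=vocab) == ["OUTSIDE"]

    def test_padding_rows_dropped(self):
        scores = np.tile([[0.0, 1.0]], (32, 1))
        assert len(predict_labels(scores, pad_count=28)) == 4


class TestFreezingContract:
    def test_backbone_never_changes(self):
        clf, _, _ = _toy_fitted()
        fresh = nn.tiny_conv_weights()
        for k, v in clf.backbone_weights_.items():
            assert np.array_equal(v, fresh[k])

    def test_strict_mode_trains_only_the_head(self):
        clf, _, _ = _toy_fitted(trainable=("head",))
        for name, init in clf._initial_weights_.items():
            if name.startswith("head."):
                assert not np.array_equal(clf.weights_[name], init)
            else:
                assert np.array_equal(clf.weights_[name], init)

    def test_default_mode_trains_fc_lstm_and_head(self):
        clf, _, _ = _toy_fitted()
        for name, init in clf._initial_weights_.items():
            if name.endswith(".W") or name.startswith("lstm.W"):
                assert not np.array_equal(clf.weights_[name], init)


class TestConfigAndCheckpoint:
    def test_num_classes_restricted(self):
        with pytest.raises(ValueError):
            ModelConfig(num_classes=3)

    def test_trainable_set_restricted(self):
        with pytest.raises(ValueError):
            ModelConfig(trainable_set=("backbone",))

    def test_checkpoint_round_trip(self, tmp_path):
        clf, X, _ = _toy_fitted()
        p = tmp_path / "model.npz"
        clf.save(p)
        back = InsideOutsideSequenceClassifier.load(p)
        assert np.array_equal(back.predict_proba(X), clf.predict_proba(X))
        assert list(back.classes_) == list(clf.classes_)

    def test_checkpoint_refuses_task_mismatch(self, tmp_path):
        clf, _, _ = _toy_fitted(num_classes=2)
        p = tmp_path / "model.npz"
        clf.save(p)
        with pytest.raises(ValueError, match="num_classes"):
            InsideOutsideSequenceClassifier.load(p, num_classes=5)

    def test_absent_class_gets_zero_alpha_with_warning(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 8, nn.TINY_CONV_FEATURE_DIM))
        y = np.zeros((4, 8), dtype=int)  # INSIDE only
        clf = InsideOutsideSequenceClassifier(epochs=1)
        with pytest.warns(UserWarning, match="alpha 0"):
            clf.fit(X, y)
        assert clf.focal_params_.alpha[1] == 0.0

    def test_sklearn_get_set_params_round_trip(self):
        clf = InsideOutsideSequenceClassifier(gamma=1.5)
        params = clf.get_params()
        assert params["gamma"] == 1.5
        clone = InsideOutsideSequenceClassifier().set_params(**params)
        assert clone.get_params() == params
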