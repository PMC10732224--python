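"""Classifier architecture, losses, binarisation and the LSTM localiser."""

import numpy as np
import pytest

from writhenet.models import (PARAM_BUDGET_LOCAL, PARAM_BUDGET_STS,
                              ClassifierSpec, TrainConfig, bce_loss, binarise,
                              binary_accuracy, hidden_widths, predict,
                              train_classifier)
from writhenet.rnn import BiLSTMLocaliser, LocaliserSpec, predict_mask, train_localiser


class TestArchitectureBudgets:
    @pytest.mark.parametrize("input_dim,n_classes,budget", [
        (100, 5, PARAM_BUDGET_LOCAL),
        (200, 3, PARAM_BUDGET_LOCAL),
        (300, 5, PARAM_BUDGET_LOCAL),
        (10000, 15, PARAM_BUDGET_STS),
    ])
    def test_parameter_count_within_quarter_of_budget(self, input_dim,
                                                      n_classes, budget):
        spec = ClassifierSpec(input_dim, n_classes, budget)
        assert len(spec.widths) == 4
        assert 0.75 * budget <= spec.n_parameters <= 1.25 * budget

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec(100, 1)


class TestLossesAndBinarisation:
    def test_bce_perfect_prediction_is_tiny(self):
        y = np.array([1, 0, 1, 1, 0], dtype=float)
        assert bce_loss(y, y) < 1e-5

    def test_bce_uniform_half_is_log_two(self):
        y = np.array([1, 0, 1, 0, 1, 1])
        y_hat = np.full(6, 0.5)
        assert bce_loss(y, y_hat) == pytest.approx(np.log(2), abs=1e-12)

    def test_bce_hand_computed_example(self):
        # mean of -[ln .9, ln .9, ln .8, ln .8] = -ln(0.72)/2
        y = np.array([1, 0, 1, 0], dtype=float)
        y_hat = np.array([0.9, 0.1, 0.8, 0.2])
        assert bce_loss(y, y_hat) == pytest.approx(-np.log(0.72) / 2, abs=1e-12)

    def test_bce_shape_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros(3), np.zeros(4))

    def test_binarise_heaviside_with_half_mapping_to_one(self):
        probs = np.array([0.49, 0.51, 0.5, 0.0, 1.0])
        assert binarise(probs).tolist() == [0, 1, 1, 0, 1]

    def test_binary_accuracy_counting(self):
        a = np.zeros(100, dtype=int)
        b = a.copy()
        b[:7] = 1
        assert binary_accuracy(a, a) == 1.0
        assert binary_accuracy(a, 1 - a) == 0.0
        assert binary_accuracy(b, a) == pytest.approx(0.93)

    def test_binarise_idempotent_under_rethresholding(self):
        probs = np.random.default_rng(0).random(50)
        bits = binarise(probs)
        assert np.array_equal(binarise(bits.astype(float)), bits)


class TestClassifierTraining:
    def test_separable_blobs_reach_near_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        n = 400
        x0 = rng.normal(loc=-2.0, size=(n, 20))
        x1 = rng.normal(loc=2.0, size=(n, 20))
        X = np.vstack([x0, x1])
        y = np.repeat([0, 1], n)
        spec = ClassifierSpec(20, 2)
        model, history = train_classifier(X, y, spec, TrainConfig(seed=0,
                                                                  max_epochs=60))
        acc = (model.predict(X) == y).mean()
        assert acc >= 0.99
        assert history["n_epochs"] >= 1

    def test_softmax_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 10))
        y = rng.integers(0, 3, 300)
        model, _ = train_classifier(X, y, ClassifierSpec(10, 3),
                                    TrainConfig(seed=1, max_epochs=12))
        probs = predict(model, X[:20])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_label_shuffled_features_score_at_chance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2500, 30))
        y = rng.integers(0, 5, 2500)  # labels carry no signal
        model, _ = train_classifier(X[:2000], y[:2000], ClassifierSpec(30, 5),
                                    TrainConfig(seed=2, max_epochs=30))
        acc = (model.predict(X[2000:]) == y[2000:]).mean()
        assert acc == pytest.approx(0.2, abs=0.05)


class TestLocaliser:
    def test_gradients_match_numerical_differentiation(self):
        spec = LocaliserSpec(sequence_length=7, n_features=2, hidden_size=5,
                             seed=3)
        model = BiLSTMLocaliser(spec)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 7, 2)).astype(np.float32)
        y = (rng.random((3, 7)) > 0.5).astype(np.float32)
        _, grads = model.loss_and_grads(x, y)
        worst = 0.0
        for pi, p in enumerate(model.params()):
            flat = p.ravel()
            for k in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                eps = 3e-3
                old = flat[k]
                flat[k] = old + eps
                lp, _ = model.loss_and_grads(x, y)
                flat[k] = old - eps
                lm, _ = model.loss_and_grads(x, y)
                flat[k] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[pi].ravel()[k]
                worst = max(worst, abs(num - ana) / max(abs(num), abs(ana), 1e-4))
        assert worst < 0.1  # float32 finite-difference noise floor

    def test_learns_contiguous_runs(self):
        rng = np.random.default_rng(1)
        n, T = 300, 30
        X = rng.normal(0, 0.3, (n, T)).astype(np.float32)
        Y = np.zeros((n, T), dtype=np.float32)
        for i in range(n):
            s, L = rng.integers(0, T), rng.integers(8, 16)
            idx = (s + np.arange(L)) % T
            Y[i, idx] = 1
            X[i, idx] += 1.0
        model, history = train_localiser(X, Y, max_epochs=40, seed=0)
        pred = predict_mask(model, X, binarised=True)
        assert binary_accuracy(pred, Y.astype(np.int8)) > 0.9
        assert history["val_loss"][-1] <= history["val_loss"][0]

    def test_constant_zero_masks_learned_exactly(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(150, 20)).astype(np.float32)
        Y = np.zeros((150, 20), dtype=np.float32)
        model, _ = train_localiser(X, Y, max_epochs=12, seed=0)
        pred = predict_mask(model, X, binarised=True)
        assert binary_accuracy(pred, Y.astype(np.int8)) == 1.0

    def test_probabilities_in_unit_interval(self):
        spec = LocaliserSpec(sequence_length=10, n_features=1, hidden_size=8)
        model = BiLSTMLocaliser(spec)
        probs = model.forward(np.random.default_rng(0).normal(size=(4, 10, 1)))
        assert np.all(probs >= 0) and np.all(probs <= 1)
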