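"""Stacked encoder + softmax: closed forms, gradient checks, fine-tuning."""

import numpy as np
import pytest

from ftirsel import (
    SSAEModel,
    TrainOptions,
    TrainingDivergedError,
    ValidationError,
    fine_tune,
    predict,
    sigmoid,
    softmax_probs,
    stack_pretrain,
    supervised_loss,
    supervised_loss_and_grads,
)
from conftest import rel_err


def _random_model(rng, d_in=6, sizes=(5, 4), k=3, lam=0.0):
    layers = []
    prev = d_in
    for s in sizes:
        layers.append((0.5 * rng.normal(size=(s, prev)), 0.1 * rng.normal(size=s)))
        prev = s
    theta = 0.5 * rng.normal(size=(k, prev + 1))
    return SSAEModel(encoder_layers=layers, theta=theta, lambda_decay=lam)


class TestStackPretrain:
    def test_shape_chaining(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0.1, 0.9, size=(30, 8))
        layers, hists = stack_pretrain(
            X, (4, 2), opts=TrainOptions(epochs=20, learning_rate=0.1, seed=0)
        )
        assert layers[0][0].shape == (4, 8)
        assert layers[1][0].shape == (2, 4)
        assert len(hists) == 2

    def test_single_layer_equals_sae_encoder(self):
        from ftirsel import train_sae

        rng = np.random.default_rng(1)
        X = rng.uniform(0.1, 0.9, size=(12, 5))
        opts = TrainOptions(epochs=30, learning_rate=0.1, seed=7)
        layers, _ = stack_pretrain(X, (3,), opts=opts)
        params, _ = train_sae(X, 3, opts=opts)
        assert np.array_equal(layers[0][0], params.W1)
        assert np.array_equal(layers[0][1], params.b1)


class TestSoftmax:
    def test_zero_theta_uniform_over_13(self):
        F = np.random.default_rng(2).normal(size=(5, 4))
        P = softmax_probs(np.zeros((13, 4)), F)
        assert np.allclose(P, 1 / 13)

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        theta = rng.normal(size=(4, 5))
        F = rng.normal(size=(6, 5))
        shift = rng.normal(size=5)
        assert np.allclose(
            softmax_probs(theta, F), softmax_probs(theta + shift, F), atol=1e-12
        )

    def test_two_class_reduces_to_logistic(self):
        theta = np.array([[1.0], [0.0]])
        for x in (-3.0, 0.0, 2.5):
            P = softmax_probs(theta, np.array([[x]]))
            assert P[0, 0] == pytest.approx(sigmoid(x), abs=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        P = softmax_probs(rng.normal(size=(7, 9)) * 50, rng.normal(size=(11, 9)))
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestSupervisedLoss:
    def test_uniform_prediction_is_log_k(self):
        rng = np.random.default_rng(5)
        model = _random_model(rng, k=13)
        model.theta[:] = 0.0
        X = rng.uniform(0.1, 0.9, size=(10, 6))
        y = rng.integers(0, 13, size=10)
        assert supervised_loss(model, X, y) == pytest.approx(np.log(13), abs=1e-12)

    def test_matches_per_sample_loop_oracle(self):
        rng = np.random.default_rng(6)
        model = _random_model(rng, lam=0.01)
        X = rng.uniform(0.1, 0.9, size=(7, 6))
        y = rng.integers(0, 3, size=7)
        loss = supervised_loss(model, X, y)

        total = 0.0
        for i in range(7):
            f = X[i]
            for W, b in model.encoder_layers:
                f = 1 / (1 + np.exp(-(W @ f + b)))
            f = np.append(f, 1.0)
            scores = model.theta @ f
            p = np.exp(scores) / np.exp(scores).sum()
            total -= np.log(p[y[i]])
        total = total / 7 + 0.005 * np.sum(model.theta**2)
        assert abs(loss - total) < 1e-10

    def test_label_out_of_range(self):
        rng = np.random.default_rng(7)
        model = _random_model(rng)
        with pytest.raises(ValidationError, match="label"):
            supervised_loss(model, rng.uniform(size=(2, 6)), np.array([0, 5]))

    def test_gradients_match_central_differences(self):
        rng = np.random.default_rng(8)
        model = _random_model(rng, d_in=6, sizes=(4,), k=3, lam=0.01)
        X = rng.uniform(0.1, 0.9, size=(5, 6))
        y = np.array([0, 1, 2, 1, 0])
        _, grads = supervised_loss_and_grads(model, X, y)

        eps = 1e-6
        # theta block
        num = np.zeros_like(model.theta)
        for idx in np.ndindex(model.theta.shape):
            orig = model.theta[idx]
            model.theta[idx] = orig + eps
            up = supervised_loss(model, X, y)
            model.theta[idx] = orig - eps
            down = supervised_loss(model, X, y)
            model.theta[idx] = orig
            num[idx] = (up - down) / (2 * eps)
        assert rel_err(grads["theta"], num) < 1e-5
        # every encoder block
        for li, (W, b) in enumerate(model.encoder_layers):
            for arr, g in ((W, grads["layers"][li][0]), (b, grads["layers"][li][1])):
                num = np.zeros_like(arr)
                for idx in np.ndindex(arr.shape):
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    up = supervised_loss(model, X, y)
                    arr[idx] = orig - eps
                    down = supervised_loss(model, X, y)
                    arr[idx] = orig
                    num[idx] = (up - down) / (2 * eps)
                assert rel_err(g, num) < 1e-5


class TestFineTune:
    def test_separable_two_class_reaches_full_accuracy(self):
        rng = np.random.default_rng(9)
        X = np.vstack(
            [rng.uniform(0.1, 0.3, size=(15, 4)), rng.uniform(0.7, 0.9, size=(15, 4))]
        )
        y = np.repeat([0, 1], 15)
        layers, _ = stack_pretrain(
            X, (3,), opts=TrainOptions(epochs=50, learning_rate=0.1, seed=0)
        )
        model = SSAEModel(encoder_layers=layers, lambda_decay=0.0)
        model, _ = fine_tune(
            model, X, y, TrainOptions(epochs=500, learning_rate=0.5, seed=0)
        )
        assert np.array_equal(predict(model, X), y)

    def test_huge_decay_shrinks_theta_toward_uniform(self):
        rng = np.random.default_rng(10)
        model = _random_model(rng, lam=100.0)
        X = rng.uniform(0.1, 0.9, size=(8, 6))
        y = rng.integers(0, 3, size=8)
        model, _ = fine_tune(
            model, X, y, TrainOptions(epochs=500, learning_rate=0.005, momentum=0.0,
                                      seed=0)
        )
        assert np.linalg.norm(model.theta) < 1e-2
        P = softmax_probs(model.theta, np.hstack([model.features(X), np.ones((8, 1))]))
        assert np.allclose(P, 1 / 3, atol=0.01)

    def test_deterministic_loss_history(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0.1, 0.9, size=(10, 6))
        y = rng.integers(0, 3, size=10)
        hists = []
        for _ in range(2):
            model = _random_model(np.random.default_rng(12))
            _, hist = fine_tune(
                model, X, y, TrainOptions(epochs=40, learning_rate=0.2, seed=1)
            )
            hists.append(hist)
        assert hists[0] == hists[1]

    def test_near_monotone_descent_at_default_rate(self):
        rng = np.random.default_rng(13)
        model = _random_model(rng)
        X = rng.uniform(0.1, 0.9, size=(12, 6))
        y = rng.integers(0, 3, size=12)
        _, hist = fine_tune(
            model, X, y, TrainOptions(epochs=200, learning_rate=0.1, momentum=0.0,
                                      seed=0)
        )
        increases = np.diff(hist) > np.abs(np.array(hist[:-1])) * 0.01
        assert not increases.any()

    def test_divergence_raises_with_epoch(self):
        rng = np.random.default_rng(14)
        model = _random_model(rng)
        X = rng.uniform(0.1, 0.9, size=(6, 6))
        y = rng.integers(0, 3, size=6)
        with pytest.raises(TrainingDivergedError):
            fine_tune(model, X, y, TrainOptions(epochs=10, learning_rate=1e308,
                                                seed=0))


class TestPredict:
    def test_argmax_row(self):
        model = SSAEModel(
            encoder_layers=[(np.zeros((2, 3)), np.zeros(2))],
            theta=np.array([[0.0, 0.0, 0.0], [10.0, 10.0, 5.0], [1.0, 1.0, 0.0]]),
        )
        X = np.full((1, 3), 0.5)
        assert predict(model, X)[0] == 1

    def test_exact_tie_goes_to_smaller_index(self):
        model = SSAEModel(
            encoder_layers=[(np.zeros((2, 3)), np.zeros(2))],
            theta=np.zeros((2, 3)),
        )
        assert predict(model, np.full((3, 3), 0.5)).tolist() == [0, 0, 0]

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(15)
        model = _random_model(rng)
        path = model.save(tmp_path / "model.json")
        back = SSAEModel.load(path)
        X = rng.uniform(0.1, 0.9, size=(4, 6))
        assert np.array_equal(predict(model, X), predict(back, X))
        assert np.allclose(back.theta, model.theta)
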