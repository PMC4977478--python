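"""Softplus network: forward pass, gradients, dropout, SGD training, persistence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enhancernet.network import (
    NetworkParams,
    TrainConfig,
    classify,
    forward,
    init_network,
    load_model,
    loss_and_gradients,
    predict,
    save_model,
    softplus,
    train_best,
    train_network,
)


class TestSoftplus:
    def test_closed_form_at_zero(self):
        assert softplus(0.0) == pytest.approx(math.log(2))

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-500, 500))
    def test_softplus_minus_mirrored_softplus_is_identity(self, x):
        assert softplus(x) - softplus(-x) == pytest.approx(x, abs=1e-9)

    def test_no_overflow_for_large_arguments(self):
        assert softplus(1000.0) == pytest.approx(1000.0)
        assert softplus(-1000.0) == pytest.approx(0.0)


class TestInit:
    def test_same_seed_reproduces_parameters(self):
        a = init_network([4, 3, 1], seed=5)
        b = init_network([4, 3, 1], seed=5)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_weight_shapes_chain_with_layer_sizes(self):
        p = init_network([4, 3, 1], seed=0)
        assert [w.shape for w in p.weights] == [(4, 3), (3, 1)]
        assert [b.shape for b in p.biases] == [(3,), (1,)]

    def test_different_seeds_differ(self):
        a = init_network([4, 3, 1], seed=1)
        b = init_network([4, 3, 1], seed=2)
        assert any(not np.array_equal(x, y) for x, y in zip(a.weights, b.weights))

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            NetworkParams((3, 2, 1), [np.zeros((3, 3))], [np.zeros(2)])
        with pytest.raises(ValueError):
            NetworkParams((3, 2), [np.zeros((3, 2))], [np.zeros(2)])  # output != 1


def zero_net(sizes=(3, 2, 1)):
    weights = [np.zeros((a, b)) for a, b in zip(sizes[:-1], sizes[1:])]
    biases = [np.zeros(b) for b in sizes[1:]]
    return NetworkParams(tuple(sizes), weights, biases)


class TestForward:
    def test_all_zero_parameters_give_log2_score(self):
        p = zero_net()
        # hidden softplus(0)=ln2 contributes nothing through zero weights
        assert forward(p, np.zeros((1, 3)))[0] == pytest.approx(math.log(2))

    def test_two_layer_unit_chain_hand_computed(self):
        # 1-1-1 net, all weights 1, biases 0, input 0:
        # hidden = softplus(0) = ln 2; output = softplus(ln 2) = ln 3
        p = NetworkParams((1, 1, 1), [np.ones((1, 1)), np.ones((1, 1))],
                          [np.zeros(1), np.zeros(1)])
        assert forward(p, [[0.0]])[0] == pytest.approx(math.log(3))

    def test_full_dropout_mask_leaves_only_output_bias(self):
        rng = np.random.default_rng(0)
        p = init_network([3, 4, 1], seed=0)
        p.biases[-1][:] = 0.7
        masks = [np.zeros((1, 4))]
        score = forward(p, rng.random((1, 3)), dropout_masks=masks, dropout_rate=0.5)
        assert score[0] == pytest.approx(softplus(0.7))

    def test_dimension_mismatch_rejected(self):
        p = zero_net()
        with pytest.raises(ValueError):
            forward(p, np.zeros((1, 5)))

    def test_linear_output_activation(self):
        p = zero_net()
        p.output_activation = "linear"
        p.biases[-1][:] = -3.0
        assert forward(p, np.zeros((1, 3)))[0] == pytest.approx(
            -3.0 + 2 * 0.0  # zero weights: only the bias
        )


class TestGradients:
    @pytest.mark.parametrize("output_activation", ["softplus", "linear"])
    @pytest.mark.parametrize("dropout", [False, True])
    def test_analytic_matches_central_differences(self, output_activation, dropout):
        """5-4-3-1 network: relative error below 1e-5 against finite differences."""
        rng = np.random.default_rng(42)
        params = init_network([5, 4, 3, 1], seed=1,
                              output_activation=output_activation)
        X = rng.normal(size=(7, 5))
        y = rng.integers(0, 2, size=7).astype(float)
        masks = None
        rate = 0.0
        if dropout:
            rate = 0.5
            masks = [(rng.random((7, h)) >= rate).astype(float) for h in (4, 3)]
        _, gW, gb = loss_and_gradients(params, X, y, masks, rate)
        eps = 1e-6
        worst = 0.0
        for l in range(len(params.weights)):
            for arr, grad in ((params.weights[l], gW[l]), (params.biases[l], gb[l])):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    lp, _, _ = loss_and_gradients(params, X, y, masks, rate)
                    arr[idx] = orig - eps
                    lm, _, _ = loss_and_gradients(params, X, y, masks, rate)
                    arr[idx] = orig
                    numeric = (lp - lm) / (2 * eps)
                    denom = max(abs(numeric), abs(grad[idx]), 1e-8)
                    worst = max(worst, abs(numeric - grad[idx]) / denom)
        assert worst < 1e-5

    def test_dropout_expectation_matches_no_dropout(self):
        """Inverted scaling: E over masks of the output equals the mask-free output."""
        rng = np.random.default_rng(0)
        params = init_network([3, 5, 1], seed=3, output_activation="linear")
        x = rng.normal(size=(1, 3))
        clean = forward(params, x)[0]
        rate = 0.5
        n = 20_000
        masks = (rng.random((n, 5)) >= rate).astype(float)
        scores = forward(params, np.repeat(x, n, axis=0),
                         dropout_masks=[masks], dropout_rate=rate)
        assert np.mean(scores) == pytest.approx(clean, rel=0.01, abs=0.01)


class TestTraining:
    @staticmethod
    def toy_data(n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 2)) + 3.0 * y[:, None]
        return X, y.astype(float)

    def test_training_reduces_mse_on_separable_data(self):
        X, y = self.toy_data()
        cfg = TrainConfig(hidden_sizes=(8,), epochs=50, seed=0, learning_rate=0.05)
        _, losses = train_network(X, y, cfg)
        assert losses[-1] < losses[0]

    def test_five_epoch_descent_sanity(self):
        X, y = self.toy_data()
        cfg = TrainConfig(hidden_sizes=(8,), epochs=5, seed=0, learning_rate=0.05)
        _, losses = train_network(X, y, cfg)
        assert losses[-1] <= losses[0]

    def test_same_seed_gives_identical_parameters(self):
        X, y = self.toy_data()
        cfg = TrainConfig(hidden_sizes=(6, 4), epochs=3, seed=11)
        p1, l1 = train_network(X, y, cfg)
        p2, l2 = train_network(X, y, cfg)
        assert l1 == l2
        for a, b in zip(p1.weights, p2.weights):
            np.testing.assert_array_equal(a, b)

    def test_zero_dropout_equals_explicit_all_ones_masks(self):
        # dropout_rate=0 draws all-ones masks, so the path reduces to plain SGD
        X, y = self.toy_data(n=64)
        cfg = TrainConfig(hidden_sizes=(5,), epochs=2, seed=2, dropout_rate=0.0)
        params, _ = train_network(X, y, cfg)
        scores = predict(params, X)
        assert np.all(np.isfinite(scores))

    def test_divergence_raises_with_diagnostic(self):
        X, y = self.toy_data(n=100)
        cfg = TrainConfig(hidden_sizes=(8,), epochs=20, seed=0,
                          learning_rate=1e6, output_activation="linear")
        with pytest.raises(FloatingPointError, match="learning_rate"):
            train_network(1e3 * X, y, cfg)

    def test_invalid_labels_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="labels"):
            train_network(X, np.array([0, 1, 2, 0]), TrainConfig(hidden_sizes=(3,)))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_network(np.zeros((0, 2)), np.zeros(0), TrainConfig(hidden_sizes=(3,)))

    def test_train_best_selects_lowest_training_error(self):
        X, y = self.toy_data()
        cfg = TrainConfig(hidden_sizes=(8,), epochs=10, seed=4, learning_rate=0.05)
        _, losses = train_best(X, y, cfg, n_restarts=3)
        singles = []
        from dataclasses import replace
        for r in range(3):
            c = replace(cfg, seed=int((cfg.seed + 7919 * r) % 2**31))
            _, l = train_network(X, y, c)
            singles.append(l[-1])
        assert losses[-1] == min(singles)


class TestPredictClassify:
    def test_duplicate_rows_get_identical_scores(self):
        p = init_network([3, 4, 1], seed=0)
        x = np.array([[0.5, -1.0, 2.0]])
        s = predict(p, np.vstack([x, x]))
        assert s[0] == s[1]

    def test_softplus_scores_nonnegative_and_empty_input(self):
        p = init_network([3, 4, 1], seed=0)
        rng = np.random.default_rng(1)
        assert np.all(predict(p, rng.normal(size=(20, 3))) >= 0)
        assert predict(p, np.empty((0, 3))).size == 0

    def test_classify_is_strict(self):
        scores = np.array([0.1, 0.9])
        np.testing.assert_array_equal(classify(scores, 0.5), [0, 1])
        np.testing.assert_array_equal(classify(scores, -np.inf), [1, 1])
        np.testing.assert_array_equal(classify(scores, scores.max()), [0, 0])


def test_model_persistence_roundtrip(tmp_path):
    cfg = TrainConfig(hidden_sizes=(4, 3), epochs=2, seed=9)
    rng = np.random.default_rng(0)
    X, y = rng.normal(size=(30, 5)), rng.integers(0, 2, 30).astype(float)
    params, _ = train_network(X, y, cfg)
    path = tmp_path / "model.npz"
    save_model(path, params, cfg)
    loaded, loaded_cfg = load_model(path)
    assert loaded.layer_sizes == params.layer_sizes
    assert loaded_cfg == cfg
    np.testing.assert_array_equal(predict(loaded, X), predict(params, X))
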