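import dataclasses
import math

import numpy as np
import pytest

from ppifuse.neural import (
    LstmParams,
    RbmParams,
    TrainConfig,
    _CdState,
    cd1_epoch,
    cross_entropy,
    dbn_forward,
    lstm_forward,
    lstm_loss_and_grads,
    prob_hidden,
    prob_visible,
    rbm_energy,
    train_dbn_predict,
    train_mrnn,
)


def planted_dataset(n=120, d=10, seed=0):
    """Features with a linear-logistic planted signal in the unit cube."""
    rng = np.random.default_rng(seed)
    x = rng.random((n, d))
    w = rng.normal(size=d) * 3.0
    p = 1.0 / (1.0 + np.exp(-(x - 0.5) @ w))
    y = (rng.random(n) < p).astype(float)
    return x, y


class TestLstmForward:
    def test_zero_parameters_score_half(self):
        params = LstmParams.zeros(4)
        assert lstm_forward(params, np.zeros(6)) == pytest.approx(0.5)
        assert lstm_forward(params, np.ones(6)) == pytest.approx(0.5)

    def test_single_step_matches_hand_unrolled_gates(self):
        # hidden size 1, one timestep, hand-set scalar parameters
        params = LstmParams.zeros(1, dense_sizes=())
        params.w_x = np.array([0.5, -0.3, 0.8, 0.2])  # [f, i, g, o] input weights
        params.b = np.array([0.1, 0.0, -0.1, 0.3])
        params.dense = [(np.array([[2.0]]), np.array([0.5]))]
        x = 0.7
        f = 1 / (1 + math.exp(-(0.5 * x + 0.1)))
        i = 1 / (1 + math.exp(-(-0.3 * x)))
        g = math.tanh(0.8 * x - 0.1)
        o = 1 / (1 + math.exp(-(0.2 * x + 0.3)))
        c = i * g  # previous cell state is zero
        h = o * math.tanh(c)
        expected = 1 / (1 + math.exp(-(2.0 * h + 0.5)))
        assert lstm_forward(params, np.array([x])) == pytest.approx(expected, abs=1e-12)

    def test_scores_stay_in_open_unit_interval(self):
        rng = np.random.default_rng(0)
        params = LstmParams.init(8, (16, 8), rng)
        scores = lstm_forward(params, rng.random((20, 12)))
        assert np.all((scores > 0) & (scores < 1))


class TestCrossEntropy:
    def test_perfect_prediction_is_almost_free(self):
        assert cross_entropy([1.0, 0.0], [1.0, 0.0]) < 1e-10

    def test_half_score_on_positive_label(self):
        assert cross_entropy([1.0], [0.5]) == pytest.approx(math.log(2), abs=1e-12)

    def test_non_negative(self):
        rng = np.random.default_rng(3)
        y = (rng.random(50) < 0.5).astype(float)
        assert cross_entropy(y, rng.random(50)) >= 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy([1.0], [0.5, 0.5])


class TestLstmTraining:
    def test_gradients_match_numerical_differentiation(self):
        rng = np.random.default_rng(0)
        params = LstmParams.init(3, (4, 2), rng)
        x = rng.random((1, 5))
        y = np.array([1.0])
        _, grads = lstm_loss_and_grads(params, x, y)
        for name, arr in params.named_arrays():
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                h = 1e-6
                arr[idx] = orig + h
                up = cross_entropy(y, np.atleast_1d(lstm_forward(params, x)))
                arr[idx] = orig - h
                down = cross_entropy(y, np.atleast_1d(lstm_forward(params, x)))
                arr[idx] = orig
                numeric = (up - down) / (2 * h)
                scale = max(abs(numeric), abs(grads[name][idx]), 1e-8)
                assert abs(numeric - grads[name][idx]) / scale < 1e-4

    def test_training_reduces_loss_on_planted_signal(self):
        x, y = planted_dataset(200, 8, seed=1)
        config = TrainConfig(seed=1, rnn_epochs=30)
        _, trace = train_mrnn(x, y, config)
        assert trace[-1] < trace[0]

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        x, y = planted_dataset(40, 4, seed=2)
        config = TrainConfig(seed=2, rnn_lr=0.0, rnn_epochs=3)
        params, trace = train_mrnn(x, y, config)
        fresh = LstmParams.init(config.lstm_hidden, config.dense_sizes, np.random.default_rng(2))
        for (_, a), (_, b) in zip(params.named_arrays(), fresh.named_arrays()):
            np.testing.assert_array_equal(a, b)
        assert np.allclose(trace, trace[0])

    def test_same_seed_gives_identical_traces(self):
        x, y = planted_dataset(60, 5, seed=3)
        config = TrainConfig(seed=7, rnn_epochs=5)
        _, t1 = train_mrnn(x, y, config)
        _, t2 = train_mrnn(x, y, config)
        np.testing.assert_array_equal(t1, t2)


class TestRbm:
    def test_energy_of_zero_configuration_is_zero(self):
        params = RbmParams(np.ones((2, 2)), np.ones(2), np.ones(2))
        assert rbm_energy(params, np.zeros(2), np.zeros(2)) == 0.0

    def test_energy_hand_sum(self):
        params = RbmParams(np.array([[1.0]]), np.array([0.5]), np.array([0.25]))
        assert rbm_energy(params, np.array([1.0]), np.array([1.0])) == pytest.approx(-1.75)

    def test_energy_is_linear_in_biases(self):
        rng = np.random.default_rng(4)
        v, h = rng.random(3), rng.random(2)
        w = rng.normal(size=(3, 2))
        e1 = rbm_energy(RbmParams(w, np.ones(3), np.zeros(2)), v, h)
        e2 = rbm_energy(RbmParams(w, 2 * np.ones(3), np.zeros(2)), v, h)
        e0 = rbm_energy(RbmParams(w, np.zeros(3), np.zeros(2)), v, h)
        assert e2 - e1 == pytest.approx(e1 - e0)

    def test_zero_parameters_give_half_probabilities(self):
        params = RbmParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        np.testing.assert_allclose(prob_hidden(params, np.ones(3)), 0.5)
        np.testing.assert_allclose(prob_visible(params, np.ones(2)), 0.5)

    def test_probability_grows_monotonically_with_bias(self):
        probs = [
            prob_hidden(RbmParams(np.zeros((1, 1)), np.zeros(1), np.array([b])), np.ones(1))[0, 0]
            for b in (0.0, 1.0, 5.0, 20.0)
        ]
        assert np.all(np.diff(probs) > 0) and probs[-1] > 0.999

    def test_conditionals_match_direct_sigmoid_oracle(self):
        rng = np.random.default_rng(5)
        params = RbmParams(rng.normal(size=(4, 3)), rng.normal(size=4), rng.normal(size=3))
        v = rng.random(4)
        expected = 1 / (1 + np.exp(-(params.b_hidden + v @ params.w)))
        np.testing.assert_allclose(prob_hidden(params, v)[0], expected, atol=1e-12)


class TestCd1:
    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        rng = np.random.default_rng(6)
        params = RbmParams.init(4, 3, rng)
        before = params.w.copy()
        config = TrainConfig(seed=0, dbn_lr=0.0)
        cd1_epoch(params, rng.random((10, 4)), config, rng)
        np.testing.assert_array_equal(params.w, before)

    def test_empty_batch_is_rejected(self):
        params = RbmParams.init(4, 3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            cd1_epoch(params, np.empty((0, 4)), TrainConfig(), np.random.default_rng(0))

    def test_reconstruction_error_decreases_on_bernoulli_patterns(self):
        rng = np.random.default_rng(0)
        protos = rng.random((4, 8)) < 0.5
        data = np.array(
            [protos[rng.integers(4)] ^ (rng.random(8) < 0.1) for _ in range(64)], dtype=float
        )
        params = RbmParams.init(8, 16, rng)
        state = _CdState.zeros(params)
        config = TrainConfig(seed=0)
        errors = [cd1_epoch(params, data, config, rng, epoch, state) for epoch in range(50)]
        assert np.median(errors[-5:]) < np.median(errors[:5])
        assert np.all(np.isfinite(params.w))


class TestDbn:
    def test_scores_in_unit_interval_and_deterministic(self):
        x, y = planted_dataset(80, 6, seed=8)
        config = TrainConfig(seed=9, pretrain_epochs=10, finetune_epochs=20)
        _, s1 = train_dbn_predict(x, y, config)
        _, s2 = train_dbn_predict(x, y, config)
        assert np.all((s1 > 0) & (s1 < 1))
        np.testing.assert_array_equal(s1, s2)

    def test_finetuning_reduces_loss_on_planted_signal(self):
        x, y = planted_dataset(150, 8, seed=10)
        config = TrainConfig(seed=11, pretrain_epochs=10, finetune_epochs=40)
        model, _ = train_dbn_predict(x, y, config)
        assert model.finetune_trace[-1] < model.finetune_trace[0]

    def test_unscaled_input_is_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            train_dbn_predict(np.array([[2.0, 0.5]]), np.array([1.0]), TrainConfig())

    def test_forward_is_pure_function_of_parameters(self):
        x, y = planted_dataset(50, 5, seed=12)
        config = TrainConfig(seed=13, pretrain_epochs=5, finetune_epochs=5)
        model, _ = train_dbn_predict(x, y, config)
        np.testing.assert_array_equal(dbn_forward(model, x), dbn_forward(model, x))
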