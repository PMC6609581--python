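import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dbnexpr.rbm import (
    CDConfig,
    CDState,
    MinMaxScaler,
    RBMModel,
    cd_update,
    exact_log_likelihood,
    hidden_probs,
    init_rbm,
    pretrain_stack,
    sample_binary,
    stack_transform,
    train_rbm,
    visible_probs,
)


def zero_rbm(nv, nh):
    return RBMModel(np.zeros((nv, nh)), np.zeros(nv), np.zeros(nh))


class TestConditionals:
    def test_zero_parameters_give_half(self):
        m = zero_rbm(3, 2)
        np.testing.assert_allclose(hidden_probs(m, np.ones(3)), 0.5)
        np.testing.assert_allclose(visible_probs(m, np.ones(2)), 0.5)

    def test_unit_weight_logistic_value(self):
        m = RBMModel(np.array([[1.0]]), np.zeros(1), np.zeros(1))
        assert hidden_probs(m, np.array([1.0]))[0] == pytest.approx(
            0.7310585786, abs=1e-9)

    def test_bias_saturation(self):
        m = RBMModel(np.zeros((2, 2)), np.zeros(2), np.array([20.0, -20.0]))
        p = hidden_probs(m, np.zeros(2))
        assert p[0] == pytest.approx(1.0, abs=1e-8)
        assert p[1] == pytest.approx(0.0, abs=1e-8)

    def test_visible_probs_cancellation(self):
        m = RBMModel(np.array([[2.0]]), np.array([-2.0]), np.zeros(1))
        assert visible_probs(m, np.array([1.0]))[0] == pytest.approx(0.5)

    def test_shape_mismatch_rejected(self):
        m = zero_rbm(3, 2)
        with pytest.raises(ValueError):
            hidden_probs(m, np.ones(4))
        with pytest.raises(ValueError):
            visible_probs(m, np.ones(3))

    def test_weight_symmetry_contract(self):
        rng = np.random.default_rng(0)
        m = RBMModel(rng.normal(size=(4, 3)), rng.normal(size=4),
                     rng.normal(size=3))
        transposed = RBMModel(m.weights.T, m.hidden_bias, m.visible_bias)
        h = rng.random(3)
        np.testing.assert_allclose(visible_probs(m, h),
                                   hidden_probs(transposed, h))

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-5, 5))
    def test_probs_in_open_unit_interval_and_monotone_in_bias(self, seed, shift):
        rng = np.random.default_rng(seed)
        m = RBMModel(rng.normal(size=(3, 2)), rng.normal(size=3),
                     rng.normal(size=2))
        v = rng.random(3)
        p = hidden_probs(m, v)
        assert np.all((p > 0) & (p < 1))
        m2 = RBMModel(m.weights, m.visible_bias, m.hidden_bias + abs(shift))
        assert np.all(hidden_probs(m2, v) >= p)


class TestSampleBinary:
    def test_degenerate_probabilities(self):
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(sample_binary(np.zeros(5), rng), 0)
        np.testing.assert_array_equal(sample_binary(np.ones(5), rng), 1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sample_binary(np.array([1.2]), np.random.default_rng(0))

    def test_mean_within_binomial_bound(self):
        rng = np.random.default_rng(123)
        draws = sample_binary(np.full(1000, 0.5), rng)
        sd = np.sqrt(0.25 / 1000)
        assert abs(draws.mean() - 0.5) < 4 * sd


def enumerate_negative_statistic(lr):
    """Independent oracle: expected CD-1 Δw for a 2-visible/1-hidden RBM at
    zero parameters on the single pattern [1, 1].

    Enumerates the hidden state h0 ∈ {0, 1}; at zero parameters the
    reconstruction probabilities are 0.5 regardless, giving the exact
    expectation of the negative statistic v¹·h¹-prob.
    """
    pos = np.array([1.0, 1.0]) * 0.5  # v0=1, h0-prob = sigmoid(0) = 0.5
    neg = 0.0
    for h0 in (0.0, 1.0):
        p_h0 = 0.5
        v1 = np.array([0.5, 0.5])  # sigmoid(0)
        h1 = 0.5
        neg += p_h0 * v1 * h1
    return lr * (pos - neg)


class TestCDUpdate:
    def test_expected_first_step_matches_enumeration(self):
        cfg = CDConfig(learning_rate=0.1, weight_cost=0.0, momentum=0.0)
        expected = enumerate_negative_statistic(cfg.learning_rate)
        updates = []
        for seed in range(10_000):
            m = zero_rbm(2, 1)
            rng = np.random.default_rng(seed)
            new, _ = cd_update(m, np.array([[1.0, 1.0]]), cfg,
                               CDState.zeros_like(m), rng)
            updates.append(new.weights[:, 0])
        mean_dw = np.mean(updates, axis=0)
        # Monte-Carlo error bound: the update is in [−lr, lr]
        np.testing.assert_allclose(mean_dw, expected, atol=4 * 0.1 / 100)

    def test_zero_learning_rate_leaves_model_unchanged(self):
        cfg = CDConfig(learning_rate=0.0, weight_cost=0.0, momentum=0.0)
        m = init_rbm(3, 2, seed=1)
        new, _ = cd_update(m, np.array([[1.0, 0.0, 1.0]]), cfg,
                           CDState.zeros_like(m), np.random.default_rng(0))
        np.testing.assert_array_equal(new.weights, m.weights)
        np.testing.assert_array_equal(new.hidden_bias, m.hidden_bias)

    def test_batch_outside_unit_interval_rejected(self):
        m = zero_rbm(2, 1)
        with pytest.raises(ValueError):
            cd_update(m, np.array([[2.0, 0.0]]), CDConfig(),
                      CDState.zeros_like(m), np.random.default_rng(0))


def independent_nll(m, patterns):
    """Exact mean NLL by brute-force enumeration, written independently of
    the package's own enumeration helper."""
    nv, nh = m.n_visible, m.n_hidden
    states_v = list(itertools.product([0, 1], repeat=nv))
    states_h = list(itertools.product([0, 1], repeat=nh))
    weights = []
    for v in states_v:
        for h in states_h:
            v, h = np.array(v, float), np.array(h, float)
            weights.append(np.exp(v @ m.visible_bias + h @ m.hidden_bias
                                  + v @ m.weights @ h))
    Z = np.sum(weights)
    nll = 0.0
    for p in np.atleast_2d(patterns):
        num = sum(
            np.exp(p @ m.visible_bias + np.array(h, float) @ m.hidden_bias
                   + p @ m.weights @ np.array(h, float))
            for h in states_h
        )
        nll -= np.log(num / Z)
    return nll / len(np.atleast_2d(patterns))


class TestTrainRBM:
    def test_zero_epochs_returns_initialization(self):
        data = np.array([[1.0, 0.0, 1.0]])
        cfg = CDConfig(epochs=0, seed=4)
        m = train_rbm(data, 2, cfg)
        np.testing.assert_array_equal(m.weights, init_rbm(3, 2, seed=4).weights)

    def test_training_raises_exact_pattern_likelihood(self):
        patterns = np.array([[1.0, 1.0, 1.0]])
        cfg = CDConfig(epochs=500, batch_size=1, learning_rate=0.1, seed=0)
        m0 = init_rbm(3, 2, seed=0)
        m = train_rbm(patterns, 2, cfg)
        assert exact_log_likelihood(m, patterns) > exact_log_likelihood(m0, patterns)
        # the package's enumeration agrees with an independent brute force
        np.testing.assert_allclose(-exact_log_likelihood(m, patterns),
                                   independent_nll(m, patterns), rtol=1e-10)

    def test_seed_determinism(self):
        data = np.random.default_rng(1).random((20, 4))
        cfg = CDConfig(epochs=5, seed=11)
        a, b = train_rbm(data, 3, cfg), train_rbm(data, 3, cfg)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestPretrainStack:
    def test_layer_chaining(self):
        data = np.random.default_rng(0).random((15, 20))
        stack = pretrain_stack(data, [8, 3], CDConfig(epochs=2, seed=0))
        assert [r.n_visible for r in stack] == [20, 8]
        assert [r.n_hidden for r in stack] == [8, 3]

    def test_single_layer(self):
        data = np.random.default_rng(0).random((10, 6))
        stack = pretrain_stack(data, [5], CDConfig(epochs=1, seed=0))
        assert len(stack) == 1 and stack[0].n_hidden == 5

    def test_empty_hidden_sizes(self):
        assert pretrain_stack(np.zeros((3, 4)), [], CDConfig()) == []

    def test_stack_transform_chains_hidden_probs(self):
        data = np.random.default_rng(2).random((8, 10))
        stack = pretrain_stack(data, [6, 4], CDConfig(epochs=1, seed=2))
        manual = hidden_probs(stack[1], hidden_probs(stack[0], data))
        np.testing.assert_allclose(stack_transform(stack, data), manual)


class TestMinMaxScaler:
    def test_transform_range_and_train_parameters(self):
        X = np.array([[0.0, 10.0], [5.0, 20.0]])
        s = MinMaxScaler().fit(X)
        out = s.transform(X)
        assert out.min() == 0.0 and out.max() == 1.0
        # test data outside the training range are clipped
        np.testing.assert_array_equal(
            s.transform(np.array([[-1.0, 30.0]])), [[0.0, 1.0]])

    def test_constant_gene_maps_to_zero(self):
        X = np.array([[3.0], [3.0]])
        np.testing.assert_array_equal(MinMaxScaler().fit_transform(X), 0.0)
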