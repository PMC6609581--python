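import numpy as np
import pytest

from dbnexpr.finetune import (
    RpropState,
    SGDState,
    TrainConfig,
    backprop_gradients,
    batch_objective,
    irpropplus_step,
    momentum_at_epoch,
    normalize_weights,
    sgd_step,
    train,
)
from dbnexpr.network import NetworkModel, OutputEncoding, forward_batch, init_random


def finite_difference_grads(m, X, T, h=1e-5):
    """Central finite differences of the implemented per-batch objective."""
    fd_w, fd_b = [], []
    for l in range(len(m.weights)):
        gw = np.zeros_like(m.weights[l])
        for idx in np.ndindex(*m.weights[l].shape):
            mp, mm = m.copy(), m.copy()
            mp.weights[l][idx] += h
            mm.weights[l][idx] -= h
            gw[idx] = (batch_objective(mp, X, T) - batch_objective(mm, X, T)) / (2 * h)
        fd_w.append(gw)
        gb = np.zeros_like(m.biases[l])
        for i in range(len(gb)):
            mp, mm = m.copy(), m.copy()
            mp.biases[l][i] += h
            mm.biases[l][i] -= h
            gb[i] = (batch_objective(mp, X, T) - batch_objective(mm, X, T)) / (2 * h)
        fd_b.append(gb)
    return fd_w, fd_b


def max_relative_deviation(m, X, T):
    g = backprop_gradients(m, X, T)
    fd_w, fd_b = finite_difference_grads(m, X, T)
    devs = []
    for a, b in zip(g.weight_grads + g.bias_grads, fd_w + fd_b):
        devs.append(np.max(np.abs(a - b) / np.maximum(1.0, np.abs(b))))
    return max(devs)


class TestBackpropGradients:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            sizes = rng.choice([2, 3, 4, 5], size=rng.integers(2, 4)).tolist()
            m = init_random(sizes, seed=trial)
            for w in m.weights:
                w += rng.normal(scale=0.5, size=w.shape)
            X = rng.random((rng.integers(1, 6), sizes[0]))
            T = rng.random((X.shape[0], sizes[-1]))
            assert max_relative_deviation(m, X, T) <= 1e-6

    def test_perfect_fit_gives_zero_gradients(self):
        m = init_random([3, 2], seed=0)
        X = np.random.default_rng(1).random((4, 3))
        T = forward_batch(m, X)[-1]
        g = backprop_gradients(m, X, T)
        for arr in g.weight_grads + g.bias_grads:
            np.testing.assert_array_equal(arr, 0.0)

    def test_one_one_net_closed_form(self):
        # w=0, b=0, x=1, t=1: a=0.5, phi'=0.25, delta = (0.5-1)*0.25 = -0.125
        m = NetworkModel([1, 1], [np.zeros((1, 1))], [np.zeros(1)])
        g = backprop_gradients(m, np.array([[1.0]]), np.array([[1.0]]))
        assert g.bias_grads[0][0] == pytest.approx(-0.125)
        assert g.weight_grads[0][0, 0] == pytest.approx(-0.125)

    def test_shape_mismatch_rejected(self):
        m = init_random([3, 2], seed=0)
        with pytest.raises(ValueError):
            backprop_gradients(m, np.ones((2, 3)), np.ones((2, 3)))


class TestSGDStep:
    def _grads(self, m, scale=0.0):
        from dbnexpr.finetune import GradientSet
        return GradientSet(
            deltas=[],
            weight_grads=[np.full_like(w, scale) for w in m.weights],
            bias_grads=[np.full_like(b, scale) for b in m.biases],
        )

    def test_plain_gradient_descent(self):
        m = init_random([2, 1], seed=0)
        cfg = TrainConfig(algorithm="bprop", learning_rate=0.5,
                          weight_cost=0.0, momentum=0.0)
        new, _ = sgd_step(m, self._grads(m, scale=1.0), cfg,
                          SGDState.zeros_like(m), momentum=0.0)
        np.testing.assert_allclose(new.weights[0], m.weights[0] - 0.5)

    def test_weight_cost_scales_weights(self):
        m = init_random([2, 1], seed=0)
        cfg = TrainConfig(algorithm="bprop", weight_cost=0.1, momentum=0.0)
        new, _ = sgd_step(m, self._grads(m), cfg, SGDState.zeros_like(m),
                          momentum=0.0)
        np.testing.assert_allclose(new.weights[0], 0.9 * m.weights[0])
        np.testing.assert_allclose(new.biases[0], m.biases[0])  # biases exempt

    def test_momentum_is_only_surviving_term(self):
        m = init_random([1, 1], seed=0)
        cfg = TrainConfig(algorithm="bprop", weight_cost=0.0, momentum=0.5)
        prev = SGDState([np.array([[-0.2]])], [np.array([0.0])])
        new, _ = sgd_step(m, self._grads(m), cfg, prev, momentum=0.5)
        assert new.weights[0][0, 0] == pytest.approx(m.weights[0][0, 0] - 0.1)

    def test_small_step_decreases_batch_error(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            m = init_random([4, 3, 2], seed=trial)
            for w in m.weights:
                w += rng.normal(scale=0.5, size=w.shape)
            X = rng.random((6, 4))
            T = rng.random((6, 2))
            g = backprop_gradients(m, X, T)
            cfg = TrainConfig(algorithm="bprop", learning_rate=1e-3,
                              weight_cost=0.0, momentum=0.0)
            new, _ = sgd_step(m, g, cfg, SGDState.zeros_like(m), momentum=0.0)
            assert batch_objective(new, X, T) < batch_objective(m, X, T)


class TestIRpropPlus:
    def test_converges_on_quadratic(self):
        w = [np.array([0.0])]
        state = RpropState.initial(w)
        for _ in range(100):
            err = float((w[0][0] - 3) ** 2)
            g = [np.array([2 * (w[0][0] - 3)])]
            w, state = irpropplus_step(w, g, state, err)
        assert abs(w[0][0] - 3) < 1e-3

    def test_first_step_uses_initial_delta(self):
        w = [np.array([1.0])]
        state = RpropState.initial(w)
        new, _ = irpropplus_step(w, [np.array([2.0])], state, 1.0)
        assert new[0][0] == pytest.approx(1.0 - 0.1)  # Δ0 = 0.1

    def test_backtracking_restores_prior_parameter(self):
        w = [np.array([1.0])]
        state = RpropState.initial(w)
        # step 1: positive gradient, moves down by Δ0
        w, state = irpropplus_step(w, [np.array([1.0])], state, 5.0)
        w_after_first = w[0].copy()
        # step 2: same sign, error decreased -> accelerated step
        w, state = irpropplus_step(w, [np.array([1.0])], state, 4.0)
        # step 3: sign flip AND error increase -> exact revert of step 2
        w, state = irpropplus_step(w, [np.array([-1.0])], state, 6.0)
        assert w[0][0] == w_after_first[0]

    def test_zero_gradient_leaves_parameter_and_step_size(self):
        w = [np.array([2.0])]
        state = RpropState.initial(w)
        new, new_state = irpropplus_step(w, [np.array([0.0])], state, 1.0)
        assert new[0][0] == 2.0
        assert new_state.step_sizes[0][0] == state.step_sizes[0][0]


class TestNormalizeWeights:
    def test_three_four_five_column(self):
        m = NetworkModel([2, 2], [np.array([[3.0, 0.0], [4.0, 0.0]])],
                         [np.zeros(2)])
        out = normalize_weights(m)
        np.testing.assert_allclose(out.weights[0][:, 0], [0.6, 0.8])
        np.testing.assert_array_equal(out.weights[0][:, 1], 0.0)  # zero kept

    def test_idempotent_and_unit_norms(self):
        m = init_random([5, 4, 2], seed=2)
        for w in m.weights:
            w += np.random.default_rng(0).normal(size=w.shape)
        once = normalize_weights(m)
        twice = normalize_weights(once)
        for w1, w2 in zip(once.weights, twice.weights):
            np.testing.assert_allclose(w1, w2, atol=1e-15)
            norms = np.linalg.norm(w1, axis=0)
            np.testing.assert_allclose(norms[norms > 0], 1.0, atol=1e-12)


class TestMomentumSchedule:
    @pytest.mark.parametrize("epoch,expected", [(10, 0.5), (50, 0.5), (51, 0.9)])
    def test_default_switch_at_50(self, epoch, expected):
        assert momentum_at_epoch(TrainConfig(), epoch) == expected

    def test_switch_epoch_zero_means_final_from_start(self):
        cfg = TrainConfig(momentum_switch_epoch=0)
        assert momentum_at_epoch(cfg, 1) == cfg.final_momentum


class TestTrain:
    def _separable(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        half = n // 2
        X = np.vstack([rng.normal(0, 1, (half, 2)),
                       rng.normal(6, 1, (n - half, 2))])
        T = np.vstack([np.zeros((half, 1)), np.ones((n - half, 1))])
        X = (X - X.min(0)) / (X.max(0) - X.min(0))
        return X, T

    def test_zero_epochs_is_identity(self):
        m = init_random([2, 1], seed=0)
        X, T = self._separable(20)
        out, hist = train(m, X, T, TrainConfig(epochs=0))
        np.testing.assert_array_equal(out.weights[0], m.weights[0])
        assert hist.epochs == []

    def test_early_stop_caps_epochs(self):
        m = init_random([2, 1], seed=0)
        X, T = self._separable(20)
        cfg = TrainConfig(algorithm="rprop", epochs=200, early_stop_epoch=90)
        _, hist = train(m, X, T, cfg)
        assert hist.epochs == list(range(1, 91))

    def test_rprop_separates_gaussian_clouds(self):
        X, T = self._separable(100, seed=42)
        m = init_random([2, 3, 1], seed=0)
        _, hist = train(m, X, T, TrainConfig(algorithm="rprop", epochs=200))
        assert hist.train_acc[-1] == 1.0

    def test_bprop_separates_gaussian_clouds(self):
        X, T = self._separable(100, seed=42)
        m = init_random([2, 3, 1], seed=0)
        cfg = TrainConfig(algorithm="bprop", epochs=100, learning_rate=0.5)
        _, hist = train(m, X, T, cfg)
        assert hist.train_acc[-1] == 1.0

    def test_seed_determinism(self):
        X, T = self._separable(30)
        cfg = TrainConfig(algorithm="bprop", epochs=5, seed=3)
        a, _ = train(init_random([2, 2, 1], seed=1), X, T, cfg)
        b, _ = train(init_random([2, 2, 1], seed=1), X, T, cfg)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_weight_normalization_keeps_unit_columns(self):
        X, T = self._separable(30)
        cfg = TrainConfig(algorithm="rprop", epochs=10, weight_normalization=True)
        m, _ = train(init_random([2, 3, 1], seed=1), X, T, cfg)
        for w in m.weights:
            norms = np.linalg.norm(w, axis=0)
            np.testing.assert_allclose(norms[norms > 0], 1.0, atol=1e-12)

    def test_history_records_monitor_accuracy(self):
        X, T = self._separable(40)
        cfg = TrainConfig(algorithm="rprop", epochs=5)
        _, hist = train(init_random([2, 2, 1], seed=0), X, T, cfg,
                        monitor=(X, T))
        assert len(hist.monitor_acc) == 5
        assert not np.isnan(hist.monitor_acc[-1])

    def test_unsupported_variant_rejected(self):
        with pytest.raises(ValueError, match="iRprop"):
            TrainConfig(algorithm="irprop-minus")
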