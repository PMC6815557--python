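"""LSTM cell, losses, gradients, optimizer, training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgbeat import (
    BeatDataset,
    LSTMParams,
    LSTMState,
    NadamState,
    TrainConfig,
    backward,
    batch_loss,
    cross_entropy,
    focal_loss,
    forward,
    init_params,
    load_checkpoint,
    lstm_step,
    nadam_update,
    predict,
    save_checkpoint,
    softmax,
    train,
)
from ecgbeat.dataset import Beat
from ecgbeat.model import _forward_batch
from ecgbeat.synthetic import template_signal


def zero_params(H=4, D=1, H1=3, C=3, standard_lstm=False):
    in_w = (H + D) if standard_lstm else (2 * H + D)
    return LSTMParams(
        W_f=np.zeros((H, in_w)), W_i=np.zeros((H, in_w)),
        W_c=np.zeros((H, in_w)), W_o=np.zeros((H, in_w)),
        b_f=np.zeros(H), b_i=np.zeros(H), b_c=np.zeros(H), b_o=np.zeros(H),
        W_fc1=np.zeros((H1, H)), b_fc1=np.zeros(H1),
        W_fc2=np.zeros((C, H1)), b_fc2=np.zeros(C),
        standard_lstm=standard_lstm,
    )


class TestInitParams:
    def test_deterministic(self):
        a, b = init_params(seed=5), init_params(seed=5)
        for k, arr in a.arrays().items():
            np.testing.assert_array_equal(arr, b.arrays()[k])

    def test_peephole_gate_shape(self):
        params = init_params(H=64, D=1, standard_lstm=False)
        assert params.W_f.shape == (64, 129)  # 2H + D
        assert params.D == 1

    def test_standard_gate_shape(self):
        params = init_params(H=64, D=1, standard_lstm=True)
        assert params.W_f.shape == (64, 65)  # H + D

    def test_forget_bias_one_others_zero(self):
        params = init_params(H=8)
        np.testing.assert_array_equal(params.b_f, 1.0)
        for b in (params.b_i, params.b_c, params.b_o, params.b_fc1, params.b_fc2):
            np.testing.assert_array_equal(b, 0.0)

    def test_bad_dims_rejected(self):
        with pytest.raises(ValueError):
            init_params(H=0)


class TestLSTMStep:
    @pytest.mark.parametrize("standard", [False, True])
    def test_all_zero_params_and_state(self, standard):
        params = zero_params(standard_lstm=standard)
        state = lstm_step(params, [0.7], LSTMState.zero(4))
        np.testing.assert_allclose(state.f, 0.5)
        np.testing.assert_allclose(state.i, 0.5)
        np.testing.assert_allclose(state.o, 0.5)
        np.testing.assert_allclose(state.c_in, 0.0)
        np.testing.assert_allclose(state.c, 0.0)
        np.testing.assert_allclose(state.a, 0.0)

    def test_zero_weights_nonzero_prev_cell(self):
        # with W=0, b=0: f=i=o=0.5, c_in=0, so c_t = v/2, a_t = tanh(v/2)/2
        params = zero_params()
        v = np.array([0.4, -1.2, 2.0, 0.1])
        prev = LSTMState(a=np.zeros(4), c=v.copy())
        state = lstm_step(params, [0.0], prev)
        np.testing.assert_allclose(state.c, 0.5 * v)
        np.testing.assert_allclose(state.a, 0.5 * np.tanh(0.5 * v))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_gate_codomain_bounds(self, seed):
        rng = np.random.default_rng(seed)
        params = init_params(H=6, seed=seed, standard_lstm=False)
        prev = LSTMState(a=rng.normal(size=6) * 0.5, c=rng.normal(size=6))
        state = lstm_step(params, rng.normal(size=1) * 3, prev)
        for g in (state.f, state.i, state.o):
            assert np.all((g > 0) & (g < 1))
        assert np.all(np.abs(state.c_in) < 1)
        assert np.all(np.abs(state.a) < 1)


class TestSoftmax:
    def test_uniform_on_zeros(self):
        np.testing.assert_allclose(softmax(np.zeros(8)), 1 / 8)

    def test_shift_invariance(self, rng):
        z = rng.normal(size=8)
        np.testing.assert_allclose(softmax(z + 123.4), softmax(z), atol=1e-12)

    def test_large_logits_stable(self):
        y = softmax(np.array([1000.0, 0.0, -500.0]))
        assert np.isfinite(y).all()
        assert y[0] == pytest.approx(1.0)
        assert y.sum() == pytest.approx(1.0, abs=1e-12)


class TestForward:
    def test_deterministic_without_dropout(self, rng):
        params = init_params(H=6, H1=4, C=8, seed=3)
        beat = rng.normal(size=250)
        z1, y1, _ = forward(params, beat)
        z2, y2, _ = forward(params, beat)
        np.testing.assert_array_equal(z1, z2)
        np.testing.assert_array_equal(y1, y2)

    def test_collapse_to_output_bias_when_hidden_path_zero(self, rng):
        params = zero_params(H=5, H1=4, C=6)
        v = rng.normal(size=6)
        params.b_fc2[:] = v
        _, yhat, _ = forward(params, rng.normal(size=250))
        np.testing.assert_allclose(yhat, softmax(v), atol=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        params = init_params(H=6, seed=1)
        _, yhat, _ = forward(params, rng.normal(size=250))
        assert yhat.sum() == pytest.approx(1.0, abs=1e-12)


class TestLosses:
    def test_cross_entropy_closed_forms(self):
        assert cross_entropy(1.0) == 0.0
        assert cross_entropy(np.exp(-1.0)) == pytest.approx(1.0, abs=1e-12)
        assert cross_entropy(0.5) == pytest.approx(-np.log(0.5), abs=1e-15)

    def test_focal_zero_at_certainty(self):
        for gamma in (0.0, 0.5, 2.0, 5.0):
            assert focal_loss(1.0, gamma) == 0.0

    def test_gamma_zero_is_cross_entropy(self):
        grid = np.linspace(1e-6, 1.0, 10_000)
        np.testing.assert_allclose(
            focal_loss(grid, 0.0), cross_entropy(grid), atol=1e-12
        )

    def test_focal_hand_value_and_downweighting(self):
        expected = -0.25 * np.log(0.5)  # (1-0.5)^2 * CE(0.5)
        assert focal_loss(0.5, 2.0) == pytest.approx(expected, abs=1e-15)
        assert focal_loss(0.5, 2.0) < cross_entropy(0.5)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(1e-6, 1 - 1e-9), st.floats(0.1, 8.0))
    def test_focal_never_exceeds_cross_entropy(self, p, gamma):
        assert focal_loss(p, gamma) <= cross_entropy(p)

    def test_monotone_decreasing_in_gamma_for_fixed_p(self):
        p = 0.8
        vals = [focal_loss(p, g) for g in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(0.5, -1.0)


class TestBatchLoss:
    def test_singleton_batch_equals_example_loss(self):
        cfg = TrainConfig(gamma=2.0, loss="focal")
        yhat = np.array([[0.2, 0.5, 0.3]])
        assert batch_loss(yhat, [1], cfg) == pytest.approx(focal_loss(0.5, 2.0))

    def test_certain_batch_has_zero_loss(self):
        cfg = TrainConfig()
        yhat = np.eye(3)
        assert batch_loss(yhat, [0, 1, 2], cfg) == 0.0

    def test_mean_matches_per_example_sum(self, rng):
        cfg = TrainConfig(gamma=1.5, loss="focal")
        yhat = softmax(rng.normal(size=(7, 4)))
        labels = rng.integers(0, 4, size=7)
        expected = sum(
            focal_loss(yhat[k, labels[k]], 1.5) for k in range(7)
        ) / 7
        assert batch_loss(yhat, labels, cfg) == pytest.approx(expected, abs=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            batch_loss(np.empty((0, 3)), np.empty(0, dtype=int), TrainConfig())


def finite_difference_check(params, X, y, cfg, eps=1e-6):
    _, grads = backward(params, X, y, cfg)

    def loss_at(p):
        _, yhat, _ = _forward_batch(p, X)
        return batch_loss(yhat, y, cfg)

    max_rel = 0.0
    for name, arr in params.arrays().items():
        g = grads.arrays()[name]
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            p_plus, p_minus = params.copy(), params.copy()
            p_plus.arrays()[name][ix] += eps
            p_minus.arrays()[name][ix] -= eps
            fd = (loss_at(p_plus) - loss_at(p_minus)) / (2 * eps)
            denom = max(abs(fd), abs(g[ix]), 1e-8)
            max_rel = max(max_rel, abs(fd - g[ix]) / denom)
    return max_rel


class TestBackward:
    @pytest.mark.parametrize("standard,gamma", [(False, 2.0), (True, 2.0),
                                                (False, 0.0)])
    def test_matches_finite_differences(self, rng, standard, gamma):
        params = init_params(H=3, D=1, H1=3, C=3, seed=11,
                             standard_lstm=standard)
        cfg = TrainConfig(gamma=gamma, loss="focal", standard_lstm=standard)
        X = rng.normal(size=(2, 5))
        y = np.array([0, 2])
        assert finite_difference_check(params, X, y, cfg) < 1e-4

    def test_gamma_zero_equals_cross_entropy_gradients(self, rng):
        params = init_params(H=4, H1=3, C=3, seed=2)
        X = rng.normal(size=(3, 8))
        y = np.array([0, 1, 2])
        _, g_focal = backward(params, X, y, TrainConfig(gamma=0.0, loss="focal"))
        _, g_ce = backward(params, X, y, TrainConfig(loss="cross_entropy"))
        for k, arr in g_focal.arrays().items():
            np.testing.assert_allclose(arr, g_ce.arrays()[k], atol=1e-10)

    def test_zero_gradients_when_prediction_certain(self):
        # saturate the output bias so the true class has probability 1.0
        params = zero_params(H=3, H1=2, C=2)
        params.b_fc2[:] = [800.0, -800.0]
        X = np.zeros((2, 6))
        y = np.array([0, 0])
        loss, grads = backward(params, X, y, TrainConfig(gamma=2.0, loss="focal"))
        assert loss == 0.0
        for arr in grads.arrays().values():
            np.testing.assert_array_equal(arr, 0.0)


class TestNadam:
    def test_zero_gradient_leaves_params_unchanged(self):
        params = init_params(H=3, seed=0)
        state = NadamState.zero(params)
        new, _ = nadam_update(params, params.zeros_like(), state, TrainConfig())
        for k, arr in new.arrays().items():
            np.testing.assert_array_equal(arr, params.arrays()[k])

    def test_first_step_direction_and_magnitude(self):
        params = zero_params(H=3, H1=2, C=2)
        grads = params.zeros_like()
        grads.W_f[:] = 0.25  # constant positive gradient
        grads.b_fc2[:] = [-1.0, 3.0]
        cfg = TrainConfig(learning_rate=0.002)
        new, state = nadam_update(params, grads, NadamState.zero(params), cfg)
        step_wf = new.W_f - params.W_f
        assert np.all(step_wf < 0)  # opposite sign to the gradient
        np.testing.assert_allclose(np.abs(step_wf), cfg.learning_rate,
                                   rtol=1.0)  # magnitude ~ lr
        step_b = new.b_fc2 - params.b_fc2
        assert step_b[0] > 0 and step_b[1] < 0
        assert state.t == 1

    def test_deterministic(self):
        params = init_params(H=3, seed=1)
        grads = init_params(H=3, seed=2)
        s0 = NadamState.zero(params)
        a, sa = nadam_update(params, grads, s0, TrainConfig())
        b, sb = nadam_update(params, grads, s0, TrainConfig())
        for k, arr in a.arrays().items():
            np.testing.assert_array_equal(arr, b.arrays()[k])
        assert sa.t == sb.t == 1


def constant_beat_dataset():
    """Two trivially separable classes: each beat is its class's exact
    (standardized) template."""
    beats = []
    for label, cls in enumerate([0, 1]):
        t = template_signal(cls)
        t = (t - t.mean()) / t.std(ddof=1)
        for _ in range(50):
            beats.append(Beat(t.copy(), label=label))
    return BeatDataset(beats)


class TestTrain:
    def test_separable_by_construction_reaches_full_accuracy(self):
        ds = constant_beat_dataset()
        cfg = TrainConfig(epochs=5, batch_size=16, gamma=2.0, hidden_size=8,
                          fc_width=8, n_classes=2, seed=0)
        params, history = train(ds, None, cfg)
        labels, _ = predict(params, ds)
        assert np.mean(labels == ds.labels()) == 1.0
        assert len(history) == cfg.epochs
        assert all(np.isfinite(h["train_loss"]) for h in history)

    def test_deterministic_given_seed(self):
        ds = constant_beat_dataset()
        cfg = TrainConfig(epochs=2, batch_size=32, hidden_size=4, fc_width=4,
                          n_classes=2, seed=9)
        p1, h1 = train(ds, None, cfg)
        p2, h2 = train(ds, None, cfg)
        for k, arr in p1.arrays().items():
            np.testing.assert_array_equal(arr, p2.arrays()[k])
        np.testing.assert_equal(h1, h2)  # nan-tolerant elementwise equality

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train(BeatDataset([]), None, TrainConfig(epochs=1))


class TestPredict:
    def test_uniform_probabilities_tie_break_to_class_zero(self, rng):
        params = zero_params(H=3, H1=2, C=4)
        labels, probs = predict(params, rng.normal(size=(5, 250)))
        np.testing.assert_allclose(probs, 0.25)
        np.testing.assert_array_equal(labels, 0)

    def test_invariant_to_batch_partitioning(self, rng):
        params = init_params(H=5, H1=4, C=8, seed=4)
        X = rng.normal(size=(23, 250))
        l1, p1 = predict(params, X, batch_size=23)
        l2, p2 = predict(params, X, batch_size=7)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(p1, p2)

    def test_labels_are_argmax_of_probabilities(self, rng):
        params = init_params(H=5, seed=6)
        labels, probs = predict(params, rng.normal(size=(10, 250)))
        np.testing.assert_array_equal(labels, probs.argmax(axis=1))


class TestCheckpoint:
    def test_round_trip_is_bit_exact(self, tmp_path, rng):
        params = init_params(H=6, H1=4, C=8, seed=13)
        cfg = TrainConfig(epochs=3, gamma=1.5, hidden_size=6, fc_width=4)
        path = save_checkpoint(tmp_path / "model.npz", params, cfg)
        loaded, cfg2 = load_checkpoint(path)
        assert cfg2 == cfg
        X = rng.normal(size=(4, 250))
        l1, p1 = predict(params, X)
        l2, p2 = predict(loaded, X)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(l1, l2)
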