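import numpy as np
import pytest

from i2idepth import network as nw
from i2idepth.network import (
    I2IModel,
    NetworkConfig,
    TrainConfig,
    build,
    forward,
    leaky_relu,
    parameter_count,
    predict,
    train,
)

from conftest import make_separable_sequences

TINY = NetworkConfig(input_dim=6, n_classes=3, lstm_units=5,
                     fc_sizes=(8, 7), fc_dropouts=(0.3, 0.2))


def reference_forward(model, x):
    """Independent eval-mode forward pass: plain Python loops over exported
    parameters (gate order input, forget, cell, output along the last axis)."""
    cfg, p = model.config, model.params
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    H = cfg.lstm_units
    a = x
    for k in range(cfg.n_lstm):
        Wx, Wh, b = p[f"lstm{k}_Wx"], p[f"lstm{k}_Wh"], p[f"lstm{k}_b"]
        h = np.zeros(H)
        c = np.zeros(H)
        hs = []
        for t in range(a.shape[0]):
            z = a[t] @ Wx + h @ Wh + b
            i, f, g, o = sig(z[:H]), sig(z[H:2*H]), np.tanh(z[2*H:3*H]), sig(z[3*H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            hs.append(h)
        a = np.array(hs) if k < cfg.n_lstm - 1 else hs[-1]
    for k in range(len(cfg.fc_sizes)):
        z = a @ p[f"fc{k}_W"] + p[f"fc{k}_b"]
        a = np.where(z >= 0, z, cfg.leaky_slope * z)
    logits = a @ p[f"fc{len(cfg.fc_sizes)}_W"] + p[f"fc{len(cfg.fc_sizes)}_b"]
    e = np.exp(logits - logits.max())
    return e / e.sum()


class TestLeakyRelu:
    def test_positive_passthrough_and_negative_slope(self):
        assert leaky_relu(3.0, 0.01) == 3.0
        assert leaky_relu(-2.0, 0.01) == pytest.approx(-0.02)

    def test_elementwise_on_vectors(self):
        np.testing.assert_allclose(
            leaky_relu(np.array([-1.0, 0.0, 2.0]), 0.1), [-0.1, 0.0, 2.0])


class TestBuild:
    def test_layer_shapes_match_architecture(self):
        model = build(NetworkConfig(input_dim=127, n_classes=9), seed=0)
        p = model.params
        assert p["lstm0_Wx"].shape == (127, 400)
        assert p["lstm1_Wx"].shape == (100, 400)
        assert p["fc0_W"].shape == (100, 1024)  # first FC: 1024 wide after LSTM(100)
        assert p["fc4_W"].shape == (64, 9)  # 9-way classifier head

    def test_same_seed_gives_identical_parameters(self):
        a, b = build(TINY, seed=5), build(TINY, seed=5)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_forget_gate_bias_is_one(self):
        b = build(TINY, seed=0).params["lstm0_b"]
        H = TINY.lstm_units
        assert np.all(b[H:2*H] == 1.0) and np.all(b[:H] == 0.0)

    def test_inconsistent_fc_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            NetworkConfig(input_dim=4, n_classes=2, fc_sizes=(8,), fc_dropouts=(0.3, 0.2))

    def test_parameter_count_closed_form(self):
        model = build(TINY, seed=0)
        assert parameter_count(TINY) == sum(v.size for v in model.params.values())


class TestForward:
    def test_probabilities_sum_to_one(self, rng):
        model = build(TINY, seed=1)
        probs = forward(model, rng.standard_normal((10, 4, 6)))
        assert probs.shape == (10, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_eval_mode_is_deterministic(self, rng):
        model = build(TINY, seed=1)
        x = rng.standard_normal((4, 6))
        np.testing.assert_array_equal(forward(model, x), forward(model, x))

    def test_train_mode_dropout_changes_output(self, rng):
        model = build(TINY, seed=1)
        x = rng.standard_normal((4, 6))
        a = forward(model, x, train_mode=True, rng=np.random.default_rng(0))
        b = forward(model, x)
        assert not np.allclose(a, b)

    def test_matches_independent_layer_by_layer_oracle(self, rng):
        model = build(TINY, seed=3)
        for _ in range(3):
            x = rng.standard_normal((5, 6))
            np.testing.assert_allclose(forward(model, x), reference_forward(model, x),
                                       atol=1e-10)

    def test_single_timestep_sequences_supported(self, rng):
        model = build(TINY, seed=1)
        assert forward(model, rng.standard_normal((1, 6))).shape == (3,)

    def test_width_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="width"):
            forward(build(TINY, seed=0), rng.standard_normal((4, 5)))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        cfg = NetworkConfig(input_dim=3, n_classes=3, lstm_units=4,
                            lstm_dropout=0.0, fc_sizes=(6, 5),
                            fc_dropouts=(0.0, 0.0), l2_coeff=1e-3)
        model = build(cfg, seed=0)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5, 4, 3))
        y = np.array([0, 1, 2, 0, 1])
        _, grads, _ = nw._loss_and_grads(model.params, cfg, x, y, None)
        eps = 1e-6
        for name, g in grads.items():
            w = model.params[name]
            for ix in list(np.ndindex(w.shape))[:6]:
                orig = w[ix]
                w[ix] = orig + eps
                lp, _, _ = nw._loss_and_grads(model.params, cfg, x, y, None)
                w[ix] = orig - eps
                lm, _, _ = nw._loss_and_grads(model.params, cfg, x, y, None)
                w[ix] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[ix]) <= 1e-4 * max(1.0, abs(num)), name

    def test_confident_correct_logits_give_near_zero_loss(self):
        cfg = NetworkConfig(input_dim=2, n_classes=3, lstm_units=2,
                            lstm_dropout=0.0, fc_sizes=(4,), fc_dropouts=(0.0,),
                            l2_coeff=0.0)
        model = build(cfg, seed=0)
        for k in range(2):  # zero everything, then force a margin-20 logit
            model.params[f"fc{k}_W"][:] = 0.0
            model.params[f"fc{k}_b"][:] = 0.0
        model.params["fc1_b"][1] = 20.0
        x = np.zeros((3, 2, 2))
        y = np.array([1, 1, 1])
        loss, _, _ = nw._loss_and_grads(model.params, cfg, x, y, None)
        assert loss < 1e-3


class TestTraining:
    def test_separable_two_class_problem_is_learned(self):
        x, y = make_separable_sequences(12, 2, T=4, p=10, seed=0)
        cfg = NetworkConfig(input_dim=10, n_classes=2, lstm_units=12,
                            fc_sizes=(16, 8), fc_dropouts=(0.3, 0.2))
        opt = TrainConfig(lr=3e-3, epochs=30, batch_size=8, seed=0)
        model = train((x, y), cfg, opt)
        assert model.history[-1]["loss"] < model.history[0]["loss"]
        assert model.history[-1]["accuracy"] >= 0.95

    def test_recorded_gradient_norms_respect_the_clip_threshold(self):
        x, y = make_separable_sequences(6, 2, T=3, p=8, seed=1)
        cfg = NetworkConfig(input_dim=8, n_classes=2, lstm_units=6,
                            fc_sizes=(8,), fc_dropouts=(0.3,))
        opt = TrainConfig(lr=1e-3, epochs=3, batch_size=4, grad_clip=0.02, seed=0)
        model = train((x, y), cfg, opt)
        assert all(h["max_grad_norm"] <= 0.02 + 1e-9 for h in model.history)

    def test_training_is_seed_deterministic(self):
        x, y = make_separable_sequences(5, 2, T=3, p=8, seed=2)
        cfg = NetworkConfig(input_dim=8, n_classes=2, lstm_units=4,
                            fc_sizes=(6,), fc_dropouts=(0.3,))
        opt = TrainConfig(lr=1e-3, epochs=2, batch_size=4, seed=9)
        a, b = train((x, y), cfg, opt), train((x, y), cfg, opt)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)
        assert a.history == b.history

    def test_missing_class_is_named(self):
        x = np.zeros((4, 3, 5))
        y = np.array([0, 0, 1, 1])
        cfg = NetworkConfig(input_dim=5, n_classes=3, lstm_units=4,
                            fc_sizes=(4,), fc_dropouts=(0.0,))
        with pytest.raises(ValueError, match=r"\[2\]"):
            train((x, y), cfg, TrainConfig(epochs=1))


class TestPredict:
    def test_argmax_with_low_index_tie_break(self):
        cfg = NetworkConfig(input_dim=2, n_classes=4, lstm_units=2,
                            fc_sizes=(3,), fc_dropouts=(0.0,))
        model = build(cfg, seed=0)
        model.params["fc1_W"][:] = 0.0  # uniform logits: exact 4-way tie
        model.params["fc1_b"][:] = 0.0
        assert np.all(predict(model, np.ones((5, 3, 2))) == 0)

    def test_batch_partition_invariance(self, rng):
        model = build(TINY, seed=2)
        x = rng.standard_normal((9, 4, 6))
        whole = predict(model, x)
        chunked = predict(model, x, batch_size=2)
        single = np.array([predict(model, x[i])[0] for i in range(9)])
        np.testing.assert_array_equal(whole, chunked)
        np.testing.assert_array_equal(whole, single)
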