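"""Layer-level oracle equivalence and numerical gradient checks.

Every forward pass is compared against a brute-force definition on small
random inputs; every backward pass against central finite differences.
"""

import numpy as np
import pytest

from ppgrehab.nn import (
    AdaptiveMaxPool1D,
    AttentionPool,
    Conv1D,
    Dense,
    Dropout,
    LSTM,
    MaxPool1D,
    ReLU,
    softmax,
    softmax_cross_entropy,
)


def brute_conv1d(x, W, b):
    B, Ci, T = x.shape
    Co, _, K = W.shape
    out = np.zeros((B, Co, T - K + 1))
    for bb in range(B):
        for o in range(Co):
            for t in range(T - K + 1):
                acc = 0.0
                for i in range(Ci):
                    for k in range(K):
                        acc += W[o, i, k] * x[bb, i, t + k]
                out[bb, o, t] = acc + b[o]
    return out


def brute_lstm_step(x, h, c, Wx, Wh, b):
    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))
    H = h.shape[-1]
    z = x @ Wx + h @ Wh + b
    i, f, g, o = z[:, :H], z[:, H:2*H], z[:, 2*H:3*H], z[:, 3*H:]
    i, f, o = sig(i), sig(f), sig(o)
    g = np.tanh(g)
    c_new = f * c + i * g
    return np.tanh(c_new) * o, c_new


def numerical_grad(f, x, eps=1e-6):
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


class TestForwardOracles:
    def test_conv_matches_sliding_dot_product(self, rng):
        x = rng.standard_normal((2, 3, 8))
        conv = Conv1D(3, 4, 3, rng)
        np.testing.assert_allclose(
            conv.forward(x),
            brute_conv1d(x, conv.params["W"], conv.params["b"]),
            atol=1e-10,
        )

    def test_identity_kernel_is_identity(self, rng):
        x = rng.standard_normal((1, 1, 10))
        conv = Conv1D(1, 1, 1, rng)
        conv.params["W"][...] = 1.0
        conv.params["b"][...] = 0.0
        np.testing.assert_allclose(conv.forward(x), x)

    def test_maxpool_direct_example(self):
        pool = MaxPool1D(2)
        out = pool.forward(np.array([[[1.0, 3.0, 2.0, 5.0]]]))
        np.testing.assert_array_equal(out, [[[3.0, 5.0]]])

    def test_conv_input_shorter_than_kernel_raises(self, rng):
        with pytest.raises(ValueError):
            Conv1D(1, 1, 5, rng).forward(np.zeros((1, 1, 3)))

    def test_lstm_zero_parameters_give_zero_states(self, rng):
        lstm = LSTM(2, 3, rng)
        for key in lstm.params:
            lstm.params[key][...] = 0.0
        hs = lstm.forward(rng.standard_normal((2, 5, 2)))
        np.testing.assert_allclose(hs, 0.0)

    def test_lstm_single_step_hand_arithmetic(self, rng):
        lstm = LSTM(1, 1, rng)
        lstm.params["Wx"][...] = np.array([[0.5, -0.3, 0.8, 0.2]])
        lstm.params["Wh"][...] = np.array([[0.1, 0.4, -0.2, 0.6]])
        lstm.params["b"][...] = np.array([0.05, -0.1, 0.2, 0.0])
        x = np.array([[[0.7]]])
        h = lstm.forward(x)[0, 0, 0]
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        i = sig(0.5 * 0.7 + 0.05)
        g = np.tanh(0.8 * 0.7 + 0.2)
        o = sig(0.2 * 0.7 + 0.0)
        assert h == pytest.approx(o * np.tanh(i * g), abs=1e-10)

    def test_lstm_matches_step_oracle_on_sequence(self, rng):
        lstm = LSTM(3, 4, rng)
        x = rng.standard_normal((2, 8, 3))
        hs = lstm.forward(x)
        h = np.zeros((2, 4))
        c = np.zeros((2, 4))
        for t in range(8):
            h, c = brute_lstm_step(x[:, t], h, c, lstm.params["Wx"],
                                   lstm.params["Wh"], lstm.params["b"])
            np.testing.assert_allclose(hs[:, t], h, atol=1e-12)

    def test_lstm_gate_activations_in_unit_interval(self, rng):
        lstm = LSTM(2, 3, rng)
        lstm.forward(rng.standard_normal((4, 6, 2)) * 3)
        for (_, _, i, f, g, o, _) in lstm._cache:
            for gate in (i, f, o):
                assert np.all((gate > 0) & (gate < 1))
            assert np.all(np.abs(g) <= 1)

    def test_lstm_rejects_nan_input(self, rng):
        lstm = LSTM(2, 3, rng)
        x = np.zeros((1, 4, 2))
        x[0, 1, 0] = np.nan
        with pytest.raises(FloatingPointError):
            lstm.forward(x)

    def test_attention_singleton_sequence(self, rng):
        att = AttentionPool(3, 2, rng)
        h = rng.standard_normal((2, 1, 3))
        ctx = att.forward(h)
        np.testing.assert_allclose(att.last_alpha, 1.0)
        np.testing.assert_allclose(ctx, h[:, 0, :])

    def test_attention_uniform_over_identical_states(self, rng):
        att = AttentionPool(3, 2, rng)
        h = np.tile(rng.standard_normal((1, 1, 3)), (2, 5, 1))
        att.forward(h)
        np.testing.assert_allclose(att.last_alpha, 0.2, atol=1e-12)

    def test_attention_matches_exp_normalize_oracle(self, rng):
        att = AttentionPool(4, 3, rng)
        h = rng.standard_normal((3, 6, 4))
        att.forward(h)
        e = np.tanh(h @ att.params["W"] + att.params["b"]) @ att.params["v"]
        expected = np.exp(e) / np.exp(e).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(att.last_alpha, expected, atol=1e-10)
        np.testing.assert_allclose(att.last_alpha.sum(axis=1), 1.0, atol=1e-12)

    def test_attention_empty_sequence_raises(self, rng):
        with pytest.raises(ValueError):
            AttentionPool(3, 2, rng).forward(np.zeros((1, 0, 3)))

    def test_softmax_shift_invariance(self, rng):
        z = rng.standard_normal((4, 3))
        np.testing.assert_allclose(softmax(z), softmax(z + 7.3), atol=1e-12)

    def test_cross_entropy_uniform_start(self):
        loss, _ = softmax_cross_entropy(np.zeros((6, 3)), np.array([0, 1, 2] * 2))
        assert loss == pytest.approx(np.log(3))


class TestGradients:
    """Central-difference checks of every backward pass."""

    def check_layer(self, layer, x, rng, tol=1e-6):
        r = rng.standard_normal(layer.forward(x).shape)  # fixed projection

        def loss():
            return float(np.sum(layer.forward(x) * r))

        layer.forward(x)
        layer.zero_grad()
        dx = layer.backward(r)
        np.testing.assert_allclose(dx, numerical_grad(loss, x), atol=tol)
        for key, p in layer.params.items():
            np.testing.assert_allclose(
                layer.grads[key], numerical_grad(loss, p), atol=tol,
                err_msg=f"param {key}",
            )

    def test_conv_gradients(self, rng):
        self.check_layer(Conv1D(2, 3, 3, rng), rng.standard_normal((2, 2, 7)), rng)

    def test_dense_gradients(self, rng):
        self.check_layer(Dense(4, 3, rng), rng.standard_normal((3, 4)), rng)

    def test_lstm_gradients(self, rng):
        self.check_layer(LSTM(2, 3, rng), rng.standard_normal((2, 5, 2)), rng)

    def test_attention_gradients(self, rng):
        self.check_layer(AttentionPool(3, 2, rng), rng.standard_normal((2, 4, 3)), rng)

    def test_maxpool_gradients(self, rng):
        self.check_layer(MaxPool1D(2), rng.standard_normal((2, 2, 8)), rng)

    def test_adaptive_pool_gradients(self, rng):
        # both the equal-segment and ragged-segment paths
        self.check_layer(AdaptiveMaxPool1D(3), rng.standard_normal((2, 2, 9)), rng)
        self.check_layer(AdaptiveMaxPool1D(3), rng.standard_normal((2, 2, 10)), rng)

    def test_relu_gradients(self, rng):
        self.check_layer(ReLU(), rng.standard_normal((3, 4)) + 0.1, rng)

    def test_dropout_identity_in_eval_mode(self, rng):
        drop = Dropout(0.5, rng)
        drop.training = False
        x = rng.standard_normal((3, 4))
        np.testing.assert_array_equal(drop.forward(x), x)
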