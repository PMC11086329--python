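"""Layers with explicit forward/backward passes.

Shapes: convolutional layers operate on (batch, channels, time); the LSTM
and attention operate on (batch, time, features).  Each layer stores its
parameters in ``params`` and accumulates gradients in ``grads`` with
matching keys; ``backward`` consumes the gradient of the loss with respect
to the layer output and returns it with respect to the input.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit as sigmoid


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


class Layer:
    """Base class: parameterized, differentiable transform."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())


class Conv1D(Layer):
    """Valid 1-D convolution (cross-correlation), stride 1.

    y[b, o, t] = sum_{i,k} W[o, i, k] x[b, i, t+k] + b[o]
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True) -> None:
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.params["W"] = scale * rng.standard_normal((c_out, c_in, kernel))
        self.params["b"] = np.zeros(c_out) if bias else None
        if not bias:
            del self.params["b"]
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] < self.kernel:
            raise ValueError(
                f"input length {x.shape[2]} shorter than kernel {self.kernel}"
            )
        self._xw = sliding_window_view(x, self.kernel, axis=2)  # (B,Ci,T',K)
        y = np.einsum("bitk,oik->bot", self._xw, self.params["W"], optimize=True)
        if "b" in self.params:
            y = y + self.params["b"][:, None]
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        self.grads["W"] += np.einsum("bot,bitk->oik", grad, self._xw, optimize=True)
        if "b" in self.params:
            self.grads["b"] += grad.sum(axis=(0, 2))
        k = self.kernel
        gp = np.pad(grad, ((0, 0), (0, 0), (k - 1, k - 1)))
        gw = sliding_window_view(gp, k, axis=2)  # (B,Co,T,K)
        return np.einsum("botk,oik->bit", gw, W[:, :, ::-1], optimize=True)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling of width W along the time axis; trailing
    samples that do not fill a window are dropped (floor arithmetic)."""

    def __init__(self, width: int) -> None:
        super().__init__()
        if width < 1:
            raise ValueError("pool width must be >= 1")
        self.width = width

    def forward(self, x: np.ndarray) -> np.ndarray:
        w = self.width
        t_out = x.shape[2] // w
        xr = x[:, :, : t_out * w].reshape(x.shape[0], x.shape[1], t_out, w)
        self._arg = np.argmax(xr, axis=3)
        self._in_shape = x.shape
        return np.max(xr, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, t_out = grad.shape
        dx = np.zeros(self._in_shape)
        bi, ci, ti = np.indices((b, c, t_out))
        dx[bi, ci, ti * self.width + self._arg] = grad
        return dx


class AdaptiveMaxPool1D(Layer):
    """Max pooling onto a fixed number of output steps (contiguous segments
    of near-equal length), used to align branch time axes."""

    def __init__(self, out_len: int) -> None:
        super().__init__()
        self.out_len = out_len

    def forward(self, x: np.ndarray) -> np.ndarray:
        t_in = x.shape[2]
        if t_in < self.out_len:
            raise ValueError(
                f"cannot adaptively pool length {t_in} onto {self.out_len} steps"
            )
        bounds = np.linspace(0, t_in, self.out_len + 1).astype(int)
        self._bounds = bounds
        self._in_shape = x.shape
        if t_in % self.out_len == 0:
            w = t_in // self.out_len
            xr = x.reshape(x.shape[0], x.shape[1], self.out_len, w)
            self._arg = np.argmax(xr, axis=3)
            return np.max(xr, axis=3)
        self._arg = None
        self._args = []
        out = np.empty((x.shape[0], x.shape[1], self.out_len))
        for j in range(self.out_len):
            seg = x[:, :, bounds[j]:bounds[j + 1]]
            self._args.append(np.argmax(seg, axis=2))
            out[:, :, j] = np.max(seg, axis=2)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._in_shape)
        b, c = self._in_shape[:2]
        bi, ci = np.indices((b, c))
        if self._arg is not None:
            w = self._in_shape[2] // self.out_len
            ti = np.arange(self.out_len)
            dx[bi[:, :, None], ci[:, :, None], ti * w + self._arg] = grad
            return dx
        for j in range(self.out_len):
            dx[bi, ci, self._bounds[j] + self._args[j]] += grad[:, :, j]
        return dx


class LSTM(Layer):
    """Single-layer LSTM over (batch, time, features) -> (batch, time, hidden).

    Standard non-peephole gates:

        i_t = sigma(x_t Wxi + h_{t-1} Whi + bi)      (input gate)
        f_t = sigma(x_t Wxf + h_{t-1} Whf + bf)      (forget gate)
        g_t = tanh (x_t Wxg + h_{t-1} Whg + bg)      (candidate)
        o_t = sigma(x_t Wxo + h_{t-1} Who + bo)      (output gate)
        C_t = f_t * C_{t-1} + i_t * g_t
        h_t = o_t * tanh(C_t)

    The forget-gate bias is initialized to 1 (standard practice so early
    training retains state).
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.d_in, self.hidden = d_in, hidden
        sx = np.sqrt(1.0 / d_in)
        sh = np.sqrt(1.0 / hidden)
        self.params["Wx"] = sx * rng.standard_normal((d_in, 4 * hidden))
        self.params["Wh"] = sh * rng.standard_normal((hidden, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget-gate slice
        self.params["b"] = b
        self.zero_grad()

    def _split(self, z: np.ndarray):
        h = self.hidden
        return z[:, :h], z[:, h:2 * h], z[:, 2 * h:3 * h], z[:, 3 * h:]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] == 0:
            raise ValueError("LSTM requires a nonempty sequence")
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite values entering LSTM")
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        self._x = x
        zx = x @ Wx + b  # input projection for all steps at once
        hs = np.empty((B, T, H))
        for t in range(T):
            z = zx[:, t] + h @ Wh
            i, f, g, o = self._split(z)
            i, f, o = sigmoid(i), sigmoid(f), sigmoid(o)
            g = np.tanh(g)
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, t] = h
        self._hs = hs
        return hs

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, T, H = grad.shape
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWh = np.zeros_like(Wh)
        dzs = np.empty((B, T, 4 * H))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = grad[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1 - tc ** 2)
            dz = dzs[:, t]
            dz[:, :H] = dc * g * i * (1 - i)
            dz[:, H:2 * H] = dc * c_prev * f * (1 - f)
            dz[:, 2 * H:3 * H] = dc * i * (1 - g ** 2)
            dz[:, 3 * H:] = do * o * (1 - o)
            dWh += h_prev.T @ dz
            dh_next = dz @ Wh.T
            dc_next = dc * f
        flat_x = self._x.reshape(B * T, -1)
        flat_dz = dzs.reshape(B * T, 4 * H)
        self.grads["Wx"] += flat_x.T @ flat_dz
        self.grads["Wh"] += dWh
        self.grads["b"] += flat_dz.sum(axis=0)
        return dzs @ Wx.T


class AttentionPool(Layer):
    """Additive attention pooling of a state sequence to one context vector.

    Alignment score per step: e_j = v . tanh(W h_j + b); weights by softmax
    (sum to 1 by construction); context C = sum_j alpha_j h_j.  A single
    learned query v stands in for the decoder state: classification has one
    output step.
    """

    def __init__(self, d_in: int, d_att: int, rng: np.random.Generator) -> None:
        super().__init__()
        s = np.sqrt(1.0 / d_in)
        self.params["W"] = s * rng.standard_normal((d_in, d_att))
        self.params["b"] = np.zeros(d_att)
        self.params["v"] = np.sqrt(1.0 / d_att) * rng.standard_normal(d_att)
        self.zero_grad()
        self.last_alpha: np.ndarray | None = None

    def forward(self, h: np.ndarray) -> np.ndarray:
        if h.shape[1] == 0:
            raise ValueError("attention over an empty sequence")
        self._h = h
        self._u = np.tanh(h @ self.params["W"] + self.params["b"])  # (B,T,A)
        e = self._u @ self.params["v"]                              # (B,T)
        self._alpha = softmax(e, axis=1)
        self.last_alpha = self._alpha
        return np.einsum("bt,bth->bh", self._alpha, h)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        h, u, alpha = self._h, self._u, self._alpha
        W, v = self.params["W"], self.params["v"]
        dh = alpha[:, :, None] * grad[:, None, :]
        dalpha = np.einsum("bh,bth->bt", grad, h)
        # softmax jacobian
        de = alpha * (dalpha - np.sum(alpha * dalpha, axis=1, keepdims=True))
        self.grads["v"] += np.einsum("bt,bta->a", de, u)
        du = de[:, :, None] * v
        dpre = du * (1 - u ** 2)
        self.grads["W"] += np.einsum("bti,bta->ia", h, dpre)
        self.grads["b"] += dpre.sum(axis=(0, 1))
        dh += dpre @ W.T
        return dh


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        s = np.sqrt(2.0 / d_in)
        self.params["W"] = s * rng.standard_normal((d_in, d_out))
        self.params["b"] = np.zeros(d_out)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ grad
        self.grads["b"] += grad.sum(axis=0)
        return grad @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity when not training or p == 0."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits, axis=1)
    n = logits.shape[0]
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + eps)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n
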