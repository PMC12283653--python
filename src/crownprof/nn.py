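"""Compact NumPy sequence-network core: dense, 1-D convolution, LSTM,
time-step attention, Adam — with hand-written backpropagation.

The networks here are small (10 time steps, tens of units), so explicit
NumPy forward/backward passes are fast and fully deterministic.  Gradients
of every layer are verified against central finite differences in the test
suite.  Shapes follow the (batch, time, channels) convention.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: forward caches what backward needs; params/grads expose
    flat lists of arrays for the optimiser."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


class Dense(Layer):
    """Affine map on the last axis (time-distributed when input is 3-D)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = _glorot(rng, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self.w.shape[0])
        g2 = grad.reshape(-1, self.w.shape[1])
        self.dw[...] = x2.T @ g2
        self.db[...] = g2.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Conv1DSame(Layer):
    """1-D convolution along the time axis with 'same' zero padding."""

    def __init__(self, n_in: int, n_out: int, kernel: int,
                 rng: np.random.Generator, relu: bool = False):
        self.kernel = kernel
        self.relu = relu
        scale = np.sqrt(6.0 / (kernel * n_in + kernel * n_out))
        self.w = rng.uniform(-scale, scale, (kernel, n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.pad_l = (kernel - 1) // 2
        self.pad_r = kernel - 1 - self.pad_l

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_l, self.pad_r), (0, 0)))
        self._xp, self._T = xp, T
        y = np.full((B, T, self.w.shape[2]), self.b, dtype=float)
        for d in range(self.kernel):
            y += xp[:, d:d + T, :] @ self.w[d]
        if self.relu:
            self._mask = y > 0
            y = y * self._mask
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.relu:
            grad = grad * self._mask
        T = self._T
        self.db[...] = grad.sum(axis=(0, 1))
        dxp = np.zeros_like(self._xp)
        for d in range(self.kernel):
            seg = self._xp[:, d:d + T, :]
            self.dw[d] = np.einsum("btn,btm->nm", seg, grad)
            dxp[:, d:d + T, :] += grad @ self.w[d].T
        return dxp[:, self.pad_l:self.pad_l + T, :]

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """Single LSTM layer returning the full hidden-state sequence.

    Gate order in the packed weight matrices is (input, forget, cell, output);
    the forget-gate bias starts at 1 (standard initialisation that eases
    gradient flow early in training).
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.wx = _glorot(rng, (n_in, 4 * units))
        self.wh = _glorot(rng, (units, 4 * units))
        self.b = np.zeros(4 * units)
        self.b[units:2 * units] = 1.0
        self.dwx = np.zeros_like(self.wx)
        self.dwh = np.zeros_like(self.wh)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        U = self.units
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        self._x = x
        self._cache = []
        out = np.empty((B, T, U))
        for t in range(T):
            z = x[:, t, :] @ self.wx + h @ self.wh + self.b
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U:2 * U])
            g = np.tanh(z[:, 2 * U:3 * U])
            o = _sigmoid(z[:, 3 * U:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            out[:, t, :] = h
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, _ = x.shape
        U = self.units
        self.dwx[...] = 0.0
        self.dwh[...] = 0.0
        self.db[...] = 0.0
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, U))
        dc_next = np.zeros((B, U))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = self._cache[t]
            dh = grad[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g**2), do * o * (1 - o)], axis=1
            )
            self.dwx += x[:, t, :].T @ dz
            self.dwh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.wx.T
            dh_next = dz @ self.wh.T
        return dx

    def params(self):
        return [self.wx, self.wh, self.b]

    def grads(self):
        return [self.dwx, self.dwh, self.db]


class TimeAttention(Layer):
    """Time-step attention: hidden states are permuted so the time axis is
    innermost, a fully connected layer maps the T step scores of each unit to
    T logits, and a softmax over steps yields an attention distribution which
    reweights the original sequence elementwise (length preserved).

    Each hidden unit carries its own distribution over the T steps (summing
    to 1), so the layer learns which crown layers matter per feature channel.
    The weights of the last forward pass are kept on ``last_alpha`` with
    shape (batch, T, units).
    """

    def __init__(self, n_steps: int, rng: np.random.Generator):
        self.w = _glorot(rng, (n_steps, n_steps))
        self.b = np.zeros(n_steps)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.last_alpha: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = np.swapaxes(x, 1, 2)                       # (B, U, T)
        e = xp @ self.w + self.b
        e = e - e.max(axis=2, keepdims=True)
        a = np.exp(e)
        alpha_p = a / a.sum(axis=2, keepdims=True)      # softmax over steps
        alpha = np.swapaxes(alpha_p, 1, 2)              # (B, T, U)
        self._x, self._xp, self._alpha_p = x, xp, alpha_p
        self.last_alpha = alpha
        return x * alpha

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, xp, alpha_p = self._x, self._xp, self._alpha_p
        alpha = np.swapaxes(alpha_p, 1, 2)
        dx = grad * alpha
        dalpha_p = np.swapaxes(grad * x, 1, 2)          # (B, U, T)
        de = alpha_p * (dalpha_p
                        - (alpha_p * dalpha_p).sum(axis=2, keepdims=True))
        self.dw[...] = np.einsum("but,buk->tk", xp, de)
        self.db[...] = de.sum(axis=(0, 1))
        dx += np.swapaxes(de @ self.w.T, 1, 2)
        return dx

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class ResidualConvBlock(Layer):
    """Two 1-D convolutions (the second with twice the filters) plus a linear
    projection of the input added elementwise, then ReLU."""

    def __init__(self, n_in: int, filters: int, kernel: int,
                 rng: np.random.Generator):
        self.conv1 = Conv1DSame(n_in, filters, kernel, rng, relu=True)
        self.conv2 = Conv1DSame(filters, 2 * filters, kernel, rng, relu=False)
        self.proj = Dense(n_in, 2 * filters, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv2.forward(self.conv1.forward(x))
        r = self.proj.forward(x)
        y = h + r
        self._mask = y > 0
        return y * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad * self._mask
        dx = self.conv1.backward(self.conv2.backward(grad))
        dx += self.proj.backward(grad)
        return dx

    def params(self):
        return self.conv1.params() + self.conv2.params() + self.proj.params()

    def grads(self):
        return self.conv1.grads() + self.conv2.grads() + self.proj.grads()


class Network:
    """A plain stack of layers with MSE loss on (batch, time) outputs."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x[..., 0] if x.ndim == 3 and x.shape[-1] == 1 else x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if grad.ndim == 2:
            grad = grad[..., None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size


class Adam:
    """Adaptive-moment gradient optimiser (standard bias-corrected form)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
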