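"""Minimal NumPy neural-network core used by the tissue classifier and the
per-tissue survival risk networks.

Layers follow the NCHW convention for images. Every layer implements
``forward(x, train)`` and ``backward(grad)``; ``backward`` accumulates
parameter gradients in ``layer.grads`` (aligned with ``layer.params``) and
returns the gradient with respect to the layer input. Initialization is He
normal, drawn from an ``numpy.random.Generator`` supplied by the caller, so
model construction is a pure function of the seed.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    h_out = (h + 2 * pad - k) // stride + 1
    w_out = (w + 2 * pad - k) // stride + 1
    cols = np.empty((n, c, k, k, h_out, w_out), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * h_out : stride,
                                 j : j + stride * w_out : stride]
    return cols.reshape(n, c * k * k, h_out * w_out), (h_out, w_out)


def _col2im(cols, x_shape, k, stride, pad):
    n, c, h, w = x_shape
    h_p, w_p = h + 2 * pad, w + 2 * pad
    h_out = (h_p - k) // stride + 1
    w_out = (w_p - k) // stride + 1
    cols = cols.reshape(n, c, k, k, h_out, w_out)
    x = np.zeros((n, c, h_p, w_p), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            x[:, :, i : i + stride * h_out : stride,
              j : j + stride * w_out : stride] += cols[:, :, i, j]
    if pad:
        x = x[:, :, pad:-pad, pad:-pad]
    return x


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None):
        super().__init__()
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        self._x_shape = x.shape
        self._cols, (h_out, w_out) = _im2col(x, self.k, self.stride, self.pad)
        out = np.einsum("ok,nkl->nol", self.W, self._cols)
        out += self.b[None, :, None]
        return out.reshape(x.shape[0], -1, h_out, w_out)

    def backward(self, grad):
        n, c_out = grad.shape[:2]
        g = grad.reshape(n, c_out, -1)
        self.grads[0][...] = np.einsum("nol,nkl->ok", g, self._cols)
        self.grads[1][...] = g.sum(axis=(0, 2))
        dcols = np.einsum("ok,nol->nkl", self.W, g)
        return _col2im(dcols, self._x_shape, self.k, self.stride, self.pad)


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class SEBlock(Layer):
    """Squeeze-and-excitation channel gate.

    Squeeze: global average per channel. Excitation: two-layer bottleneck
    C → C/r → C with ReLU then sigmoid. The input feature map is rescaled
    per channel by the resulting gate.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if reduction < 1 or reduction > channels:
            raise ValueError(
                f"se reduction must be in [1, channels]; got {reduction} for "
                f"{channels} channels"
            )
        hidden = max(1, channels // reduction)
        self.fc1 = Dense(channels, hidden, rng)
        self.fc2 = Dense(hidden, channels, rng)
        self.relu = ReLU()
        self.params = self.fc1.params + self.fc2.params
        self.grads = self.fc1.grads + self.fc2.grads

    def gate(self, x: np.ndarray) -> np.ndarray:
        """Channel gate values in (0,1) for an NCHW feature map."""
        z = x.mean(axis=(2, 3))
        return sigmoid(self.fc2.forward(self.relu.forward(self.fc1.forward(z))))

    def forward(self, x, train=True):
        self._x = x
        self._s = self.gate(x)
        return x * self._s[:, :, None, None]

    def backward(self, grad):
        x, s = self._x, self._s
        dx = grad * s[:, :, None, None]
        ds = (grad * x).sum(axis=(2, 3))          # N×C
        dz_pre = ds * s * (1.0 - s)               # through sigmoid
        dz = self.fc1.backward(self.relu.backward(self.fc2.backward(dz_pre)))
        h, w = x.shape[2], x.shape[3]
        dx += dz[:, :, None, None] / (h * w)
        return dx


class ResidualSEBlock(Layer):
    """conv3×3 → ReLU → conv3×3 → SE gate → add input → ReLU."""

    def __init__(self, channels: int, rng: np.random.Generator, se_reduction: int = 4):
        super().__init__()
        self.conv1 = Conv2d(channels, channels, 3, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, 3, rng)
        self.se = SEBlock(channels, se_reduction, rng)
        self.relu_out = ReLU()
        self._children = [self.conv1, self.conv2, self.se]
        for ch in self._children:
            self.params += ch.params
            self.grads += ch.grads

    def forward(self, x, train=True):
        y = self.conv1.forward(x, train)
        y = self.relu1.forward(y, train)
        y = self.conv2.forward(y, train)
        y = self.se.forward(y, train)
        return self.relu_out.forward(y + x, train)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        gy = self.se.backward(g)
        gy = self.conv2.backward(gy)
        gy = self.relu1.backward(gy)
        gy = self.conv1.backward(gy)
        return gy + g


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers
        for lay in layers:
            self.params += lay.params
            self.grads += lay.grads

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, grad):
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad


class Adam:
    def __init__(self, params: list, grads: list, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def get_state(model: Layer) -> list[np.ndarray]:
    return [p.copy() for p in model.params]


def set_state(model: Layer, state: list[np.ndarray]) -> None:
    for p, s in zip(model.params, state):
        p[...] = s
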