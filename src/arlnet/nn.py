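"""Minimal CNN layer framework (NumPy, CPU).

Implements exactly the operators the lung-nodule architectures need —
3x3/7x7 convolutions, 2x2 max pooling, dense layers, inverted dropout,
global average pooling, channel and spatial attention gates, and a
parameter-free scaled dot-product token-mixing step — each with an
explicit backward pass so that training (Adam on binary cross-entropy)
and Grad-CAM (gradients of the class logit with respect to intermediate
feature maps) use the same machinery.

Data layout is (N, C, H, W) throughout, float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: forward caches what backward needs; params/grads are
    parallel lists of arrays."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def zero_grads(self) -> None:
        for g in self.grads():
            g[...] = 0.0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patch matrix, stride 1."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,Ho,Wo,k,k
    n, c, ho, wo, _, _ = win.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)


class Conv2D(Layer):
    """Same-padded stride-1 convolution with bias (He-normal init)."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, k, k))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k, self.pad = k, k // 2
        self.in_ch, self.out_ch = in_ch, out_ch
        self._x: np.ndarray | None = None

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        self._x = x
        n, _, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)
        wmat = self.W.reshape(self.out_ch, -1)
        y = cols @ wmat.T + self.b
        return y.transpose(0, 2, 1).reshape(n, self.out_ch, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, _, h, w = x.shape
        dy_flat = dy.reshape(n, self.out_ch, h * w).transpose(0, 2, 1)  # N,HW,O
        cols = _im2col(x, self.k, self.pad)
        self.dW += np.einsum("npo,npq->oq", dy_flat, cols).reshape(self.W.shape)
        self.db += dy.sum(axis=(0, 2, 3))
        # dx = dy convolved with the flipped, channel-transposed kernel
        w_flip = self.W.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        cols_dy = _im2col(dy, self.k, self.pad)
        dx = cols_dy @ w_flip.reshape(self.in_ch, -1).T
        return dx.transpose(0, 2, 1).reshape(n, self.in_ch, h, w)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are cropped.
    Gradient is split evenly among tied maxima."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        xc = x[:, :, :ho * 2, :wo * 2]
        x6 = xc.reshape(n, c, ho, 2, wo, 2)
        y = x6.max(axis=(3, 5))
        self._x_shape = x.shape
        self._x6 = x6
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        ho, wo = h // 2, w // 2
        mask = self._x6 == self._y[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        dx6 = mask * (dy[:, :, :, None, :, None] / counts)
        dx = np.zeros(self._x_shape)
        dx[:, :, :ho * 2, :wo * 2] = dx6.reshape(n, c, ho * 2, wo * 2)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T


class GlobalAvgPool2D(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w) + 0.0


class SelfAttention2D(Layer):
    """Parameter-free scaled dot-product token mixing over spatial
    positions: tokens are the C-dim feature vectors at each pixel."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        t = x.reshape(n, c, h * w).transpose(0, 2, 1)          # N, P, C
        s = t @ t.transpose(0, 2, 1) / np.sqrt(c)              # N, P, P
        s -= s.max(axis=-1, keepdims=True)
        e = np.exp(s)
        a = e / e.sum(axis=-1, keepdims=True)
        y = a @ t
        self._t, self._a, self._shape = t, a, x.shape
        return y.transpose(0, 2, 1).reshape(x.shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        t, a = self._t, self._a
        dyt = dy.reshape(n, c, h * w).transpose(0, 2, 1)       # N, P, C
        dt = a.transpose(0, 2, 1) @ dyt
        da = dyt @ t.transpose(0, 2, 1)
        ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
        dt += (ds + ds.transpose(0, 2, 1)) @ t / np.sqrt(c)
        return dt.transpose(0, 2, 1).reshape(self._shape)


class ChannelAttention(Layer):
    """Squeeze-and-excite gate: GAP per channel -> 2-layer MLP (hidden
    C / reduction, ReLU) -> sigmoid -> per-channel multiplicative gate."""

    def __init__(self, channels: int, reduction: int = 8,
                 rng: np.random.Generator | None = None) -> None:
        if reduction >= channels:
            raise ValueError("reduction must be < channels")
        rng = rng or np.random.default_rng(0)
        hidden = channels // reduction
        self.fc1 = Dense(channels, hidden, rng)
        self.fc2 = Dense(hidden, channels, rng)

    def params(self) -> list[np.ndarray]:
        return self.fc1.params() + self.fc2.params()

    def grads(self) -> list[np.ndarray]:
        return self.fc1.grads() + self.fc2.grads()

    def gates(self, x: np.ndarray) -> np.ndarray:
        """Gate values only, shape (N, C); all strictly in (0, 1)."""
        s = x.mean(axis=(2, 3))
        h = np.maximum(self.fc1.forward(s), 0.0)
        return sigmoid(self.fc2.forward(h))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        s = x.mean(axis=(2, 3))
        h_pre = self.fc1.forward(s)
        h = np.maximum(h_pre, 0.0)
        self._h_mask = h_pre > 0
        g = sigmoid(self.fc2.forward(h))
        self._g = g
        return x * g[:, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, g = self._x, self._g
        dg = (dy * x).sum(axis=(2, 3))
        dx = dy * g[:, :, None, None]
        dz2 = dg * g * (1.0 - g)
        dh = self.fc2.backward(dz2) * self._h_mask
        ds = self.fc1.backward(dh)
        _, _, h_, w_ = x.shape
        dx += ds[:, :, None, None] / (h_ * w_)
        return dx


class SpatialAttention(Layer):
    """Spatial gate: channel-mean and channel-max maps stacked (2, H, W),
    7x7 convolution, sigmoid -> per-pixel multiplicative gate."""

    def __init__(self, kernel: int = 7, rng: np.random.Generator | None = None) -> None:
        self.conv = Conv2D(2, 1, k=kernel, rng=rng or np.random.default_rng(0))

    def params(self) -> list[np.ndarray]:
        return self.conv.params()

    def grads(self) -> list[np.ndarray]:
        return self.conv.grads()

    @staticmethod
    def descriptor(x: np.ndarray) -> np.ndarray:
        """The 2-channel (mean, max over channels) spatial descriptor."""
        return np.stack([x.mean(axis=1), x.max(axis=1)], axis=1)

    def gate_map(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.conv.forward(self.descriptor(x)))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[2] < self.conv.k or x.shape[3] < self.conv.k:
            raise ValueError("spatial size smaller than the attention kernel")
        self._x = x
        d = self.descriptor(x)
        m = sigmoid(self.conv.forward(d))
        self._m = m
        self._max_mask = x == x.max(axis=1, keepdims=True)
        return x * m

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, m = self._x, self._m
        dm = (dy * x).sum(axis=1, keepdims=True)
        dx = dy * m
        dz = dm * m * (1.0 - m)
        dd = self.conv.backward(dz)
        c = x.shape[1]
        dx += dd[:, 0:1] / c
        counts = self._max_mask.sum(axis=1, keepdims=True)
        dx += self._max_mask * (dd[:, 1:2] / counts)
        return dx


# ---------------------------------------------------------------------------
# containers, loss, optimizer
# ---------------------------------------------------------------------------

class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def bce_loss_and_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on logits; returns (mean loss, d loss/d logit)."""
    logits = logits.reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    p = sigmoid(logits)
    eps = 1e-12
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    dlogit = (p - y) / len(y)
    return float(loss), dlogit.reshape(-1, 1)


class Adam:
    """Adam with the usual defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params, self.grad_refs = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
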