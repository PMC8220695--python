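"""Minimal NumPy layers with reverse-mode gradients, plus Adam.

Small, explicit and CPU-friendly: strided convolution via sliding windows,
ReLU, global average pooling, fully connected layers, and the norm-alpha
rescaling layer the L2-softmax constraint requires. Enough to train the
compact reference backbone on desk-scale image sets; every backward pass is
verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: ``params()`` yields (name, value, grad) triples."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """3x3-style convolution over NCHW tensors with stride and zero padding."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3, stride: int = 1,
                 pad: int = 1):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.ksize, self.stride, self.pad = ksize, stride, pad
        self.W = np.zeros((out_ch, in_ch, ksize, ksize))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._win = None

    @property
    def fan_in(self) -> int:
        return self.in_ch * self.ksize * self.ksize

    def he_init(self, rng: np.random.Generator) -> None:
        self.W = rng.normal(0.0, np.sqrt(2.0 / self.fan_in), size=self.W.shape)
        self.b = np.zeros(self.out_ch)

    def params(self):
        return [("W", self, "W", "dW"), ("b", self, "b", "db")]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p, s, k = self.pad, self.stride, self.ksize
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp_shape = x.shape
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        self._win = win  # (N, Cin, Ho, Wo, k, k)
        y = np.einsum("nchwij,ocij->nohw", win, self.W, optimize=True)
        return y + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p, s, k = self.pad, self.stride, self.ksize
        self.dW += np.einsum("nchwij,nohw->ocij", self._win, dy, optimize=True)
        self.db += dy.sum(axis=(0, 2, 3))
        n, _, ho, wo = dy.shape
        dxp = np.zeros(self._xp_shape)
        for i in range(k):
            for j in range(k):
                contrib = np.einsum("nohw,oc->nchw", dy, self.W[:, :, i, j],
                                    optimize=True)
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += contrib
        self._win = None
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class GlobalAvgPool(Layer):
    """NCHW -> NC mean over the spatial grid."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, use_bias: bool = True):
        self.in_dim, self.out_dim = in_dim, out_dim
        self.use_bias = use_bias
        self.W = np.zeros((in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def fan_in(self) -> int:
        return self.in_dim

    def he_init(self, rng: np.random.Generator) -> None:
        self.W = rng.normal(0.0, np.sqrt(2.0 / self.fan_in), size=self.W.shape)
        self.b = np.zeros(self.out_dim)

    def params(self):
        out = [("W", self, "W", "dW")]
        if self.use_bias:
            out.append(("b", self, "b", "db"))
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W
        return y + self.b if self.use_bias else y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ dy
        if self.use_bias:
            self.db += dy.sum(axis=0)
        return dy @ self.W.T


class L2Scale(Layer):
    """Project rows onto the radius-alpha sphere: y = alpha * x / ||x||.

    Backward removes the radial gradient component:
    dx = alpha * (dy / n - x * (x . dy) / n^3).
    """

    def __init__(self, alpha: float):
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._n = np.linalg.norm(x, axis=1, keepdims=True)
        if np.any(self._n < 1e-12):
            raise FloatingPointError("zero-norm embedding row")
        return self.alpha * x / self._n

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, n = self._x, self._n
        dot = np.sum(x * dy, axis=1, keepdims=True)
        return self.alpha * (dy / n - x * dot / n**3)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for _, obj, _, gname in self.params():
            getattr(obj, gname).fill(0.0)


class Adam:
    """Adam over the (value, grad) attribute pairs of a parameter list."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(o, v)) for _, o, v, _ in self.params]
        self.v = [np.zeros_like(getattr(o, v)) for _, o, v, _ in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (_, obj, vname, gname) in enumerate(self.params):
            g = getattr(obj, gname)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            setattr(
                obj,
                vname,
                getattr(obj, vname) - self.lr * mhat / (np.sqrt(vhat) + self.eps),
            )
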