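"""Layers with explicit forward/backward passes.

Conventions:
  * image tensors are NHWC float arrays;
  * every layer keeps its parameters in ``self.params`` and accumulates
    gradients into ``self.grads`` (same keys) during ``backward``;
  * ``forward`` caches whatever the matching ``backward`` needs, so a
    backward call is only valid right after the forward it pairs with.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from cytomil.nn.functional import he_normal


class Layer:
    """Base class; parameter-free layers leave ``params`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Conv2D(Layer):
    """2D convolution, stride 1, 'same' zero padding, square kernel."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.k = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        rng = rng or np.random.default_rng()
        fan_in = kernel_size * kernel_size * in_channels
        self.params = {
            "W": he_normal(rng, (kernel_size, kernel_size, in_channels, out_channels), fan_in),
            "b": np.zeros(out_channels),
        }
        self.zero_grads()
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp = xp
        # windows: (B, H, W, C, k, k)
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        y = np.tensordot(win, self.params["W"], axes=([4, 5, 3], [0, 1, 2]))
        return y + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = self._xp
        win = sliding_window_view(xp, (k, k), axis=(1, 2))
        # dW[k1,k2,cin,cout] = sum_{b,i,j} xp[b,i+k1,j+k2,cin] dy[b,i,j,cout]
        dW = np.tensordot(win, dy, axes=([0, 1, 2], [0, 1, 2]))  # (C,k,k,cout)
        self.grads["W"] += dW.transpose(1, 2, 0, 3)
        self.grads["b"] += dy.sum(axis=(0, 1, 2))
        # dx: correlate dy with spatially flipped kernel, channels swapped
        Wf = self.params["W"][::-1, ::-1].transpose(0, 1, 3, 2)  # (k,k,cout,cin)
        dyp = np.pad(dy, ((0, 0), (p, p), (p, p), (0, 0)))
        dwin = sliding_window_view(dyp, (k, k), axis=(1, 2))
        return np.tensordot(dwin, Wf, axes=([4, 5, 3], [0, 1, 2]))


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; odd extents are padded with -inf."""

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        s = self.pool
        b, h, w, c = x.shape
        ph, pw = (-h) % s, (-w) % s
        self._in_shape = x.shape
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), constant_values=-np.inf)
        h2, w2 = x.shape[1] // s, x.shape[2] // s
        xr = (
            x.reshape(b, h2, s, w2, s, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h2, w2, s * s, c)
        )
        self._idx = xr.argmax(axis=3)
        self._pad_shape = (b, h2, w2, s, s, c)
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s = self.pool
        b, h2, w2, _, _, c = self._pad_shape
        dxr = np.zeros((b, h2, w2, s * s, c), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = (
            dxr.reshape(b, h2, w2, s, s, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h2 * s, w2 * s, c)
        )
        _, h, w, _ = self._in_shape
        return dx[:, :h, :w, :]


class GlobalAvgPool(Layer):
    """Spatial mean over each feature map: (B,H,W,C) -> (B,C)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._hw = x.shape[1] * x.shape[2]
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :], (b, h, w, c)) / self._hw


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params = {
            "W": he_normal(rng, (in_dim, out_dim), in_dim),
            "b": np.zeros(out_dim),
        }
        self.zero_grads()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity when not training. Needs a seeded rng."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()
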