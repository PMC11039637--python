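"""Minimal numpy layer zoo used by the segmentation and classification networks.

All layers operate on ``float32`` NCHW tensors and implement explicit
``forward``/``backward`` passes.  Convolutions are realised through
``sliding_window_view`` + GEMM (im2col), which keeps the whole training loop
BLAS-bound; the backward input gradient is scattered back with a small
``kh x kw`` loop of vectorised slice additions rather than ``np.add.at``.

Stochastic layers (weight init, dropout masks) draw from ``numpy.random
.Generator`` objects that are injected by the owning network, so a run is a
pure function of the seeds handed to it.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from ..exceptions import ValidationError

__all__ = [
    "Layer", "Conv2D", "TransposedConv2D", "MaxPool2D", "Unpool2D",
    "ReLU", "Dropout", "Flatten", "Dense", "BatchNorm2D", "Sigmoid",
]


class Layer:
    """Base layer: parameter-free, stateless forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _same_padding(k: int) -> tuple[int, int]:
    # 'same' padding; even kernels pad one more on the trailing edge
    total = k - 1
    lead = total // 2
    return lead, total - lead


class Conv2D(Layer):
    """Stride-1 'same' 2-D convolution (cross-correlation), He-initialised."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel_size < 1:
            raise ValidationError(f"kernel_size must be >= 1, got {kernel_size}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = int(kernel_size)
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.params = {
            "W": (rng.standard_normal((out_channels, in_channels, kernel_size, kernel_size))
                  * scale).astype(np.float32),
            "b": np.zeros(out_channels, dtype=np.float32),
        }
        self._cache: Optional[tuple] = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        # im2col assembled from k*k contiguous block copies so the whole pass
        # stays memcpy- and GEMM-bound (no strided gathers)
        N, C, H, W = x.shape
        k = self.kernel_size
        pt, pb = _same_padding(k)
        xp = np.pad(x.astype(np.float32, copy=False),
                    ((0, 0), (0, 0), (pt, pb), (pt, pb)))
        cols = np.empty((N, C, k, k, H, W), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i:i + H, j:j + W]
        cols = cols.reshape(N, C * k * k, H * W)
        Wm = self.params["W"].reshape(self.out_channels, -1)
        out = np.matmul(Wm[None], cols)                          # (N, F, H*W)
        out = out.reshape(N, self.out_channels, H, W) + self.params["b"][None, :, None, None]
        if training:
            self._cache = (cols, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        N, C, H, W = x_shape
        k = self.kernel_size
        pt, pb = _same_padding(k)
        dm = dout.reshape(N, self.out_channels, H * W).astype(np.float32, copy=False)
        Wm = self.params["W"].reshape(self.out_channels, -1)
        self.grads["W"] = np.matmul(dm, cols.transpose(0, 2, 1)).sum(axis=0).reshape(
            self.params["W"].shape)
        self.grads["b"] = dm.sum(axis=(0, 2))
        dcols = np.matmul(Wm.T[None], dm).reshape(N, C, k, k, H, W)
        dxp = np.zeros((N, C, H + k - 1, W + k - 1), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + W] += dcols[:, :, i, j]
        self._cache = None
        return dxp[:, :, pt:pt + H, pt:pt + W]


class TransposedConv2D(Conv2D):
    """Stride-1 transposed convolution.

    At stride 1 the transposed operator is the correlation with the spatially
    flipped kernel; spatial up-sampling is handled separately by
    :class:`Unpool2D`, so sharing the im2col machinery with :class:`Conv2D`
    is exact.
    """

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        W = self.params["W"]
        self.params["W"] = W[:, :, ::-1, ::-1].copy()
        try:
            return super().forward(x, training)
        finally:
            self.params["W"] = W

    def backward(self, dout: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        self.params["W"] = W[:, :, ::-1, ::-1].copy()
        try:
            dx = super().backward(dout)
        finally:
            self.params["W"] = W
        self.grads["W"] = self.grads["W"][:, :, ::-1, ::-1].copy()
        return dx


class MaxPool2D(Layer):
    """Non-overlapping max pooling with window = stride = ``size``."""

    def __init__(self, size: int) -> None:
        super().__init__()
        if size < 2:
            raise ValidationError(f"pool size must be >= 2, got {size}")
        self.size = int(size)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        N, C, H, W = x.shape
        p = self.size
        if H % p or W % p:
            raise ValidationError(f"input {H}x{W} not divisible by pool size {p}")
        Ho, Wo = H // p, W // p
        xr = x.reshape(N, C, Ho, p, Wo, p).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Ho, Wo, p * p)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, x_shape = self._cache
        N, C, H, W = x_shape
        p = self.size
        Ho, Wo = H // p, W // p
        dxr = np.zeros((N, C, Ho, Wo, p * p), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], dout[..., None].astype(np.float32), axis=-1)
        dx = dxr.reshape(N, C, Ho, Wo, p, p).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
        self._cache = None
        return dx


class Unpool2D(Layer):
    """Nearest-neighbour up-sampling by an integer factor (no switch indices)."""

    def __init__(self, size: int) -> None:
        super().__init__()
        if size < 2:
            raise ValidationError(f"unpool size must be >= 2, got {size}")
        self.size = int(size)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x.repeat(self.size, axis=2).repeat(self.size, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H, W = dout.shape
        p = self.size
        return dout.reshape(N, C, H // p, p, W // p, p).sum(axis=(3, 5))


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        if training:
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._out * (1.0 - self._out)


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValidationError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = float(rate)
        self.rng: Optional[np.random.Generator] = None
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            return x
        if self.rng is None:
            raise ValidationError("dropout layer has no RNG; call network.set_rng first")
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        out = dout * self._mask
        self._mask = None
        return out


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.params = {
            "W": (rng.standard_normal((in_features, out_features)) * scale).astype(np.float32),
            "b": np.zeros(out_features, dtype=np.float32),
        }

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class BatchNorm2D(Layer):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(channels, dtype=np.float32),
            "beta": np.zeros(channels, dtype=np.float32),
        }
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._cache = (xhat, inv, x.shape)
        g = self.params["gamma"][None, :, None, None]
        return (g * xhat + self.params["beta"][None, :, None, None]).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        N, C, H, W = shape
        m = N * H * W
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        dx = (inv[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        )
        self._cache = None
        return dx.astype(np.float32)
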