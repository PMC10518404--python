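"""Minimal CPU neural-network layers with explicit forward/backward passes.

Implemented directly on numpy so the segmentation ensemble has no deep-learning
framework dependency.  Layout is NHWC float32 throughout.  Convolutions use an
im2col/GEMM formulation (``sliding_window_view`` + matmul), which is the fastest
pure-numpy route for the small networks used here.

Each layer exposes ``forward(x, train)`` / ``backward(dout)`` and a ``params``
dict of learnable arrays with matching ``grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv2D", "ReLU", "Dropout", "MaxPool2x2", "UpConv2x2",
    "softmax", "softmax_cross_entropy",
]


class Layer:
    """Base class: stateless pass-through with no parameters."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """k x k same-padding convolution (stride 1), He-initialised."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3) -> None:
        super().__init__()
        self.k = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in = kernel * kernel * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(fan_in, c_out)).astype(np.float32)
        b = np.zeros(c_out, dtype=np.float32)
        self.params = {"W": w, "b": b}
        self.grads = {"W": np.zeros_like(w), "b": np.zeros_like(b)}
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, p = self.k, self.k // 2
        b_, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (B, H, W, k, k, C) view -> (B*H*W, k*k*C) copy for GEMM
        cols = sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = cols.transpose(0, 1, 2, 4, 5, 3).reshape(b_ * h * w, k * k * c)
        self._xshape = x.shape
        if train:
            self._cols = cols
        out = cols @ self.params["W"] + self.params["b"]
        return out.reshape(b_, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cols is not None, "backward before training forward"
        b_, h, w, c = self._xshape
        k, p = self.k, self.k // 2
        dflat = dout.reshape(-1, self.c_out)
        self.grads["W"][...] = self._cols.T @ dflat
        self.grads["b"][...] = dflat.sum(axis=0)
        dcols = (dflat @ self.params["W"].T).reshape(b_, h, w, k, k, c)
        dxp = np.zeros((b_, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        self._cols = None
        return dxp[:, p:p + h, p:p + w, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.rate == 0.0:
            return dout
        return dout * self._mask


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = xr.reshape(b, h // 2, w // 2, 4, c)
        if train:
            self._arg = xr.argmax(axis=3)
            self._xshape = x.shape
        return xr.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._xshape
        dxr = np.zeros((b, h // 2, w // 2, 4, c), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[:, :, :, None, :], dout[:, :, :, None, :],
                          axis=3)
        dxr = dxr.reshape(b, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return dxr.reshape(b, h, w, c)


class UpConv2x2(Layer):
    """2x2 stride-2 transposed convolution (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        w = rng.normal(0.0, np.sqrt(2.0 / c_in),
                       size=(c_in, 4 * c_out)).astype(np.float32)
        b = np.zeros(c_out, dtype=np.float32)
        self.params = {"W": w, "b": b}
        self.grads = {"W": np.zeros_like(w), "b": np.zeros_like(b)}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b_, h, w, c = x.shape
        if train:
            self._x = x
        out = x.reshape(-1, c) @ self.params["W"]
        out = out.reshape(b_, h, w, 2, 2, self.c_out).transpose(0, 1, 3, 2, 4, 5)
        return out.reshape(b_, 2 * h, 2 * w, self.c_out) + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b_, h2, w2, co = dout.shape
        h, w = h2 // 2, w2 // 2
        d = dout.reshape(b_, h, 2, w, 2, co).transpose(0, 1, 3, 2, 4, 5)
        d = d.reshape(-1, 4 * co)
        xflat = self._x.reshape(-1, self.c_in)
        self.grads["W"][...] = xflat.T @ d
        self.grads["b"][...] = dout.reshape(-1, co).sum(axis=0)
        dx = d @ self.params["W"].T
        return dx.reshape(b_, h, w, self.c_in)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean per-pixel categorical cross-entropy.

    Parameters
    ----------
    logits : (B, H, W, C) raw scores
    labels : (B, H, W) integer class map

    Returns
    -------
    loss : float
    dlogits : gradient of the mean loss w.r.t. logits
    """
    p = softmax(logits)
    n = labels.size
    idx = (np.arange(labels.shape[0])[:, None, None],
           np.arange(labels.shape[1])[None, :, None],
           np.arange(labels.shape[2])[None, None, :],
           labels)
    loss = float(-np.log(np.maximum(p[idx], 1e-12)).mean())
    dlogits = p.copy()
    dlogits[idx] -= 1.0
    return loss, dlogits / n
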