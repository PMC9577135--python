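"""Minimal CPU neural-network primitives (channels-first float32).

Forward and backward passes for the handful of layers the segmentation
network needs: stride-1 same-padding convolution (im2col + BLAS matmul),
per-image batch normalization, ReLU, 2x2 max pooling, nearest-neighbor x2
upsampling, and inverted dropout, plus an Adam optimizer. All arrays are
``(C, H, W)`` float32; convolutions keep spatial size.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv2d",
    "conv2d_backward",
    "batchnorm",
    "batchnorm_backward",
    "relu",
    "relu_backward",
    "maxpool2",
    "maxpool2_backward",
    "upsample2",
    "upsample2_backward",
    "dropout",
    "dropout_backward",
    "softmax",
    "Adam",
]

BN_EPS = 1e-5


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, H, W) -> (C*k*k, H*W) patch matrix for a same-padding k x k conv."""
    c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p))) if p else x
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # (C, H, W, k, k) -> (C, k, k, H, W) -> (C*k*k, H*W)
    return np.ascontiguousarray(win.transpose(0, 3, 4, 1, 2)).reshape(c * k * k, h * w)


def conv2d(x: np.ndarray, W: np.ndarray, b: np.ndarray | None = None):
    """Same-padding stride-1 convolution. W is (F, C, k, k).

    Returns (y, cols); cols is cached for the weight gradient.
    """
    f, c, k, _ = W.shape
    _, h, w = x.shape
    cols = _im2col(x, k)
    y = W.reshape(f, -1) @ cols
    if b is not None:
        y += b[:, None]
    return y.reshape(f, h, w), cols


def conv2d_backward(dy: np.ndarray, cols: np.ndarray, W: np.ndarray):
    """Gradients of conv2d: returns (dx, dW, db)."""
    f, c, k, _ = W.shape
    dyf = dy.reshape(f, -1)
    dW = (dyf @ cols.T).reshape(W.shape)
    db = dyf.sum(axis=1)
    # dx is the correlation of dy with the spatially flipped, transposed kernel
    Wt = np.ascontiguousarray(W.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
    dx, _ = conv2d(dy, Wt)
    return dx, dW, db


def batchnorm(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray):
    """Normalize each channel over its spatial extent (batch of one image)."""
    mu = x.mean(axis=(1, 2), keepdims=True)
    var = x.var(axis=(1, 2), keepdims=True)
    inv_std = 1.0 / np.sqrt(var + BN_EPS)
    xhat = (x - mu) * inv_std
    y = gamma[:, None, None] * xhat + beta[:, None, None]
    return y, (xhat, inv_std)


def batchnorm_backward(dy: np.ndarray, cache, gamma: np.ndarray):
    xhat, inv_std = cache
    m = xhat.shape[1] * xhat.shape[2]
    dgamma = (dy * xhat).sum(axis=(1, 2))
    dbeta = dy.sum(axis=(1, 2))
    dxhat = dy * gamma[:, None, None]
    dx = (
        inv_std
        / m
        * (
            m * dxhat
            - dxhat.sum(axis=(1, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(1, 2), keepdims=True)
        )
    )
    return dx.astype(np.float32), dgamma, dbeta


def relu(x):
    return np.maximum(x, 0.0)


def relu_backward(dy, y):
    return dy * (y > 0)


def maxpool2(x: np.ndarray):
    """2x2 max pooling; spatial dims must be even. Returns (y, argmax_cache)."""
    c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {h}x{w}")
    xr = x.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4).reshape(
        c, h // 2, w // 2, 4
    )
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, (idx, (c, h, w))


def maxpool2_backward(dy: np.ndarray, cache):
    idx, (c, h, w) = cache
    g = np.zeros((c, h // 2, w // 2, 4), dtype=dy.dtype)
    np.put_along_axis(g, idx[..., None], dy[..., None], axis=-1)
    return (
        g.reshape(c, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 3, 2, 4)
        .reshape(c, h, w)
    )


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    c, h, w = dy.shape
    return dy.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


def dropout(x: np.ndarray, p: float, rng: np.random.Generator):
    """Inverted dropout; returns (y, mask). Identity when p == 0."""
    if p <= 0:
        return x, None
    mask = (rng.random(x.shape, dtype=np.float32) >= p) / np.float32(1.0 - p)
    return x * mask, mask


def dropout_backward(dy, mask):
    return dy if mask is None else dy * mask


def softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer over a dict of named parameter arrays (in-place update)."""

    def __init__(self, params: dict, lr: float = 1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * (g * g)
            params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
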