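"""Minimal reverse-mode neural-net primitives on numpy (single sample, CHW).

Convolutions use im2col/col2im with cached gather indices; col2im scatters
with ``np.bincount`` which is exact and fast for float32 payloads.  All
forward functions return (output, cache); backward functions consume the
cache and the upstream gradient.  Ops preserve the input dtype (training
runs in float32; float64 is supported for verification) and are fully
deterministic.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

DTYPE = np.float32

_IDX_CACHE: dict[tuple, np.ndarray] = {}


def _out_size(h: int, k: int, stride: int, pad: int) -> int:
    return (h + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(C, H, W) -> (C*k*k, Ho*Wo) patch matrix."""
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    s0, s1, s2 = xp.strides
    win = as_strided(
        xp,
        shape=(c, k, k, ho, wo),
        strides=(s0, s1, s2, s1 * stride, s2 * stride),
    )
    return np.ascontiguousarray(win).reshape(c * k * k, ho * wo)


def _col_indices(c: int, h: int, w: int, k: int, stride: int, pad: int) -> np.ndarray:
    """Flat indices into the padded (C, H+2p, W+2p) array for each col entry."""
    key = (c, h, w, k, stride, pad)
    idx = _IDX_CACHE.get(key)
    if idx is None:
        hp, wp = h + 2 * pad, w + 2 * pad
        ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
        ci, ki, kj = np.meshgrid(np.arange(c), np.arange(k), np.arange(k), indexing="ij")
        oi, oj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        rows = (ci * hp * wp + ki * wp + kj).reshape(-1, 1)
        cols = (oi * stride * wp + oj * stride).reshape(1, -1)
        idx = (rows + cols).astype(np.int64)
        _IDX_CACHE[key] = idx
    return idx


def col2im(cols: np.ndarray, c: int, h: int, w: int, k: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add inverse of :func:`im2col`; returns (C, H, W)."""
    hp, wp = h + 2 * pad, w + 2 * pad
    idx = _col_indices(c, h, w, k, stride, pad)
    flat = np.bincount(idx.ravel(), weights=cols.ravel(), minlength=c * hp * wp)
    out = flat.reshape(c, hp, wp)
    if pad:
        out = out[:, pad : pad + h, pad : pad + w]
    return np.ascontiguousarray(out).astype(cols.dtype)


# ---------------------------------------------------------------- convolution

def conv2d_forward(x, weight, bias, stride: int = 2, pad: int = 1):
    """weight: (Cout, Cin, k, k); x: (Cin, H, W) -> (Cout, Ho, Wo)."""
    cout, cin, k, _ = weight.shape
    _, h, w = x.shape
    cols = im2col(x, k, stride, pad)
    y = weight.reshape(cout, -1) @ cols + bias[:, None]
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    return y.reshape(cout, ho, wo), (x.shape, cols)


def conv2d_backward(dy, weight, cache, stride: int = 2, pad: int = 1):
    (cin, h, w), cols = cache
    cout, _, k, _ = weight.shape
    dyf = dy.reshape(cout, -1)
    dweight = (dyf @ cols.T).reshape(weight.shape)
    dbias = dyf.sum(axis=1)
    dcols = weight.reshape(cout, -1).T @ dyf
    dx = col2im(dcols, cin, h, w, k, stride, pad)
    return dx, dweight, dbias


# ----------------------------------------------------- transposed convolution

def convT2d_forward(x, weight, bias, stride: int = 2, pad: int = 1):
    """weight: (Cin, Cout, k, k); x: (Cin, H, W) -> (Cout, H*stride, W*stride).

    Output size (H-1)*stride - 2*pad + k, which is 2H for k=4, s=2, p=1.
    """
    cin, cout, k, _ = weight.shape
    _, h, w = x.shape
    ho = (h - 1) * stride - 2 * pad + k
    wo = (w - 1) * stride - 2 * pad + k
    dcols = weight.reshape(cin, -1).T @ x.reshape(cin, -1)
    y = col2im(dcols, cout, ho, wo, k, stride, pad) + bias[:, None, None]
    return y.astype(x.dtype), (x, (ho, wo))


def convT2d_backward(dy, weight, cache, stride: int = 2, pad: int = 1):
    x, _ = cache
    cin, cout, k, _ = weight.shape
    dcols = im2col(dy, k, stride, pad)  # (Cout*k*k, H*W)
    dx = (weight.reshape(cin, -1) @ dcols).reshape(x.shape)
    dweight = (x.reshape(cin, -1) @ dcols.T).reshape(weight.shape)
    dbias = dy.sum(axis=(1, 2))
    return dx, dweight, dbias


# ---------------------------------------------------------------- batch norm

def batchnorm_forward(x, gamma, beta, eps: float = 1e-5):
    """Per-channel normalization over the spatial axes (batch of one)."""
    mu = x.mean(axis=(1, 2), keepdims=True)
    var = x.var(axis=(1, 2), keepdims=True)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * invstd
    y = gamma[:, None, None] * xhat + beta[:, None, None]
    return y.astype(x.dtype), (xhat, invstd, gamma)


def batchnorm_backward(dy, cache):
    xhat, invstd, gamma = cache
    n = xhat.shape[1] * xhat.shape[2]
    dgamma = (dy * xhat).sum(axis=(1, 2))
    dbeta = dy.sum(axis=(1, 2))
    dxhat = dy * gamma[:, None, None]
    dx = (
        invstd
        / n
        * (
            n * dxhat
            - dxhat.sum(axis=(1, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(1, 2), keepdims=True)
        )
    )
    return dx.astype(xhat.dtype), dgamma, dbeta


# --------------------------------------------------------------- activations

def leaky_relu_forward(x, slope: float = 0.2):
    y = np.where(x >= 0, x, slope * x)
    return y, (x >= 0, slope)


def leaky_relu_backward(dy, cache):
    pos, slope = cache
    return np.where(pos, dy, slope * dy)


def relu_forward(x):
    pos = x >= 0
    return np.where(pos, x, 0), pos


def relu_backward(dy, pos):
    return np.where(pos, dy, 0)


def tanh_forward(x):
    y = np.tanh(x)
    return y, y


def tanh_backward(dy, y):
    return dy * (1.0 - y * y)


def sigmoid_forward(x):
    y = 1.0 / (1.0 + np.exp(-x))
    return y, y


def sigmoid_backward(dy, y):
    return dy * y * (1.0 - y)


def dropout_forward(x, p: float, rng: np.random.Generator | None):
    """Inverted dropout; identity when rng is None (noise off)."""
    if rng is None or p <= 0:
        return x, None
    mask = (rng.random(x.shape) >= p).astype(DTYPE) / DTYPE(1.0 - p)
    return (x * mask).astype(DTYPE), mask


def dropout_backward(dy, mask):
    if mask is None:
        return dy
    return (dy * mask).astype(DTYPE)


# ------------------------------------------------------------------ optimizer

class Adam:
    """Adaptive-moment optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        # folded bias correction: lr * m^ / (sqrt(v^) + eps)
        #   = (lr * sqrt(bias2) / bias1) * m / (sqrt(v) + eps * sqrt(bias2))
        alpha = self.lr * np.sqrt(bias2) / bias1
        eps2 = self.eps * np.sqrt(bias2)
        for k, g in grads.items():
            p = self.params[k]
            m = self.m[k]
            v = self.v[k]
            g = g.astype(p.dtype, copy=False)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            denom = np.sqrt(v)
            denom += eps2
            np.divide(m, denom, out=denom)
            denom *= alpha
            p -= denom
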