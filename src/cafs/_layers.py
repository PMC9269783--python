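"""Low-level neural-network primitives on NumPy arrays.

Every primitive is a pure function returning ``(output, cache)``; the matching
``*_backward`` consumes the cache and returns gradients with respect to the
inputs and parameters. Convolutions are stride-1 with "same" zero padding and
are evaluated through :func:`numpy.lib.stride_tricks.sliding_window_view`
plus ``einsum``, which keeps them exact (no FFT round-off) and reasonably fast
for the small feature maps this package trains on.

Array layout is NCHW throughout: ``(batch, channels, height, width)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv2d", "conv2d_backward",
    "dwconv2d", "dwconv2d_backward",
    "batchnorm2d", "batchnorm2d_backward",
    "batchnorm1d", "batchnorm1d_backward",
    "relu", "relu_backward",
    "maxpool2", "maxpool2_backward",
    "convtranspose2", "convtranspose2_backward",
    "linear", "linear_backward",
    "softmax",
]

_EINSUM_KW = dict(optimize=True)


def _pad2d(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


# ---------------------------------------------------------------------------
# convolutions


def conv2d(x, W, b):
    """Stride-1 same-padded 2D convolution (cross-correlation).

    x: (B, C, H, W); W: (O, C, k, k) with odd k; b: (O,).
    """
    k = W.shape[-1]
    p = (k - 1) // 2
    win = sliding_window_view(_pad2d(x, p), (k, k), axis=(2, 3))
    y = np.einsum("bchwij,ocij->bohw", win, W, **_EINSUM_KW)
    y += b[None, :, None, None]
    return y, (win, W)


def conv2d_backward(dy, cache):
    win, W = cache
    k = W.shape[-1]
    p = (k - 1) // 2
    dW = np.einsum("bohw,bchwij->ocij", dy, win, **_EINSUM_KW)
    db = dy.sum(axis=(0, 2, 3))
    # gradient wrt input = same-padded correlation with the flipped kernel
    Wf = W[:, :, ::-1, ::-1]
    win2 = sliding_window_view(_pad2d(dy, p), (k, k), axis=(2, 3))
    dx = np.einsum("bohwij,ocij->bchw", win2, Wf, **_EINSUM_KW)
    return dx, dW, db


def dwconv2d(x, W, b):
    """Depthwise stride-1 same-padded convolution. W: (C, k, k); b: (C,).

    Evaluated as k^2 shifted scaled adds, which beats materializing the
    sliding-window view for the small channel counts used here.
    """
    k = W.shape[-1]
    p = (k - 1) // 2
    H, Wd = x.shape[2], x.shape[3]
    xp = _pad2d(x, p)
    y = np.empty_like(x)
    y[:] = b[None, :, None, None]
    for i in range(k):
        for j in range(k):
            y += W[None, :, i, j, None, None] * xp[:, :, i:i + H, j:j + Wd]
    return y, (xp, W)


def dwconv2d_backward(dy, cache):
    xp, W = cache
    k = W.shape[-1]
    p = (k - 1) // 2
    B, C, H, Wd = dy.shape
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    for i in range(k):
        for j in range(k):
            dW[:, i, j] = np.einsum(
                "bchw,bchw->c", dy, xp[:, :, i:i + H, j:j + Wd], **_EINSUM_KW)
            dxp[:, :, i:i + H, j:j + Wd] += W[None, :, i, j, None, None] * dy
    db = dy.sum(axis=(0, 2, 3))
    dx = dxp[:, :, p:p + H, p:p + Wd] if p else dxp
    return dx, dW, db


# ---------------------------------------------------------------------------
# batch normalization

_BN_EPS = 1e-5


def batchnorm2d(x, gamma, beta, run_mean, run_var, train, momentum=0.1,
                update_stats=True):
    """Per-channel batch normalization over (B, H, W).

    In training mode the batch statistics normalize; running statistics are
    updated in place unless ``update_stats`` is False (used where the forward
    must stay side-effect free, e.g. finite-difference evaluations). Evaluation
    mode uses the stored running statistics, making the op a fixed affine map.
    """
    if train:
        mu = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        if update_stats:
            run_mean *= 1.0 - momentum
            run_mean += momentum * mu
            run_var *= 1.0 - momentum
            run_var += momentum * var
    else:
        mu, var = run_mean, run_var
    inv = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
    y = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return y, (xhat, inv, gamma, train)


def batchnorm2d_backward(dy, cache):
    xhat, inv, gamma, train = cache
    dgamma = np.einsum("bchw,bchw->c", dy, xhat, **_EINSUM_KW)
    dbeta = dy.sum(axis=(0, 2, 3))
    dxhat = dy * gamma[None, :, None, None]
    if not train:
        dx = dxhat * inv[None, :, None, None]
        return dx, dgamma, dbeta
    B, C, H, W = dy.shape
    n = B * H * W
    s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
    s2 = np.einsum("bchw,bchw->c", dxhat, xhat, **_EINSUM_KW)[None, :, None, None]
    dx = (inv[None, :, None, None] / n) * (n * dxhat - s1 - xhat * s2)
    return dx, dgamma, dbeta


def batchnorm1d(x, gamma, beta, run_mean, run_var, train, momentum=0.1,
                update_stats=True):
    """Batch normalization for (B, C) feature vectors."""
    if train:
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        if update_stats:
            run_mean *= 1.0 - momentum
            run_mean += momentum * mu
            run_var *= 1.0 - momentum
            run_var += momentum * var
    else:
        mu, var = run_mean, run_var
    inv = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mu[None, :]) * inv[None, :]
    y = gamma[None, :] * xhat + beta[None, :]
    return y, (xhat, inv, gamma, train)


def batchnorm1d_backward(dy, cache):
    xhat, inv, gamma, train = cache
    dgamma = (dy * xhat).sum(axis=0)
    dbeta = dy.sum(axis=0)
    dxhat = dy * gamma[None, :]
    if not train:
        return dxhat * inv[None, :], dgamma, dbeta
    n = dy.shape[0]
    s1 = dxhat.sum(axis=0, keepdims=True)
    s2 = (dxhat * xhat).sum(axis=0, keepdims=True)
    dx = (inv[None, :] / n) * (n * dxhat - s1 - xhat * s2)
    return dx, dgamma, dbeta


# ---------------------------------------------------------------------------
# pointwise / pooling / resampling


def relu(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(dy, mask):
    return dy * mask


def maxpool2(x):
    """2x2 max pooling, stride 2. H, W must be even."""
    B, C, H, W = x.shape
    xr = (x.reshape(B, C, H // 2, 2, W // 2, 2)
           .transpose(0, 1, 2, 4, 3, 5)
           .reshape(B, C, H // 2, W // 2, 4))
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def maxpool2_backward(dy, cache):
    idx, shape = cache
    B, C, H, W = shape
    dxr = np.zeros((B, C, H // 2, W // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    dx = (dxr.reshape(B, C, H // 2, W // 2, 2, 2)
             .transpose(0, 1, 2, 4, 3, 5)
             .reshape(B, C, H, W))
    return dx


def convtranspose2(x, W, b):
    """Transposed convolution with 2x2 kernel, stride 2 (exact 2x upsampling).

    x: (B, C, H, W); W: (C, O, 2, 2); b: (O,). Output (B, O, 2H, 2W).
    """
    t = np.einsum("bchw,codu->bohdwu", x, W, **_EINSUM_KW)
    B, O, H, _, Wd, _ = t.shape
    y = t.reshape(B, O, 2 * H, 2 * Wd)
    y += b[None, :, None, None]
    return y, (x, W)


def convtranspose2_backward(dy, cache):
    x, W = cache
    B, O, H2, W2 = dy.shape
    dt = dy.reshape(B, O, H2 // 2, 2, W2 // 2, 2)
    dx = np.einsum("bohdwu,codu->bchw", dt, W, **_EINSUM_KW)
    dW = np.einsum("bchw,bohdwu->codu", x, dt, **_EINSUM_KW)
    db = dy.sum(axis=(0, 2, 3))
    return dx, dW, db


def linear(x, W, b):
    """x: (B, In); W: (Out, In); b: (Out,)."""
    return x @ W.T + b[None, :], (x, W)


def linear_backward(dy, cache):
    x, W = cache
    dW = dy.T @ x
    db = dy.sum(axis=0)
    dx = dy @ W
    return dx, dW, db


def softmax(z, axis):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
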