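"""Adjustable multi-branch (selective-kernel) channel attention gate.

The gate sits on a U-Net skip connection. An input feature map is transformed
by K parallel branches (depthwise or full convolution with kernel sizes 1, 3,
5, 7 by default, each followed by batch norm and ReLU), the branches are
summed, globally average-pooled into per-channel statistics, compressed
through a small bottleneck (linear -> BN -> ReLU), and a per-branch linear
head maps the compressed descriptor to per-channel logits. A softmax across
branches yields per-channel convex weights, and the gate output is the
weighted recombination of the branch maps:

    U = sum_k U_k
    S_c = mean_{h,w} U[c, h, w]
    m = ReLU(BN(W_sq S))
    w[k, c] = softmax_k(W_k m)[c]
    Y[c] = sum_k w[k, c] * U_k[c]

Because inputs at different object scales pool to different channel
statistics, the branch weights — and hence the effective receptive field —
adapt to scale. Each stage is exposed as a standalone function so that the
algebra can be verified against brute-force oracles; :class:`AttentionGate`
composes them and owns parameter layout and backpropagation.

Third-party attention modules (channel/spatial attention variants) can be
slotted into the backbone by implementing the same contract as
:class:`AttentionGate`: ``init_params(ps, prefix, rng, dtype)``,
``forward(ps, prefix, x, train, update_stats) -> (y, cache)`` with ``y``
shaped like ``x``, and ``backward(dy, cache, ps, prefix, grads) -> dx``;
assign instances to ``UNet.gates[level]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from . import _layers as L
from .params import ParameterSet

__all__ = [
    "AttentionConfig", "AttentionGate",
    "fuse", "channel_statistics", "apply_attention", "branch_weights_from_logits",
]


@dataclass
class AttentionConfig:
    """Configuration of the attention gate.

    kernel_sizes
        Odd kernel sizes, one per branch (default the four sizes 1/3/5/7).
        A single size degenerates the gate to the identity on its branch.
    reduction_ratio
        Channel compression ratio r of the bottleneck descriptor
        (compressed length = ceil(C / r), at least 1). r=1 keeps full width.
    grouped
        Depthwise branch convolutions when True (default); full convolutions
        otherwise.
    """

    kernel_sizes: List[int] = field(default_factory=lambda: [1, 3, 5, 7])
    reduction_ratio: int = 4
    grouped: bool = True

    def __post_init__(self):
        if len(self.kernel_sizes) < 1:
            raise ValueError("at least one kernel size is required")
        for k in self.kernel_sizes:
            if k % 2 != 1 or k < 1:
                raise ValueError(f"kernel sizes must be odd and positive, got {k}")
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")

    @property
    def n_branches(self) -> int:
        return len(self.kernel_sizes)

    def reduced_dim(self, channels: int) -> int:
        return max(1, math.ceil(channels / self.reduction_ratio))


# ---------------------------------------------------------------------------
# stage functions (stateless algebra, shared by the gate and by unit tests)


def fuse(branches: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise sum of the K branch maps."""
    shapes = {b.shape for b in branches}
    if len(shapes) != 1:
        raise ValueError(f"branch shapes disagree: {sorted(shapes)}")
    out = branches[0].copy()
    for b in branches[1:]:
        out += b
    return out


def channel_statistics(U: np.ndarray) -> np.ndarray:
    """Global average pool: (..., C, H, W) -> (..., C)."""
    return U.mean(axis=(-2, -1))


def branch_weights_from_logits(logits: np.ndarray) -> np.ndarray:
    """Softmax across the branch axis (axis -2 of a (..., K, C) array),
    computed with max subtraction for numerical stability."""
    return L.softmax(logits, axis=-2)


def apply_attention(branches: Sequence[np.ndarray], weights: np.ndarray) -> np.ndarray:
    """Per-channel convex recombination.

    branches: K maps of shape (B, C, H, W) (or (C, H, W));
    weights: (B, K, C) (or (K, C)); broadcast over spatial positions.
    """
    stack = np.stack(branches, axis=-4)          # (..., K, C, H, W)
    if weights.shape[-2] != stack.shape[-4] or weights.shape[-1] != stack.shape[-3]:
        raise ValueError(
            f"weights shape {weights.shape} does not match {len(branches)} "
            f"branches with {stack.shape[-3]} channels")
    return np.einsum("...kc,...kchw->...chw", weights, stack, optimize=True)


# ---------------------------------------------------------------------------
# the gate


class AttentionGate:
    """Selective-kernel gate over a fixed channel count.

    Parameters live in a shared :class:`ParameterSet` under a name prefix so
    that one checkpoint can hold an independent gate per skip level.
    """

    def __init__(self, config: AttentionConfig, channels: int):
        self.config = config
        self.channels = channels
        self.reduced = config.reduced_dim(channels)

    # -- parameters ---------------------------------------------------------
    def init_params(self, ps: ParameterSet, prefix: str,
                    rng: np.random.Generator, dtype=np.float64) -> None:
        C, R = self.channels, self.reduced
        for i, k in enumerate(self.config.kernel_sizes):
            # identity-centred init: each branch starts close to a pass-through
            # of the skip tensor, so an untrained gate does not degrade the
            # decoder while the softmax weights are still uniform
            if self.config.grouped:
                w = rng.normal(0.0, 0.3 * math.sqrt(2.0 / (k * k)),
                               size=(C, k, k))
                w[:, k // 2, k // 2] += 1.0
            else:
                w = rng.normal(0.0, 0.3 * math.sqrt(2.0 / (C * k * k)),
                               size=(C, C, k, k))
                w[np.arange(C), np.arange(C), k // 2, k // 2] += 1.0
            ps[f"{prefix}branch{i}.W"] = w.astype(dtype)
            ps[f"{prefix}branch{i}.b"] = np.zeros(C, dtype)
            ps[f"{prefix}branch{i}.bn.gamma"] = np.ones(C, dtype)
            ps[f"{prefix}branch{i}.bn.beta"] = np.zeros(C, dtype)
            ps.buffers[f"{prefix}branch{i}.bn.mean"] = np.zeros(C, dtype)
            ps.buffers[f"{prefix}branch{i}.bn.var"] = np.ones(C, dtype)
        ps[f"{prefix}squeeze.W"] = rng.normal(
            0.0, math.sqrt(2.0 / C), size=(R, C)).astype(dtype)
        ps[f"{prefix}squeeze.b"] = np.zeros(R, dtype)
        ps[f"{prefix}squeeze.bn.gamma"] = np.ones(R, dtype)
        ps[f"{prefix}squeeze.bn.beta"] = np.zeros(R, dtype)
        ps.buffers[f"{prefix}squeeze.bn.mean"] = np.zeros(R, dtype)
        ps.buffers[f"{prefix}squeeze.bn.var"] = np.ones(R, dtype)
        for i in range(self.config.n_branches):
            ps[f"{prefix}head{i}.W"] = rng.normal(
                0.0, math.sqrt(2.0 / R), size=(C, R)).astype(dtype)
            ps[f"{prefix}head{i}.b"] = np.zeros(C, dtype)

    # -- stages using stored parameters -------------------------------------
    def branch_transform(self, ps: ParameterSet, prefix: str, x: np.ndarray,
                         train: bool, update_stats: bool = True):
        """K parallel (conv -> BN -> ReLU) transforms preserving H x W."""
        branches, caches = [], []
        for i in range(self.config.n_branches):
            W = ps[f"{prefix}branch{i}.W"]
            b = ps[f"{prefix}branch{i}.b"]
            if self.config.grouped:
                z, c_conv = L.dwconv2d(x, W, b)
            else:
                z, c_conv = L.conv2d(x, W, b)
            z, c_bn = L.batchnorm2d(
                z, ps[f"{prefix}branch{i}.bn.gamma"],
                ps[f"{prefix}branch{i}.bn.beta"],
                ps.buffers[f"{prefix}branch{i}.bn.mean"],
                ps.buffers[f"{prefix}branch{i}.bn.var"],
                train, update_stats=update_stats)
            u, c_relu = L.relu(z)
            branches.append(u)
            caches.append((c_conv, c_bn, c_relu))
        return branches, caches

    def compress(self, ps: ParameterSet, prefix: str, S: np.ndarray,
                 train: bool, update_stats: bool = True):
        """m = ReLU(BN(Linear_{C -> C/r}(S)))."""
        z, c_lin = L.linear(S, ps[f"{prefix}squeeze.W"], ps[f"{prefix}squeeze.b"])
        z, c_bn = L.batchnorm1d(
            z, ps[f"{prefix}squeeze.bn.gamma"], ps[f"{prefix}squeeze.bn.beta"],
            ps.buffers[f"{prefix}squeeze.bn.mean"],
            ps.buffers[f"{prefix}squeeze.bn.var"],
            train, update_stats=update_stats)
        m, c_relu = L.relu(z)
        return m, (c_lin, c_bn, c_relu)

    def branch_weights(self, ps: ParameterSet, prefix: str, m: np.ndarray):
        """Per-branch linear heads -> (B, K, C) logits -> softmax over K."""
        logits, caches = [], []
        for i in range(self.config.n_branches):
            z, c = L.linear(m, ps[f"{prefix}head{i}.W"], ps[f"{prefix}head{i}.b"])
            logits.append(z)
            caches.append(c)
        logit_stack = np.stack(logits, axis=1)      # (B, K, C)
        weights = branch_weights_from_logits(logit_stack)
        return weights, (caches, weights)

    # -- full gate ----------------------------------------------------------
    def forward(self, ps: ParameterSet, prefix: str, x: np.ndarray,
                train: bool, update_stats: bool = True):
        branches, c_branch = self.branch_transform(ps, prefix, x, train,
                                                   update_stats)
        U = fuse(branches)
        S = channel_statistics(U)
        m, c_comp = self.compress(ps, prefix, S, train, update_stats)
        weights, c_wt = self.branch_weights(ps, prefix, m)
        y = apply_attention(branches, weights)
        cache = (branches, c_branch, c_comp, c_wt, x.shape)
        return y, cache

    def backward(self, dy: np.ndarray, cache, ps: ParameterSet, prefix: str,
                 grads: dict) -> np.ndarray:
        """Accumulate parameter gradients into ``grads``; return dL/dx."""
        branches, c_branch, c_comp, c_wt, xshape = cache
        head_caches, weights = c_wt
        K = self.config.n_branches
        B, C, H, W = branches[0].shape

        stack = np.stack(branches, axis=1)                     # (B, K, C, H, W)
        # through the recombination: dY -> d(branches) and d(weights)
        dbranch = weights[..., None, None] * dy[:, None]        # (B, K, C, H, W)
        dwt = np.einsum("bchw,bkchw->bkc", dy, stack, optimize=True)
        # softmax (over K) backward
        dlogits = weights * (dwt - (dwt * weights).sum(axis=1, keepdims=True))
        # per-branch heads -> dm
        dm = np.zeros_like(c_comp[2], dtype=dy.dtype, shape=(B, self.reduced))
        for i in range(K):
            dmi, dWh, dbh = L.linear_backward(dlogits[:, i], head_caches[i])
            _acc(grads, f"{prefix}head{i}.W", dWh)
            _acc(grads, f"{prefix}head{i}.b", dbh)
            dm += dmi
        # compression stage
        c_lin, c_bn, c_relu = c_comp
        dz = L.relu_backward(dm, c_relu)
        dz, dg, db_ = L.batchnorm1d_backward(dz, c_bn)
        _acc(grads, f"{prefix}squeeze.bn.gamma", dg)
        _acc(grads, f"{prefix}squeeze.bn.beta", db_)
        dS, dWs, dbs = L.linear_backward(dz, c_lin)
        _acc(grads, f"{prefix}squeeze.W", dWs)
        _acc(grads, f"{prefix}squeeze.b", dbs)
        # pooling spreads dS uniformly; fusion copies dU into every branch
        dU = dS[:, :, None, None] / (H * W)
        dx = np.zeros(xshape, dtype=dy.dtype)
        for i in range(K):
            dui = dbranch[:, i] + dU
            c_conv, c_bn2, c_relu2 = c_branch[i]
            dzi = L.relu_backward(dui, c_relu2)
            dzi, dg2, db2 = L.batchnorm2d_backward(dzi, c_bn2)
            _acc(grads, f"{prefix}branch{i}.bn.gamma", dg2)
            _acc(grads, f"{prefix}branch{i}.bn.beta", db2)
            if self.config.grouped:
                dxi, dW2, dbc = L.dwconv2d_backward(dzi, c_conv)
            else:
                dxi, dW2, dbc = L.conv2d_backward(dzi, c_conv)
            _acc(grads, f"{prefix}branch{i}.W", dW2)
            _acc(grads, f"{prefix}branch{i}.b", dbc)
            dx += dxi
        return dx


def _acc(grads: dict, name: str, g: np.ndarray) -> None:
    if name in grads:
        grads[name] += g
    else:
        grads[name] = g
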