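"""2D U-Net backbone with gated skip connections.

Encoder levels apply two (3x3 conv -> BN -> ReLU) stages and 2x2 max pooling
between levels; the decoder mirrors them with learned 2x upsampling, and each
skip tensor optionally passes through a selective-kernel attention gate (one
independently parameterized gate per level) before concatenation. The head is
a 1x1 convolution to two class logits (background, tumor), so a softmax
cross-entropy applies directly.

The forward pass records caches for an exact analytic backward pass; both are
plain functions of a :class:`~cafs.params.ParameterSet`, which keeps teacher
and student networks fully independent objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from . import _layers as L
from .attention import AttentionConfig, AttentionGate
from .errors import ConfigError, ShapeError
from .params import ParameterSet

__all__ = ["NetworkConfig", "UNet", "init_params", "forward"]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    depth
        Number of resolution levels (>= 1). Depth 1 degenerates to a single
        conv block with no pooling, used by the toy gradient checks.
    base_channels / channel_growth
        Channels at the finest level and the per-level multiplier.
    upsample
        "transposed" (default) or "nearest" (nearest-neighbour + 1x1 conv).
    dtype
        "float32" (default, training speed) or "float64" (gradient checks).
    """

    depth: int = 4
    base_channels: int = 32
    channel_growth: int = 2
    in_channels: int = 1
    out_classes: int = 2
    attention_enabled: bool = False
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    upsample: str = "transposed"
    dtype: str = "float32"

    def __post_init__(self):
        if self.depth < 1:
            raise ConfigError(f"depth must be >= 1, got {self.depth}")
        if self.base_channels < 1:
            raise ConfigError("base_channels must be >= 1")
        if self.upsample not in ("transposed", "nearest"):
            raise ConfigError(f"unknown upsample mode {self.upsample!r}")
        if self.dtype not in ("float32", "float64"):
            raise ConfigError(f"dtype must be float32/float64, got {self.dtype!r}")

    def channels(self, level: int) -> int:
        return self.base_channels * self.channel_growth ** level

    @property
    def np_dtype(self):
        return np.float32 if self.dtype == "float32" else np.float64

    def to_dict(self) -> dict:
        return {
            "depth": self.depth, "base_channels": self.base_channels,
            "channel_growth": self.channel_growth,
            "in_channels": self.in_channels, "out_classes": self.out_classes,
            "attention_enabled": self.attention_enabled,
            "attention": {
                "kernel_sizes": list(self.attention.kernel_sizes),
                "reduction_ratio": self.attention.reduction_ratio,
                "grouped": self.attention.grouped,
            },
            "upsample": self.upsample, "dtype": self.dtype,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        att = d.pop("attention", None)
        cfg = cls(**d) if att is None else cls(attention=AttentionConfig(**att), **d)
        return cfg


def _he(rng, fan_in, shape, dtype):
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class UNet:
    """Functional U-Net: parameters live outside the object."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.gates = {}
        if config.attention_enabled:
            for lvl in range(config.depth - 1):
                self.gates[lvl] = AttentionGate(config.attention,
                                                config.channels(lvl))

    # -- initialization -----------------------------------------------------
    def init_params(self, seed: int, role: str = "unspecified") -> ParameterSet:
        cfg = self.config
        dt = cfg.np_dtype
        rng = np.random.default_rng(seed)
        ps = ParameterSet(role)

        def conv(name, cin, cout, k):
            ps[f"{name}.W"] = _he(rng, cin * k * k, (cout, cin, k, k), dt)
            ps[f"{name}.b"] = np.zeros(cout, dt)

        def bn(name, c):
            ps[f"{name}.gamma"] = np.ones(c, dt)
            ps[f"{name}.beta"] = np.zeros(c, dt)
            ps.buffers[f"{name}.mean"] = np.zeros(c, dt)
            ps.buffers[f"{name}.var"] = np.ones(c, dt)

        def block(name, cin, cout):
            conv(f"{name}.conv1", cin, cout, 3)
            bn(f"{name}.bn1", cout)
            conv(f"{name}.conv2", cout, cout, 3)
            bn(f"{name}.bn2", cout)

        for i in range(cfg.depth):
            cin = cfg.in_channels if i == 0 else cfg.channels(i - 1)
            block(f"enc{i}", cin, cfg.channels(i))
        for i in range(cfg.depth - 2, -1, -1):
            cin, cout = cfg.channels(i + 1), cfg.channels(i)
            if cfg.upsample == "transposed":
                ps[f"dec{i}.up.W"] = _he(rng, cin * 4, (cin, cout, 2, 2), dt)
            else:
                ps[f"dec{i}.up.W"] = _he(rng, cin, (cout, cin, 1, 1), dt)
            ps[f"dec{i}.up.b"] = np.zeros(cout, dt)
            block(f"dec{i}", 2 * cout, cout)
        conv("head", cfg.base_channels, cfg.out_classes, 1)
        for lvl, gate in self.gates.items():
            gate.init_params(ps, f"att{lvl}.", rng, dtype=dt)
        return ps

    # -- forward ------------------------------------------------------------
    def _block_fwd(self, ps, name, x, train, update_stats):
        z, c1 = L.conv2d(x, ps[f"{name}.conv1.W"], ps[f"{name}.conv1.b"])
        z, c2 = L.batchnorm2d(z, ps[f"{name}.bn1.gamma"], ps[f"{name}.bn1.beta"],
                              ps.buffers[f"{name}.bn1.mean"],
                              ps.buffers[f"{name}.bn1.var"], train,
                              update_stats=update_stats)
        z, c3 = L.relu(z)
        z, c4 = L.conv2d(z, ps[f"{name}.conv2.W"], ps[f"{name}.conv2.b"])
        z, c5 = L.batchnorm2d(z, ps[f"{name}.bn2.gamma"], ps[f"{name}.bn2.beta"],
                              ps.buffers[f"{name}.bn2.mean"],
                              ps.buffers[f"{name}.bn2.var"], train,
                              update_stats=update_stats)
        z, c6 = L.relu(z)
        return z, (c1, c2, c3, c4, c5, c6)

    def _block_bwd(self, dy, cache, name, grads):
        c1, c2, c3, c4, c5, c6 = cache
        dz = L.relu_backward(dy, c6)
        dz, dg, db = L.batchnorm2d_backward(dz, c5)
        grads[f"{name}.bn2.gamma"] = dg
        grads[f"{name}.bn2.beta"] = db
        dz, dW, dbc = L.conv2d_backward(dz, c4)
        grads[f"{name}.conv2.W"] = dW
        grads[f"{name}.conv2.b"] = dbc
        dz = L.relu_backward(dz, c3)
        dz, dg, db = L.batchnorm2d_backward(dz, c2)
        grads[f"{name}.bn1.gamma"] = dg
        grads[f"{name}.bn1.beta"] = db
        dz, dW, dbc = L.conv2d_backward(dz, c1)
        grads[f"{name}.conv1.W"] = dW
        grads[f"{name}.conv1.b"] = dbc
        return dz

    def check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ShapeError(f"expected (B, {self.config.in_channels}, H, W) "
                             f"input, got {x.shape}")
        div = 2 ** (self.config.depth - 1)
        if x.shape[2] % div or x.shape[3] % div:
            raise ShapeError(
                f"input {x.shape[2]}x{x.shape[3]} not divisible by {div} "
                f"required at level {self.config.depth - 1}")

    def forward(self, ps: ParameterSet, x: np.ndarray, train: bool = False,
                update_stats: bool | None = None, want_cache: bool = False):
        """Compute class logits (B, 2, H, W); optionally keep backward caches."""
        cfg = self.config
        if update_stats is None:
            update_stats = train
        x = np.ascontiguousarray(x, dtype=cfg.np_dtype)
        self.check_input(x)
        caches = {"shapes": x.shape}
        skips = {}
        z = x
        for i in range(cfg.depth):
            z, c = self._block_fwd(ps, f"enc{i}", z, train, update_stats)
            caches[f"enc{i}"] = c
            if i < cfg.depth - 1:
                skips[i] = z
                z, cp = L.maxpool2(z)
                caches[f"pool{i}"] = cp
        for i in range(cfg.depth - 2, -1, -1):
            Wup, bup = ps[f"dec{i}.up.W"], ps[f"dec{i}.up.b"]
            if cfg.upsample == "transposed":
                z, cu = L.convtranspose2(z, Wup, bup)
            else:
                zr = np.repeat(np.repeat(z, 2, axis=2), 2, axis=3)
                z, cu = L.conv2d(zr, Wup, bup)
            caches[f"up{i}"] = cu
            s = skips[i]
            if cfg.attention_enabled:
                s, cg = self.gates[i].forward(ps, f"att{i}.", s, train,
                                              update_stats)
                caches[f"att{i}"] = cg
            z = np.concatenate([s, z], axis=1)
            z, c = self._block_fwd(ps, f"dec{i}", z, train, update_stats)
            caches[f"dec{i}"] = c
        logits, ch = L.conv2d(z, ps["head.W"], ps["head.b"])
        caches["head"] = ch
        if want_cache:
            return logits, caches
        return logits

    # -- backward -----------------------------------------------------------
    def backward(self, dlogits: np.ndarray, caches, ps: ParameterSet) -> dict:
        """Gradients of the loss wrt every learnable parameter."""
        cfg = self.config
        grads: dict = {}
        dz, dW, db = L.conv2d_backward(dlogits, caches["head"])
        grads["head.W"] = dW
        grads["head.b"] = db
        # decoder path, fine -> coarse (reverse of the forward's coarse -> fine)
        dskip = {}
        for i in range(0, cfg.depth - 1):
            dz = self._block_bwd(dz, caches[f"dec{i}"], f"dec{i}", grads)
            cout = cfg.channels(i)
            ds, dup = dz[:, :cout], dz[:, cout:]
            if cfg.attention_enabled:
                ds = self.gates[i].backward(ds, caches[f"att{i}"], ps,
                                            f"att{i}.", grads)
            dskip[i] = ds
            if cfg.upsample == "transposed":
                dz, dWu, dbu = L.convtranspose2_backward(dup, caches[f"up{i}"])
            else:
                dupr, dWu, dbu = L.conv2d_backward(dup, caches[f"up{i}"])
                B, C, H2, W2 = dupr.shape
                dz = dupr.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
            grads[f"dec{i}.up.W"] = dWu
            grads[f"dec{i}.up.b"] = dbu
        # encoder path, deepest (bottleneck) first; dz currently holds the
        # gradient at the bottleneck output
        d = dz
        for i in range(cfg.depth - 1, -1, -1):
            din = self._block_bwd(d, caches[f"enc{i}"], f"enc{i}", grads)
            if i > 0:
                d = dskip[i - 1] + L.maxpool2_backward(din, caches[f"pool{i - 1}"])
        return grads


def init_params(config: NetworkConfig, seed: int,
                role: str = "unspecified") -> ParameterSet:
    """Deterministic parameter initialization for ``config`` under ``seed``."""
    return UNet(config).init_params(seed, role)


def forward(params: ParameterSet, image: np.ndarray,
            config: NetworkConfig) -> np.ndarray:
    """Evaluation-mode logits for one image (H, W) or a batch (B, 1, H, W)."""
    net = UNet(config)
    x = image
    if x.ndim == 2:
        x = x[None, None]
    return net.forward(params, x, train=False)
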