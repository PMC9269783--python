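"""Named parameter collections and checkpoint I/O.

A :class:`ParameterSet` owns every learnable tensor and normalization buffer
of one network. Teacher and student each hold their own set; the two never
alias storage, so an optimizer step on one cannot touch the other except
through the explicit feedback operation.
"""

from __future__ import annotations

import io
import json
from typing import Dict, Iterator

import numpy as np

CHECKPOINT_FORMAT = "cafs-checkpoint-v1"


class ParameterSet:
    """Ordered mapping of parameter names to arrays, plus non-learnable buffers.

    ``params`` holds tensors updated by SGD (conv kernels, biases, BN affine
    terms); ``buffers`` holds state carried along but not optimized (BN running
    statistics). ``role`` tags the owning network ("teacher" or "student").
    """

    def __init__(self, role: str = "unspecified"):
        self.role = role
        self.params: Dict[str, np.ndarray] = {}
        self.buffers: Dict[str, np.ndarray] = {}

    # -- mapping helpers ----------------------------------------------------
    def __getitem__(self, name: str) -> np.ndarray:
        return self.params[name]

    def __setitem__(self, name: str, value: np.ndarray) -> None:
        self.params[name] = value

    def __contains__(self, name: str) -> bool:
        return name in self.params

    def __iter__(self) -> Iterator[str]:
        return iter(self.params)

    def __len__(self) -> int:
        return len(self.params)

    def n_scalars(self) -> int:
        """Total count of learnable scalar parameters."""
        return int(sum(v.size for v in self.params.values()))

    def copy(self, role: str | None = None) -> "ParameterSet":
        """Deep copy; guarantees no storage aliasing with the original."""
        out = ParameterSet(role or self.role)
        out.params = {k: v.copy() for k, v in self.params.items()}
        out.buffers = {k: v.copy() for k, v in self.buffers.items()}
        return out

    def astype(self, dtype) -> "ParameterSet":
        out = ParameterSet(self.role)
        out.params = {k: v.astype(dtype) for k, v in self.params.items()}
        out.buffers = {k: v.astype(dtype) for k, v in self.buffers.items()}
        return out

    def equal(self, other: "ParameterSet") -> bool:
        """Bitwise equality of every tensor and buffer."""
        if set(self.params) != set(other.params):
            return False
        if set(self.buffers) != set(other.buffers):
            return False
        for k, v in self.params.items():
            if not np.array_equal(v, other.params[k]):
                return False
        for k, v in self.buffers.items():
            if not np.array_equal(v, other.buffers[k]):
                return False
        return True


def save_checkpoint(path, params: ParameterSet, config_dict: dict,
                    rng_state: dict | None = None) -> None:
    """Serialize a ParameterSet plus its network config under a versioned header."""
    meta = {
        "format": CHECKPOINT_FORMAT,
        "role": params.role,
        "config": config_dict,
        "rng_state": rng_state,
        "param_names": list(params.params),
        "buffer_names": list(params.buffers),
    }
    arrays = {f"p::{k}": v for k, v in params.params.items()}
    arrays.update({f"b::{k}": v for k, v in params.buffers.items()})
    buf = io.BytesIO()
    np.savez(buf, __meta__=np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8), **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_checkpoint(path):
    """Return ``(ParameterSet, config_dict, rng_state)`` from a checkpoint file."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(
                f"not a recognized checkpoint (format={meta.get('format')!r})")
        ps = ParameterSet(meta["role"])
        ps.params = {k: data[f"p::{k}"].copy() for k in meta["param_names"]}
        ps.buffers = {k: data[f"b::{k}"].copy() for k in meta["buffer_names"]}
    return ps, meta["config"], meta.get("rng_state")
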