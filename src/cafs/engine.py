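"""Teacher-student cooperative training with feedback.

The loop has three phases:

1. **Pretraining** — the teacher alone minimizes cross-entropy on the small
   labeled pool until the iteration budget or a validation-DSC plateau.
2. **Cooperative phase** — per batch: the teacher predicts pseudo-masks for
   unlabeled images; the student takes an SGD step against those pseudo-masks;
   optionally the teacher receives a *feedback* update; and the teacher takes
   a periodic supervised refresh step on labeled data, so both models keep
   optimizing simultaneously.
3. **Prediction** — the student is the deployed model; evaluation defaults
   to it.

Feedback is a one-step meta-gradient: the student's post-update parameters
are treated as a differentiable function of the teacher's *soft* pseudo-mask
probabilities q, and the teacher descends the gradient of the student's
labeled-data cross-entropy through that dependence. Because the student loss
is linear in q, the required mixed second derivative reduces to a directional
derivative of the student's per-pixel log-probabilities along the labeled
gradient, which two extra forward passes evaluate to machine precision (see
``feedback_gradient``). The gradient is exact for the virtual update
``theta' = theta - lr (grad CE(x_u, q) + wd theta)`` (evaluation-mode batch
norm, no momentum); when the actual student step uses hard masks the soft
chain is the documented differentiable surrogate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data import ImageSample
from .errors import ConfigError, DataError, ProtocolError, ShapeError
from .losses import cross_entropy, log_softmax
from .metrics import confusion, dsc
from .params import ParameterSet
from .unet import NetworkConfig, UNet

__all__ = [
    "TrainConfig", "PseudoMaskBatch", "TrainHistory", "SGD",
    "batchify", "pretrain_teacher", "generate_pseudo_masks", "student_step",
    "feedback_gradient", "feedback_step", "train", "train_supervised",
    "predict", "validation_dsc",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the reference protocol: SGD, learning rate 0.001, weight
    decay 0.0001, 1500 iterations, batch size 8. ``pseudo_mask_mode``
    controls the student's supervision (hard argmax masks by default; the
    feedback chain always differentiates through the soft probabilities).
    ``feedback_mode`` selects the one-step meta-gradient ("meta", default) or
    a simpler fallback where the teacher takes a supervised step scaled by
    the student's labeled loss ("scaled").

    During the cooperative phase the teacher is only *fine-tuned*: its
    refresh and feedback steps use ``learning_rate * finetune_lr_scale``
    without momentum, which keeps the pseudo-mask source stable while the
    student trains aggressively against it. Feedback gradients are clipped
    to a global norm of ``feedback_clip_norm`` (0 disables clipping), and
    feedback only engages after ``feedback_warmup`` cooperative steps, once
    the student's predictions carry signal about the teacher's pseudo-masks.
    """

    optimizer: str = "sgd"
    learning_rate: float = 0.001
    weight_decay: float = 0.0001
    iterations: int = 1500
    batch_size: int = 8
    momentum: float = 0.0
    pretrain_iterations: int = 500
    pretrain_patience: int = 5
    eval_every: int = 50
    labeled_count: Optional[int] = None
    feedback_enabled: bool = True
    attention_enabled: bool = True
    pseudo_mask_mode: str = "hard"
    feedback_mode: str = "meta"
    teacher_refresh_every: int = 1
    finetune_lr_scale: float = 0.1
    feedback_clip_norm: float = 1.0
    feedback_warmup: int = 20
    checkpoint_every: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.optimizer != "sgd":
            raise ConfigError(f"only SGD is supported, got {self.optimizer!r}")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ConfigError("learning_rate and batch_size must be positive")
        if self.iterations < 0 or self.pretrain_iterations < 0:
            raise ConfigError("iteration counts must be >= 0")
        if self.weight_decay < 0 or not 0 <= self.momentum < 1:
            raise ConfigError("invalid weight_decay/momentum")
        if self.pseudo_mask_mode not in ("hard", "soft"):
            raise ConfigError(f"pseudo_mask_mode must be hard/soft, "
                              f"got {self.pseudo_mask_mode!r}")
        if self.feedback_mode not in ("meta", "scaled"):
            raise ConfigError(f"feedback_mode must be meta/scaled, "
                              f"got {self.feedback_mode!r}")
        if self.finetune_lr_scale <= 0:
            raise ConfigError("finetune_lr_scale must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PseudoMaskBatch:
    """Teacher predictions used as supervision for the student."""

    hard: np.ndarray            # (B, H, W) in {0, 1}
    soft: np.ndarray            # (B, 2, H, W) class probabilities
    step: int = 0
    mode: str = "hard"

    @property
    def target(self) -> np.ndarray:
        return self.hard if self.mode == "hard" else self.soft


@dataclass
class TrainHistory:
    """Per-step loss records plus periodic validation snapshots."""

    records: List[dict] = field(default_factory=list)
    seed: int = 0
    config: dict = field(default_factory=dict)

    def append(self, **kv) -> None:
        for v in kv.values():
            if isinstance(v, float) and not np.isfinite(v):
                raise FloatingPointError(f"non-finite loss recorded: {kv}")
        self.records.append(kv)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"seed": self.seed, "config": self.config})
                     + "\n")
            for r in self.records:
                fh.write(json.dumps(r) + "\n")

    def jsonl_bytes(self) -> bytes:
        lines = [json.dumps({"seed": self.seed, "config": self.config})]
        lines += [json.dumps(r) for r in self.records]
        return ("\n".join(lines) + "\n").encode()


class SGD:
    """Plain SGD with optional momentum; weight decay is coupled (L2)."""

    def __init__(self, momentum: float = 0.0):
        self.momentum = momentum
        self._vel: Dict[str, np.ndarray] = {}

    def step(self, ps: ParameterSet, grads: Dict[str, np.ndarray],
             lr: float, weight_decay: float) -> None:
        for name, p in ps.params.items():
            g = grads[name] + weight_decay * p
            if self.momentum > 0:
                v = self._vel.get(name)
                if v is None:
                    v = np.zeros_like(p)
                v *= self.momentum
                v -= lr * g
                self._vel[name] = v
                p += v
            else:
                p -= lr * g


# ---------------------------------------------------------------------------
# batching helpers


def batchify(samples: Sequence[ImageSample], need_masks: bool = True
             ) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Stack samples into (B, 1, H, W) images and (B, H, W) masks."""
    x = np.stack([s.image for s in samples])[:, None, :, :]
    if not need_masks:
        return x, None
    for s in samples:
        if s.mask is None:
            raise DataError(f"sample {s.patient_id}/{s.slice_id} lacks a mask")
    y = np.stack([s.mask for s in samples]).astype(np.int64)
    return x, y


def _draw(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    return rng.choice(n, size=min(k, n), replace=False) if n >= k \
        else rng.choice(n, size=k, replace=True)


def _supervised_step(net: UNet, ps: ParameterSet, x: np.ndarray,
                     y: np.ndarray, cfg: TrainConfig, opt: SGD) -> float:
    logits, caches = net.forward(ps, x, train=True, want_cache=True)
    loss, dl = cross_entropy(logits, y, with_grad=True)
    grads = net.backward(dl, caches, ps)
    opt.step(ps, grads, cfg.learning_rate, cfg.weight_decay)
    return loss


def predict(net: UNet, params: ParameterSet, image) -> np.ndarray:
    """Binary mask from evaluation-mode logits; logit ties go to background."""
    if isinstance(image, ImageSample):
        image = image.image
    logits = net.forward(params, np.asarray(image)[None, None], train=False)
    return (logits[0, 1] > logits[0, 0]).astype(np.int8)


def validation_dsc(net: UNet, params: ParameterSet,
                   samples: Sequence[ImageSample], batch: int = 8) -> float:
    """Mean per-image DSC of ``params`` over ``samples`` (batched forwards)."""
    vals = []
    for i in range(0, len(samples), batch):
        chunk = samples[i:i + batch]
        x, y = batchify(chunk)
        logits = net.forward(params, x, train=False)
        pred = (logits[:, 1] > logits[:, 0]).astype(np.int8)
        vals += [dsc(confusion(pred[j], y[j])) for j in range(len(chunk))]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# phases


def pretrain_teacher(labeled: Sequence[ImageSample], config: TrainConfig,
                     net_config: NetworkConfig,
                     valid: Optional[Sequence[ImageSample]] = None,
                     params: Optional[ParameterSet] = None,
                     ) -> Tuple[ParameterSet, List[dict]]:
    """Supervised teacher pretraining on the labeled pool.

    Stops at ``pretrain_iterations`` or, when a validation set is given, as
    soon as the validation DSC fails to improve for ``pretrain_patience``
    consecutive evaluations.
    """
    if not labeled:
        raise ConfigError("pretraining requires a non-empty labeled set")
    net = UNet(net_config)
    teacher = params if params is not None \
        else net.init_params(config.seed + 1, role="teacher")
    opt = SGD(config.momentum)
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 0xC0FE]))
    history: List[dict] = []
    best, stale = -1.0, 0
    best_params = None
    for step in range(1, config.pretrain_iterations + 1):
        idx = _draw(rng, len(labeled), config.batch_size)
        x, y = batchify([labeled[i] for i in idx])
        loss = _supervised_step(net, teacher, x, y, config, opt)
        rec = {"step": step, "teacher_loss": loss}
        if valid and step % config.eval_every == 0:
            v = validation_dsc(net, teacher, valid)
            rec["val_dsc"] = v
            if v > best + 1e-4:
                best, stale = v, 0
                best_params = teacher.copy()
            else:
                stale += 1
            history.append(rec)
            if stale >= config.pretrain_patience:
                break
        else:
            history.append(rec)
    # return the snapshot with the best validation DSC (standard selection)
    if best_params is not None:
        teacher = best_params
    return teacher, history


def generate_pseudo_masks(net: UNet, teacher: ParameterSet,
                          x_unlabeled: np.ndarray, mode: str = "hard",
                          step: int = 0) -> PseudoMaskBatch:
    """Teacher predictions for an unlabeled batch (evaluation mode).

    Hard masks take the per-pixel argmax with ties resolved to background;
    soft masks are the softmax probabilities. Both are returned so the
    feedback chain can differentiate through the soft version regardless of
    what supervises the student.
    """
    if mode not in ("hard", "soft"):
        raise ConfigError(f"unknown pseudo-mask mode {mode!r}")
    logits = net.forward(teacher, x_unlabeled, train=False)
    soft = np.exp(log_softmax(logits.astype(np.float64), axis=1))
    hard = (logits[:, 1] > logits[:, 0]).astype(np.int8)
    return PseudoMaskBatch(hard=hard, soft=soft, step=step, mode=mode)


def student_step(net: UNet, student: ParameterSet, x_unlabeled: np.ndarray,
                 pseudo: PseudoMaskBatch, config: TrainConfig,
                 opt: Optional[SGD] = None) -> float:
    """One SGD step of the student against the teacher's pseudo-masks."""
    if x_unlabeled.shape[0] != pseudo.hard.shape[0]:
        raise ShapeError(
            f"batch of {x_unlabeled.shape[0]} images vs "
            f"{pseudo.hard.shape[0]} pseudo-masks")
    if opt is None:
        opt = SGD(config.momentum)
    target = pseudo.target
    if pseudo.mode == "hard":
        target = target.astype(np.int64)
    logits, caches = net.forward(student, x_unlabeled, train=True,
                                 want_cache=True)
    loss, dl = cross_entropy(logits, target, with_grad=True)
    grads = net.backward(dl, caches, student)
    opt.step(student, grads, config.learning_rate, config.weight_decay)
    return loss


def feedback_gradient(net: UNet, teacher: ParameterSet,
                      student_pre: ParameterSet, x_unlabeled: np.ndarray,
                      x_labeled: np.ndarray, y_labeled: np.ndarray,
                      config: TrainConfig,
                      ) -> Tuple[Dict[str, np.ndarray], float]:
    """Exact gradient of the one-step-unrolled feedback loss wrt the teacher.

    The unrolled map is ``Phi -> q = softmax(teacher(Phi, x_u))`` followed by
    the virtual student update ``theta' = theta - lr (grad_theta CE(x_u, q)
    + wd theta)`` and the labeled loss ``L_fb = CE(student(theta', x_l),
    y_GT)``. All forwards are evaluation-mode and side-effect free. Returns
    ``(teacher gradients, L_fb)``.
    """
    lr = config.learning_rate
    # teacher soft pseudo-masks, with caches for the final backward
    zT, cT = net.forward(teacher, x_unlabeled, train=False,
                         update_stats=False, want_cache=True)
    q = np.exp(log_softmax(zT.astype(np.float64), axis=1))
    # virtual (soft, evaluation-mode, momentum-free) student step
    z0, c0 = net.forward(student_pre, x_unlabeled, train=False,
                         update_stats=False, want_cache=True)
    _, dl0 = cross_entropy(z0, q, with_grad=True)
    g_s = net.backward(dl0, c0, student_pre)
    theta_p = student_pre.copy()
    for k in theta_p.params:
        theta_p.params[k] = student_pre[k] - lr * (
            g_s[k] + config.weight_decay * student_pre[k])
    # labeled loss and its gradient at theta'
    zl, cl = net.forward(theta_p, x_labeled, train=False,
                         update_stats=False, want_cache=True)
    loss_fb, dll = cross_entropy(zl, y_labeled, with_grad=True)
    g_l = net.backward(dll, cl, theta_p)
    norm = float(np.sqrt(sum(float((g * g).sum()) for g in g_l.values())))
    if norm == 0.0:
        return {k: np.zeros_like(v) for k, v in teacher.params.items()}, loss_fb
    # directional derivative of the student's log-probabilities along g_l,
    # evaluated at the pre-update parameters with a central difference
    eps = 1e-5 if net.config.dtype == "float64" else 3e-3
    h = eps / norm
    plus = student_pre.copy()
    minus = student_pre.copy()
    for k in plus.params:
        plus.params[k] = student_pre[k] + h * g_l[k]
        minus.params[k] = student_pre[k] - h * g_l[k]
    lp_p = log_softmax(net.forward(plus, x_unlabeled, train=False,
                                   update_stats=False).astype(np.float64), 1)
    lp_m = log_softmax(net.forward(minus, x_unlabeled, train=False,
                                   update_stats=False).astype(np.float64), 1)
    B, _, H, W = x_unlabeled.shape if x_unlabeled.ndim == 4 else (
        (x_unlabeled.shape[0], 1) + x_unlabeled.shape[1:])
    n = B * H * W
    # dL_fb/dq = (lr / n) * D_{g_l}[log p];  D along g_l = norm * D along unit
    dq = (lr * norm / (2.0 * eps * n)) * (lp_p - lp_m)
    # softmax backward: dZ = q * (dq - sum_c q dq)
    dzT = q * (dq - (q * dq).sum(axis=1, keepdims=True))
    grads = net.backward(dzT.astype(zT.dtype), cT, teacher)
    return grads, loss_fb


def feedback_step(net: UNet, teacher: ParameterSet, student_pre: ParameterSet,
                  student: ParameterSet, x_unlabeled: np.ndarray,
                  x_labeled: np.ndarray, y_labeled: np.ndarray,
                  config: TrainConfig) -> float:
    """Update the teacher from the student's labeled-data error.

    "meta" mode applies the exact one-step meta-gradient of
    :func:`feedback_gradient`; "scaled" mode applies a supervised teacher
    step whose magnitude is scaled by the student's labeled loss. The update
    is a plain gradient step (no momentum, no weight decay) of size
    ``learning_rate * finetune_lr_scale``. The student is never modified
    here. ``student_pre`` must be the student state captured before this
    cycle's student step; passing None means no student step has happened
    this cycle, which is a protocol violation.
    """
    if student_pre is None:
        raise ProtocolError(
            "feedback_step requires a student_step earlier in the same "
            "cycle (student_pre is missing)")
    if config.feedback_mode == "meta":
        grads, loss_fb = feedback_gradient(
            net, teacher, student_pre, x_unlabeled, x_labeled, y_labeled,
            config)
    else:
        zl = net.forward(student, x_labeled, train=False, update_stats=False)
        loss_fb = cross_entropy(zl, y_labeled)
        zt, ct = net.forward(teacher, x_labeled, train=False,
                             update_stats=False, want_cache=True)
        _, dlt = cross_entropy(zt, y_labeled, with_grad=True)
        grads = net.backward(dlt, ct, teacher)
        grads = {k: loss_fb * g for k, g in grads.items()}
    if config.feedback_clip_norm > 0:
        gn = float(np.sqrt(sum(float((g * g).sum())
                               for g in grads.values())))
        if gn > config.feedback_clip_norm:
            scale = config.feedback_clip_norm / gn
            grads = {k: g * scale for k, g in grads.items()}
    lr_t = config.learning_rate * config.finetune_lr_scale
    for k, p in teacher.params.items():
        p -= lr_t * grads[k]
    return loss_fb


# ---------------------------------------------------------------------------
# full loops


def _check_patient_disjoint(train_side: Sequence[ImageSample],
                            valid: Sequence[ImageSample]) -> None:
    p_train = {s.patient_id for s in train_side}
    p_valid = {s.patient_id for s in valid}
    leaked = p_train & p_valid
    if leaked:
        raise DataError(f"patient leakage between training and validation: "
                        f"{sorted(leaked)[:5]}")


def train(labeled: Sequence[ImageSample], unlabeled: Sequence[ImageSample],
          valid: Sequence[ImageSample], config: TrainConfig,
          net_config: Optional[NetworkConfig] = None,
          teacher_init: Optional[ParameterSet] = None,
          checkpoint_dir=None,
          ) -> Tuple[ParameterSet, ParameterSet, TrainHistory]:
    """Full cooperative training; returns (teacher, student, history).

    The final prediction model is the student; when a validation set is
    given, the returned student is the snapshot with the best validation
    DSC. ``config.attention_enabled`` overrides the network config so
    ablations toggle a single flag. ``teacher_init`` may supply an already
    pretrained teacher (it is copied, never mutated), in which case the
    pretraining phase is skipped. With ``checkpoint_dir`` set and
    ``config.checkpoint_every > 0``, both models are checkpointed at that
    cadence.
    """
    net_config = net_config or NetworkConfig()
    net_config = replace(net_config,
                         attention_enabled=config.attention_enabled)
    if valid:
        _check_patient_disjoint(list(labeled) + list(unlabeled), valid)
    net = UNet(net_config)
    history = TrainHistory(seed=config.seed, config=config.to_dict())

    if teacher_init is not None:
        teacher = teacher_init.copy(role="teacher")
    elif config.pretrain_iterations > 0:
        teacher, pre_hist = pretrain_teacher(labeled, config, net_config,
                                             valid=valid)
        for r in pre_hist:
            history.append(phase="pretrain", **r)
    else:
        teacher = UNet(net_config).init_params(config.seed + 1, role="teacher")
    student = net.init_params(config.seed + 2, role="student")
    best_student, best_val = None, -1.0

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    opt_s = SGD(config.momentum)
    # momentum-free, down-scaled refresh keeps the pseudo-mask source stable
    opt_t = SGD(0.0)
    refresh_cfg = replace(config,
                          learning_rate=config.learning_rate
                          * config.finetune_lr_scale,
                          momentum=0.0)
    for step in range(1, config.iterations + 1):
        u_idx = _draw(rng, len(unlabeled), config.batch_size)
        x_u, _ = batchify([unlabeled[i] for i in u_idx], need_masks=False)
        pseudo = generate_pseudo_masks(net, teacher, x_u,
                                       mode=config.pseudo_mask_mode,
                                       step=step)
        fb_now = config.feedback_enabled and step > config.feedback_warmup
        student_pre = student.copy() if fb_now else None
        s_loss = student_step(net, student, x_u, pseudo, config, opt_s)
        rec = {"phase": "cotrain", "step": step, "student_loss": s_loss}
        if fb_now:
            l_idx = _draw(rng, len(labeled), config.batch_size)
            x_l, y_l = batchify([labeled[i] for i in l_idx])
            rec["feedback_loss"] = feedback_step(
                net, teacher, student_pre, student, x_u, x_l, y_l, config)
        if config.teacher_refresh_every > 0 \
                and step % config.teacher_refresh_every == 0:
            l_idx = _draw(rng, len(labeled), config.batch_size)
            x_l, y_l = batchify([labeled[i] for i in l_idx])
            rec["teacher_loss"] = _supervised_step(net, teacher, x_l, y_l,
                                                   refresh_cfg, opt_t)
        if valid and step % config.eval_every == 0:
            v = validation_dsc(net, student, valid)
            rec["val_dsc"] = v
            if v > best_val:
                best_val, best_student = v, student.copy()
        if checkpoint_dir is not None and config.checkpoint_every > 0 \
                and step % config.checkpoint_every == 0:
            from pathlib import Path

            from .params import save_checkpoint

            ckdir = Path(checkpoint_dir)
            ckdir.mkdir(parents=True, exist_ok=True)
            cfg_dict = net_config.to_dict()
            save_checkpoint(ckdir / f"teacher_{step:06d}.npz", teacher,
                            cfg_dict, rng_state={"step": step,
                                                 "seed": config.seed})
            save_checkpoint(ckdir / f"student_{step:06d}.npz", student,
                            cfg_dict, rng_state={"step": step,
                                                 "seed": config.seed})
        history.append(**rec)
    if best_student is not None:
        student = best_student
    return teacher, student, history


def train_supervised(labeled: Sequence[ImageSample],
                     valid: Sequence[ImageSample], config: TrainConfig,
                     net_config: Optional[NetworkConfig] = None,
                     ) -> Tuple[ParameterSet, TrainHistory]:
    """Supervised-only baseline: one U-Net on the labeled fraction alone.

    Runs for the same total step budget as the cooperative loop
    (pretraining + main iterations) so comparisons are step-matched.
    """
    net_config = net_config or NetworkConfig()
    net_config = replace(net_config,
                         attention_enabled=config.attention_enabled)
    if valid:
        _check_patient_disjoint(labeled, valid)
    cfg = replace(config,
                  pretrain_iterations=config.pretrain_iterations
                  + config.iterations,
                  pretrain_patience=10 ** 9)
    params, hist = pretrain_teacher(labeled, cfg, net_config, valid=valid)
    params.role = "supervised"
    history = TrainHistory(seed=config.seed, config=cfg.to_dict())
    for r in hist:
        history.append(phase="supervised", **r)
    return params, history
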