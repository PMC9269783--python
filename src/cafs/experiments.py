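"""Experiment harness: configuration files, ablation table, labeled sweep.

An :class:`ExperimentConfig` bundles everything one run needs — phantom
generator, cohort size, split ratios, network and training hyperparameters,
ablation flags — and round-trips through YAML with unknown keys rejected, so
a results directory carrying its resolved config is self-describing.

Two presets are provided. ``paper_protocol`` mirrors the reference setup
(256x256 frames, 83 patients, 1000 labeled images, SGD lr 0.001 / weight
decay 0.0001 / 1500 iterations / batch 8). ``scaled_protocol`` is the
desk-scale protocol every test and example runs: ~40 phantom patients at
64x64, a depth-2 base-6 network, 25% of training slices labeled, and a short
optimization budget with correspondingly larger step sizes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .data import ImageSample, expand_cohort, split_by_patient
from .engine import (TrainConfig, pretrain_teacher, train,
                     train_supervised)
from .errors import ConfigError
from .metrics import evaluate_dataset
from .phantom import PhantomSpec, generate_cohort
from .unet import NetworkConfig, UNet

__all__ = [
    "ExperimentConfig", "ABLATION_VARIANTS", "scaled_protocol",
    "paper_protocol", "build_cohort", "run_ablation", "run_labeled_sweep",
    "make_predictor",
]

# Ablation rows: (feedback, attention, pretraining)
ABLATION_VARIANTS = {
    "C-S + Fb + Att": dict(feedback_enabled=True, attention_enabled=True,
                           pretrain_enabled=True),
    "C-S + Fb": dict(feedback_enabled=True, attention_enabled=False,
                     pretrain_enabled=True),
    "C-S + Att": dict(feedback_enabled=False, attention_enabled=True,
                      pretrain_enabled=True),
    "C-S": dict(feedback_enabled=False, attention_enabled=False,
                pretrain_enabled=True),
    "Without Pre-training": dict(feedback_enabled=True, attention_enabled=True,
                                 pretrain_enabled=False),
}


def _from_mapping(cls, d: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**d)


@dataclass
class ExperimentConfig:
    """One fully specified experiment."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_patients: int = 83
    slices_per_patient: Tuple[int, int] = (8, 12)
    split_ratios: Tuple[float, float, float] = (0.70, 0.15, 0.15)
    split_seed: int = 0
    cohort_seed: int = 0
    augment_ops: Tuple[str, ...] = ()
    labeled_count: Optional[int] = 1000
    labeled_fraction: Optional[float] = None
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    pretrain_enabled: bool = True
    seeds: Tuple[int, ...] = (0, 1, 2)
    output_dir: str = "results"

    def __post_init__(self):
        if (self.labeled_count is None) == (self.labeled_fraction is None):
            raise ConfigError(
                "exactly one of labeled_count / labeled_fraction is required")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["network"] = self.network.to_dict()
        d["training"] = self.training.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "phantom" in d:
            ph = dict(d["phantom"])
            if "tumor_area_fraction_range" in ph:
                ph["tumor_area_fraction_range"] = tuple(
                    ph["tumor_area_fraction_range"])
            d["phantom"] = _from_mapping(PhantomSpec, ph, "phantom")
        if "network" in d:
            d["network"] = NetworkConfig.from_dict(dict(d["network"]))
        if "training" in d:
            d["training"] = _from_mapping(TrainConfig, dict(d["training"]),
                                          "training")
        for key in ("slices_per_patient", "split_ratios", "augment_ops",
                    "seeds"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(d)


def paper_protocol() -> ExperimentConfig:
    """Reference-scale settings (not intended for desk hardware)."""
    return ExperimentConfig(
        phantom=PhantomSpec(frame_size=256),
        n_patients=83, slices_per_patient=(8, 12),
        labeled_count=1000,
        augment_ops=("rotate90", "rotate180", "rotate270", "flip_horizontal"),
        network=NetworkConfig(depth=4, base_channels=32),
        training=TrainConfig(),
    )


def scaled_protocol(seed: int = 0) -> ExperimentConfig:
    """Desk-scale protocol used by the tests, examples and ablation table.

    ~40 phantom patients at 64x64 with low tumor/distractor contrast, a
    depth-2 base-6 network, 25% of training slices labeled, and a short
    SGD budget (80 pretraining + 75 cooperative iterations at lr 0.1,
    momentum 0.5) sized so a full ablation fits in CPU minutes.
    """
    return ExperimentConfig(
        phantom=PhantomSpec(
            frame_size=64, tumor_area_fraction_range=(0.05, 0.15),
            boundary_harmonics=5, boundary_roughness=0.35,
            contrast_gap=0.05, distractor_count=6, noise_sd=0.08,
            bias_field_strength=0.20, seed=seed),
        n_patients=40, slices_per_patient=(3, 5),
        cohort_seed=seed, split_seed=seed,
        labeled_count=None, labeled_fraction=0.25,
        network=NetworkConfig(depth=2, base_channels=6, dtype="float32"),
        training=TrainConfig(
            learning_rate=0.1, momentum=0.5, weight_decay=1e-4,
            pretrain_iterations=80, iterations=75, batch_size=8,
            eval_every=25, finetune_lr_scale=0.05, seed=seed),
        seeds=(seed, seed + 1, seed + 2),
    )


# ---------------------------------------------------------------------------
# cohort assembly


def build_cohort(cfg: ExperimentConfig):
    """Generate, split and label-flag a cohort.

    Returns ``(labeled, unlabeled, valid, test, split)``. The labeled pool is
    the first ``labeled_count`` training slices in deterministic patient
    order; the remaining training slices keep their ground truth for
    evaluation but are flagged unlabeled for training purposes.
    """
    samples = generate_cohort(cfg.phantom, cfg.n_patients,
                              cfg.slices_per_patient, cfg.cohort_seed)
    split = split_by_patient(samples, cfg.split_ratios, cfg.split_seed)
    tr, va, te = split.assign(samples)
    if cfg.augment_ops:
        tr = expand_cohort(tr, cfg.augment_ops)
    n_lab = cfg.labeled_count if cfg.labeled_count is not None \
        else max(1, int(round(cfg.labeled_fraction * len(tr))))
    if n_lab > len(tr):
        raise ConfigError(f"labeled_count {n_lab} exceeds training-set size "
                          f"{len(tr)}")
    labeled = [replace(s, labeled=True) for s in tr[:n_lab]]
    unlabeled = [replace(s, labeled=False) for s in tr[n_lab:]]
    return labeled, unlabeled, va, te, split


def make_predictor(params, net_config: NetworkConfig):
    """Wrap a ParameterSet as a ``sample -> binary mask`` callable."""
    net = UNet(net_config)

    def _predict(sample: ImageSample) -> np.ndarray:
        logits = net.forward(params, np.asarray(sample.image)[None, None],
                             train=False)
        return (logits[0, 1] > logits[0, 0]).astype(np.int8)

    return _predict


# ---------------------------------------------------------------------------
# harnesses


def _variant_config(cfg: ExperimentConfig, flags: dict,
                    seed: int) -> TrainConfig:
    tc = replace(cfg.training, seed=seed,
                 feedback_enabled=flags["feedback_enabled"],
                 attention_enabled=flags["attention_enabled"])
    if not flags.get("pretrain_enabled", True):
        tc = replace(tc, pretrain_iterations=0)
    return tc


_METRIC_KEYS = ("dsc", "jaccard", "precision", "recall", "specificity")


def _score_row(params, net_config, valid, test) -> dict:
    """Mean per-image metrics on the validation split, plus ``*_test``."""
    row = {}
    for suffix, subset in (("", valid), ("_test", test)):
        rep = evaluate_dataset(make_predictor(params, net_config),
                               subset)["mean_per_image"]
        for m in _METRIC_KEYS:
            row[f"{m}{suffix}"] = getattr(rep, m)
    return row


def run_ablation(cfg: ExperimentConfig,
                 seeds: Optional[Sequence[int]] = None,
                 include_supervised: bool = False,
                 progress=None) -> pd.DataFrame:
    """Run the five module-combination configurations over several seeds.

    Teacher pretraining is shared between variants that use the same
    attention setting and seed (the pretraining phase is identical there).
    Returns a tidy table: one row per (variant, seed) with DSC/Jaccard/
    precision/recall/specificity of the student on the validation split and
    the same metrics with a ``_test`` suffix for the held-out test split.
    """
    seeds = list(cfg.seeds if seeds is None else seeds)
    if len(seeds) < 2:
        import warnings
        warnings.warn("fewer than 2 seeds: dispersion estimates are empty")
    labeled, unlabeled, va, te, _ = build_cohort(cfg)
    rows = []
    for seed in seeds:
        pretrained: Dict[bool, object] = {}
        for att in (True, False):
            tc = replace(cfg.training, seed=seed, attention_enabled=att)
            ncfg = replace(cfg.network, attention_enabled=att)
            pretrained[att], _ = pretrain_teacher(labeled, tc, ncfg, valid=va)
        for name, flags in ABLATION_VARIANTS.items():
            tc = _variant_config(cfg, flags, seed)
            tinit = pretrained[tc.attention_enabled] \
                if flags.get("pretrain_enabled", True) else None
            teacher, student, _ = train(labeled, unlabeled, va, tc,
                                        cfg.network, teacher_init=tinit)
            ncfg = replace(cfg.network,
                           attention_enabled=tc.attention_enabled)
            rows.append({"variant": name, "seed": seed,
                         **_score_row(student, ncfg, va, te)})
            if progress:
                progress(rows[-1])
        if include_supervised:
            tc = replace(cfg.training, seed=seed, attention_enabled=False)
            params, _ = train_supervised(labeled, va, tc, cfg.network)
            ncfg = replace(cfg.network, attention_enabled=False)
            rows.append({"variant": "Supervised-only", "seed": seed,
                         **_score_row(params, ncfg, va, te)})
            if progress:
                progress(rows[-1])
    return pd.DataFrame(rows)


def summarize_ablation(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd per variant, in the canonical row order."""
    order = list(ABLATION_VARIANTS) + ["Supervised-only"]
    metrics = [c for c in table.columns if c not in ("variant", "seed")]
    g = table.groupby("variant")[metrics]
    out = g.mean().join(g.std(), rsuffix="_sd")
    out = out.reindex([v for v in order if v in out.index])
    return out


def run_labeled_sweep(cfg: ExperimentConfig, counts: Sequence[int],
                      seeds: Optional[Sequence[int]] = None,
                      progress=None) -> pd.DataFrame:
    """Vary the number of labeled training images, full model each time."""
    seeds = list(cfg.seeds if seeds is None else seeds)
    rows = []
    for count in counts:
        sub = replace(cfg, labeled_count=int(count), labeled_fraction=None)
        labeled, unlabeled, va, te, _ = build_cohort(sub)
        for seed in seeds:
            tc = replace(cfg.training, seed=seed)
            teacher, student, _ = train(labeled, unlabeled, va, tc,
                                        cfg.network)
            ncfg = replace(cfg.network,
                           attention_enabled=tc.attention_enabled)
            rep = evaluate_dataset(make_predictor(student, ncfg),
                                   va)["mean_per_image"]
            rows.append({"labeled_count": int(count), "seed": seed,
                         "dsc": rep.dsc, "jaccard": rep.jaccard,
                         "precision": rep.precision, "recall": rep.recall})
            if progress:
                progress(rows[-1])
    return pd.DataFrame(rows)
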