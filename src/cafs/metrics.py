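"""Confusion-count segmentation metrics.

All five scores derive from pixel confusion counts between a binary
prediction and the ground truth:

    DSC       = 2 TP / (2 TP + FP + FN)       (= 2|A∩B| / (|A| + |B|))
    Jaccard   = TP / (TP + FP + FN)           (DSC = 2J / (1 + J))
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    specificity = TN / (TN + FP)

Degenerate denominators follow the common benchmark convention: two empty
masks agree perfectly (DSC = J = 1); an undefined ratio is reported as 1 and
flagged in ``MetricReport.degenerate``; an empty prediction against a
non-empty truth scores DSC = J = 0.

Datasets can be aggregated two ways — the mean of per-image metrics, or
metrics computed on counts pooled across all images — and both are always
reported, since the two answer different questions and disagree whenever
image difficulty varies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import ImageSample
from .errors import DataError, ShapeError

__all__ = [
    "ConfusionCounts", "MetricReport", "confusion",
    "dsc", "jaccard", "precision", "recall", "specificity",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies between two binary masks of equal shape."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeError(f"pred {pred.shape} vs truth {truth.shape}")
    for name, m in (("pred", pred), ("truth", truth)):
        if not np.all(np.isin(np.unique(m), (0, 1))):
            raise DataError(f"{name} mask is not binary")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def dsc(c: ConfusionCounts) -> float:
    den = 2 * c.tp + c.fp + c.fn
    return 1.0 if den == 0 else 2 * c.tp / den


def jaccard(c: ConfusionCounts) -> float:
    den = c.tp + c.fp + c.fn
    return 1.0 if den == 0 else c.tp / den


def precision(c: ConfusionCounts) -> float:
    den = c.tp + c.fp
    return 1.0 if den == 0 else c.tp / den


def recall(c: ConfusionCounts) -> float:
    den = c.tp + c.fn
    return 1.0 if den == 0 else c.tp / den


def specificity(c: ConfusionCounts) -> float:
    den = c.tn + c.fp
    return 1.0 if den == 0 else c.tn / den


_METRICS: Dict[str, Callable[[ConfusionCounts], float]] = {
    "dsc": dsc, "jaccard": jaccard, "precision": precision,
    "recall": recall, "specificity": specificity,
}


@dataclass
class MetricReport:
    """All five metrics plus the counts they came from."""

    dsc: float
    jaccard: float
    precision: float
    recall: float
    specificity: float
    counts: ConfusionCounts
    scope: str = "per_image"
    degenerate: Tuple[str, ...] = ()

    @classmethod
    def from_counts(cls, c: ConfusionCounts, scope: str = "per_image"
                    ) -> "MetricReport":
        flags = []
        if c.tp + c.fp == 0:
            flags.append("precision")
        if c.tp + c.fn == 0:
            flags.append("recall")
        if c.tn + c.fp == 0:
            flags.append("specificity")
        return cls(dsc=dsc(c), jaccard=jaccard(c), precision=precision(c),
                   recall=recall(c), specificity=specificity(c), counts=c,
                   scope=scope, degenerate=tuple(flags))

    def to_dict(self) -> dict:
        return {
            "dsc": self.dsc, "jaccard": self.jaccard,
            "precision": self.precision, "recall": self.recall,
            "specificity": self.specificity, "scope": self.scope,
            "degenerate": list(self.degenerate),
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                       "fn": self.counts.fn, "tn": self.counts.tn},
        }


def evaluate_dataset(predict: Callable[[ImageSample], np.ndarray],
                     samples: Sequence[ImageSample]) -> dict:
    """Score a predictor on every sample.

    Returns ``{"mean_per_image": MetricReport, "pooled_counts": MetricReport,
    "per_image": DataFrame}``; the per-image table is keyed by patient and
    slice id.
    """
    if not samples:
        raise DataError("no samples to evaluate")
    rows = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for s in samples:
        if s.mask is None:
            raise DataError(f"sample {s.patient_id}/{s.slice_id} has no mask")
        c = confusion(predict(s), s.mask)
        pooled = pooled + c
        row = {"patient_id": s.patient_id, "slice_id": s.slice_id}
        row.update({k: fn(c) for k, fn in _METRICS.items()})
        rows.append(row)
    table = pd.DataFrame(rows)
    mean_vals = table[list(_METRICS)].mean()
    mean_report = MetricReport(
        dsc=float(mean_vals["dsc"]), jaccard=float(mean_vals["jaccard"]),
        precision=float(mean_vals["precision"]),
        recall=float(mean_vals["recall"]),
        specificity=float(mean_vals["specificity"]),
        counts=pooled, scope="mean_per_image")
    pooled_report = MetricReport.from_counts(pooled, scope="pooled_counts")
    return {"mean_per_image": mean_report, "pooled_counts": pooled_report,
            "per_image": table}
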