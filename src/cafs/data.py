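"""Image samples, geometric augmentation, patient-wise splitting, dataset I/O.

The unit of all I/O is :class:`ImageSample`: one grayscale slice in [0, 1]
with an optional binary tumor mask and a (patient, slice) identity. Cohorts
are split by patient — slices from one patient never appear in more than one
of train/validation/test — and datasets round-trip through 8-bit grayscale
PNG files plus a CSV manifest.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from .errors import ConfigError, DataError, InfeasibleSplitError

__all__ = [
    "ImageSample", "CohortSplit", "AUGMENT_OPS", "augment", "expand_cohort",
    "split_by_patient", "write_dataset", "read_dataset", "load_nifti_slice",
]


@dataclass
class ImageSample:
    """One grayscale slice with optional binary ground-truth mask.

    ``labeled`` marks whether the mask may be used as supervision (a synthetic
    cohort keeps ground truth on every slice for evaluation, but only the
    labeled fraction is visible to training).
    """

    image: np.ndarray
    mask: Optional[np.ndarray]
    patient_id: str
    slice_id: str
    labeled: bool = True

    def validate(self, frame_size: Optional[int] = None) -> None:
        img = self.image
        if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
            raise DataError(f"image must be 2D and non-empty, got {img.shape}")
        if self.mask is not None:
            if self.mask.shape != img.shape:
                raise DataError(
                    f"mask shape {self.mask.shape} != image shape {img.shape} "
                    f"for {self.patient_id}/{self.slice_id}")
            vals = np.unique(self.mask)
            if not np.all(np.isin(vals, (0, 1))):
                raise DataError(
                    f"mask of {self.patient_id}/{self.slice_id} contains "
                    f"values outside {{0, 1}}: {vals[:5]}")
        if frame_size is not None and img.shape != (frame_size, frame_size):
            raise DataError(f"expected {frame_size}x{frame_size} frame, "
                            f"got {img.shape}")


# ---------------------------------------------------------------------------
# augmentation

# Rotations are counter-clockwise in array coordinates and restricted to
# multiples of 90 degrees so masks stay exact (no interpolation).
AUGMENT_OPS = ("rotate90", "rotate180", "rotate270",
               "flip_horizontal", "flip_vertical")

_AUG_FN = {
    "rotate90": lambda a: np.rot90(a, 1),
    "rotate180": lambda a: np.rot90(a, 2),
    "rotate270": lambda a: np.rot90(a, 3),
    "flip_horizontal": np.fliplr,
    "flip_vertical": np.flipud,
}


def augment(sample: ImageSample, op: str) -> ImageSample:
    """Apply one exact geometric op identically to image and mask."""
    if op not in _AUG_FN:
        raise ConfigError(f"unknown augmentation op {op!r}; "
                          f"choose from {AUGMENT_OPS}")
    fn = _AUG_FN[op]
    return replace(
        sample,
        image=np.ascontiguousarray(fn(sample.image)),
        mask=None if sample.mask is None else np.ascontiguousarray(fn(sample.mask)),
        slice_id=f"{sample.slice_id}+{op}",
    )


def expand_cohort(samples: Sequence[ImageSample],
                  ops: Sequence[str] = ("rotate90", "rotate180", "rotate270",
                                        "flip_horizontal"),
                  ) -> List[ImageSample]:
    """Offline augmentation: originals followed by one variant per op."""
    out = list(samples)
    for op in ops:
        if op not in _AUG_FN:
            raise ConfigError(f"unknown augmentation op {op!r}")
    for s in samples:
        for op in ops:
            out.append(augment(s, op))
    return out


# ---------------------------------------------------------------------------
# patient-wise splitting


@dataclass
class CohortSplit:
    """Disjoint patient sets for train/validation/test."""

    train_patients: Tuple[str, ...]
    valid_patients: Tuple[str, ...]
    test_patients: Tuple[str, ...]
    ratios: Tuple[float, float, float]

    def assign(self, samples: Iterable[ImageSample]
               ) -> Tuple[List[ImageSample], List[ImageSample], List[ImageSample]]:
        tr = set(self.train_patients)
        va = set(self.valid_patients)
        te = set(self.test_patients)
        out: Tuple[List[ImageSample], ...] = ([], [], [])
        for s in samples:
            if s.patient_id in tr:
                out[0].append(s)
            elif s.patient_id in va:
                out[1].append(s)
            elif s.patient_id in te:
                out[2].append(s)
            else:
                raise DataError(f"patient {s.patient_id} not in split")
        return out


def split_counts(n: int, ratios: Sequence[float]) -> Tuple[int, int, int]:
    """Patient counts per split.

    The validation and test splits receive the ceiling of their quotas and
    training takes the remainder, so evaluation splits are never rounded away
    (83 patients at 70/15/15 gives 57/13/13). On very small cohorts, where
    the ceilings would leave training empty despite a positive ratio, seats
    are reclaimed from the most over-allocated evaluation split.
    """
    r1, r2, r3 = ratios
    n_valid = math.ceil(n * r2) if r2 > 0 else 0
    n_test = math.ceil(n * r3) if r3 > 0 else 0
    n_train = n - n_valid - n_test
    need = 1 if r1 > 0 else 0
    while n_train < need and n_valid + n_test > 0:
        if n_valid > 0 and (n_test == 0
                            or n_valid - n * r2 >= n_test - n * r3):
            n_valid -= 1
        else:
            n_test -= 1
        n_train += 1
    return n_train, n_valid, n_test


def split_by_patient(samples: Sequence[ImageSample],
                     ratios: Tuple[float, float, float],
                     seed: int) -> CohortSplit:
    """Deterministic patient-level partition with no leakage.

    Patients are shuffled by ``seed`` and partitioned by the cumulative counts
    of :func:`split_counts`.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigError(f"split ratios must sum to 1, got {ratios}")
    if any(r < 0 for r in ratios):
        raise ConfigError(f"split ratios must be non-negative, got {ratios}")
    patients = sorted({s.patient_id for s in samples})
    n = len(patients)
    n_nonzero = sum(1 for r in ratios if r > 0)
    if n < n_nonzero:
        raise InfeasibleSplitError(
            f"{n} patients cannot populate {n_nonzero} non-empty splits")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [patients[i] for i in order]
    n_tr, n_va, n_te = split_counts(n, ratios)
    if min(n_tr, n_va, n_te) < 0 or (ratios[0] > 0 and n_tr == 0):
        raise InfeasibleSplitError(
            f"cannot split {n} patients at ratios {ratios}")
    return CohortSplit(
        train_patients=tuple(shuffled[:n_tr]),
        valid_patients=tuple(shuffled[n_tr:n_tr + n_va]),
        test_patients=tuple(shuffled[n_tr + n_va:]),
        ratios=tuple(ratios),
    )


# ---------------------------------------------------------------------------
# dataset I/O (8-bit grayscale PNG + CSV manifest)

MANIFEST_COLUMNS = ("patient_id", "slice_id", "image", "mask", "labeled")


def _slug(s: ImageSample) -> str:
    return f"{s.patient_id}_{s.slice_id}".replace("/", "-").replace("+", "-")


def write_dataset(samples: Sequence[ImageSample], directory) -> Path:
    """Write PNG images/masks plus a CSV manifest; return the manifest path.

    Images are quantized to 8 bits (max round-trip error 1/255 per pixel);
    masks are written as {0, 255} and round-trip exactly.
    """
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(MANIFEST_COLUMNS)
        for s in samples:
            s.validate()
            slug = _slug(s)
            img_rel = f"images/{slug}.png"
            img8 = np.clip(np.rint(s.image * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(img8, mode="L").save(directory / img_rel)
            mask_rel = ""
            if s.mask is not None:
                mask_rel = f"masks/{slug}.png"
                Image.fromarray((s.mask.astype(np.uint8) * 255), mode="L"
                                ).save(directory / mask_rel)
            wr.writerow([s.patient_id, s.slice_id, img_rel, mask_rel,
                         int(s.labeled)])
    return manifest


def read_dataset(manifest_path) -> List[ImageSample]:
    """Load a dataset back from its manifest."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DataError(f"manifest not found: {manifest_path}")
    root = manifest_path.parent
    samples: List[ImageSample] = []
    with open(manifest_path, newline="") as fh:
        rd = csv.DictReader(fh)
        if rd.fieldnames is None or tuple(rd.fieldnames) != MANIFEST_COLUMNS:
            raise DataError(f"manifest {manifest_path} has unexpected header "
                            f"{rd.fieldnames}")
        for row in rd:
            img_path = root / row["image"]
            if not img_path.exists():
                raise DataError(f"image file missing: {img_path}")
            img = np.asarray(Image.open(img_path).convert("L"),
                             dtype=np.float64) / 255.0
            mask = None
            if row["mask"]:
                mask_path = root / row["mask"]
                if not mask_path.exists():
                    raise DataError(f"mask file missing: {mask_path}")
                raw = np.asarray(Image.open(mask_path).convert("L"))
                vals = np.unique(raw)
                if not np.all(np.isin(vals, (0, 255))):
                    raise DataError(f"mask {mask_path} has values outside "
                                    f"{{0, 255}}: {vals[:5]}")
                mask = (raw == 255).astype(np.int8)
            samples.append(ImageSample(
                image=img, mask=mask, patient_id=row["patient_id"],
                slice_id=row["slice_id"], labeled=bool(int(row["labeled"]))))
    return samples


def load_nifti_slice(path, slice_index: int = 0, axis: int = 2) -> np.ndarray:
    """Read one 2D slice from a NIfTI volume, min-max scaled to [0, 1]."""
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise DataError(f"NIfTI file missing: {path}")
    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    if vol.ndim == 2:
        sl = vol
    else:
        sl = np.take(vol, slice_index, axis=axis)
    lo, hi = float(sl.min()), float(sl.max())
    if hi > lo:
        sl = (sl - lo) / (hi - lo)
    else:
        sl = np.zeros_like(sl)
    return sl
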