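"""Synthetic tumor-phantom cohorts.

The generator emulates the statistical structure of contrast-enhanced head
MRI slices around a nasopharyngeal tumor as far as a segmentation method
cares about it: a single connected target whose intensity is close to that of
surrounding distractor tissue (low contrast), an irregular star-convex
boundary (radial Fourier harmonics on an elliptical base), several correlated
slices per patient (a shared patient-level base shape with small per-slice
deformations), a smooth multiplicative bias field, and additive Gaussian
noise. The returned mask is the exact rasterization of the tumor curve, so
ground truth is noise-free by construction.

Every output is a pure function of ``(spec, patient_seed, slice_index)``:
identical inputs reproduce identical samples bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .data import ImageSample
from .errors import ConfigError

__all__ = ["PhantomSpec", "generate_slice", "generate_cohort",
           "radial_boundary", "rasterize_star"]

_BG_LEVEL = 0.40          # mean surrounding-tissue intensity
_TUMOR_CONTRAST = 0.22    # tumor mean above background


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one phantom cohort.

    tumor_area_fraction_range
        Admissible foreground fraction of each slice, within (0, 0.5).
    boundary_harmonics / boundary_roughness
        Number of radial Fourier modes and their dimensionless amplitude;
        roughness 0 yields an exact ellipse.
    contrast_gap
        Mean intensity difference between tumor and distractor blobs in
        [0, 1]; small values make distractors resemble the tumor.
    noise_sd
        Standard deviation of additive Gaussian intensity noise.
    bias_field_strength
        Relative amplitude of the smooth multiplicative bias field.
    """

    frame_size: int = 256
    tumor_area_fraction_range: Tuple[float, float] = (0.02, 0.10)
    boundary_harmonics: int = 6
    boundary_roughness: float = 0.25
    contrast_gap: float = 0.08
    distractor_count: int = 6
    noise_sd: float = 0.05
    bias_field_strength: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.tumor_area_fraction_range
        if not (0.0 < lo < hi < 0.5):
            raise ConfigError(
                f"tumor_area_fraction_range must satisfy 0 < lo < hi < 0.5, "
                f"got {self.tumor_area_fraction_range}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.boundary_harmonics < 1:
            raise ConfigError("boundary_harmonics must be >= 1")
        if self.frame_size < 8:
            raise ConfigError("frame_size must be >= 8")
        if not (0.0 <= self.contrast_gap <= 1.0):
            raise ConfigError("contrast_gap must lie in [0, 1]")
        if self.distractor_count < 0:
            raise ConfigError("distractor_count must be >= 0")


# ---------------------------------------------------------------------------
# boundary model


def radial_boundary(phi: np.ndarray, axes: Tuple[float, float], tilt: float,
                    coeffs: np.ndarray, roughness: float) -> np.ndarray:
    """Radius of the star-convex tumor curve at polar angles ``phi``.

    The base is an ellipse with semi-axes ``axes`` rotated by ``tilt``;
    harmonics perturb it multiplicatively. The modulation factor is clipped
    at 0.2 to keep the curve star-convex and strictly positive.
    """
    a, b = axes
    ph = phi - tilt
    base = a * b / np.sqrt((b * np.cos(ph)) ** 2 + (a * np.sin(ph)) ** 2)
    mod = np.ones_like(phi)
    for h in range(1, coeffs.shape[1] + 1):
        mod += roughness * (coeffs[0, h - 1] * np.cos(h * phi)
                            + coeffs[1, h - 1] * np.sin(h * phi))
    return base * np.clip(mod, 0.2, None)


def rasterize_star(frame: int, center: Tuple[float, float],
                   axes: Tuple[float, float], tilt: float,
                   coeffs: np.ndarray, roughness: float) -> np.ndarray:
    """Exact pixel-center rasterization of the star-convex region."""
    yy, xx = np.mgrid[0:frame, 0:frame].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    rho = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)
    r = radial_boundary(phi, axes, tilt, coeffs, roughness)
    return (rho <= r).astype(np.int8)


def _fit_scale(spec: PhantomSpec, center, ratio, tilt, coeffs,
               target_frac: float) -> np.ndarray:
    """Scale the curve until the rasterized area fraction enters the range."""
    frame = spec.frame_size
    lo, hi = spec.tumor_area_fraction_range
    npx = frame * frame

    def area(scale):
        axes = (scale, scale * ratio)
        return rasterize_star(frame, center, axes, tilt, coeffs,
                              spec.boundary_roughness)

    # initial guess from the target area of an unperturbed ellipse
    scale = math.sqrt(target_frac * npx / (math.pi * ratio))
    mask = area(scale)
    for _ in range(4):
        frac = mask.sum() / npx
        if lo <= frac <= hi:
            return mask
        scale *= math.sqrt(target_frac / max(frac, 1e-9))
        mask = area(scale)
    # fall back to bisection against the midpoint of the admissible range
    s_lo, s_hi = scale * 0.25, scale * 4.0
    for _ in range(50):
        s_mid = 0.5 * (s_lo + s_hi)
        mask = area(s_mid)
        frac = mask.sum() / npx
        if lo <= frac <= hi:
            return mask
        if frac < lo:
            s_lo = s_mid
        else:
            s_hi = s_mid
    raise ConfigError(
        f"could not fit tumor area into {spec.tumor_area_fraction_range} "
        f"on a {frame}x{frame} frame")


# ---------------------------------------------------------------------------
# slice and cohort generation


def _patient_base(spec: PhantomSpec, patient_seed: int):
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, int(patient_seed)]))
    frame = spec.frame_size
    center = (frame / 2 + rng.uniform(-0.08, 0.08) * frame,
              frame / 2 + rng.uniform(-0.08, 0.08) * frame)
    ratio = rng.uniform(0.7, 1.0)          # ellipse axis ratio
    tilt = rng.uniform(0.0, math.pi)
    H = spec.boundary_harmonics
    coeffs = rng.normal(0.0, 1.0, size=(2, H)) / np.arange(1, H + 1)
    target = rng.uniform(*spec.tumor_area_fraction_range)
    return center, ratio, tilt, coeffs, target


def generate_slice(spec: PhantomSpec, patient_seed: int,
                   slice_index: int) -> ImageSample:
    """One phantom slice; slices of a patient share the base tumor shape."""
    spec.validate()
    frame = spec.frame_size
    center, ratio, tilt, coeffs, target = _patient_base(spec, patient_seed)
    rng = np.random.default_rng(np.random.SeedSequence(
        [spec.seed, int(patient_seed), int(slice_index)]))

    # small per-slice deformation of the patient base shape
    coeffs = coeffs + rng.normal(0.0, 0.12, size=coeffs.shape) \
        / np.arange(1, coeffs.shape[1] + 1)
    center = (center[0] + rng.uniform(-0.02, 0.02) * frame,
              center[1] + rng.uniform(-0.02, 0.02) * frame)
    mask = _fit_scale(spec, center, ratio, tilt, coeffs, target)

    # tissue background with smooth texture
    img = np.full((frame, frame), _BG_LEVEL)
    img += 0.06 * gaussian_filter(rng.standard_normal((frame, frame)),
                                  sigma=frame / 16.0)

    # distractor blobs whose level sits contrast_gap below the tumor level
    yy, xx = np.mgrid[0:frame, 0:frame].astype(np.float64)
    distractor_level = _TUMOR_CONTRAST - spec.contrast_gap
    for _ in range(spec.distractor_count):
        cy, cx = rng.uniform(0.1 * frame, 0.9 * frame, size=2)
        sig = rng.uniform(0.04, 0.10) * frame
        amp = distractor_level * rng.uniform(0.8, 1.2)
        img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig ** 2))

    # tumor region, slightly feathered so its edge is not a hard step
    img += _TUMOR_CONTRAST * gaussian_filter(mask.astype(np.float64), 0.7)

    # smooth multiplicative bias field (low-order cosine modes)
    u, v = rng.integers(1, 3, size=2)
    p1, p2 = rng.uniform(0, 2 * math.pi, size=2)
    bias = np.cos(math.pi * u * yy / frame + p1) \
        * np.cos(math.pi * v * xx / frame + p2)
    img *= 1.0 + spec.bias_field_strength * bias

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    sample = ImageSample(image=img, mask=mask,
                         patient_id=f"P{int(patient_seed):03d}",
                         slice_id=f"S{int(slice_index):02d}")
    sample.validate(frame_size=frame)
    return sample


def generate_cohort(spec: PhantomSpec, n_patients: int,
                    slices_per_patient_range: Tuple[int, int],
                    seed: int) -> List[ImageSample]:
    """A full cohort with per-patient slice counts drawn uniformly.

    RNG consumption order (relied on by replay tests): one Generator seeded
    with ``SeedSequence([seed])`` draws, for each patient index p in order,
    ``integers(lo, hi, endpoint=True)``; patient p then uses ``patient_seed=p``.
    """
    spec.validate()
    if n_patients < 1:
        raise ConfigError(f"n_patients must be >= 1, got {n_patients}")
    lo, hi = slices_per_patient_range
    if lo < 1 or hi < lo:
        raise ConfigError(
            f"invalid slices_per_patient_range {slices_per_patient_range}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    samples: List[ImageSample] = []
    for p in range(n_patients):
        count = int(rng.integers(lo, hi, endpoint=True))
        for j in range(count):
            samples.append(generate_slice(spec, p, j))
    return samples
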