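"""Shared fixtures: tiny phantom specs, toy networks, seeded RNGs."""

import numpy as np
import pytest

from cafs.attention import AttentionConfig
from cafs.phantom import PhantomSpec
from cafs.unet import NetworkConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """Small, fast phantom spec used across data-level tests."""
    return PhantomSpec(frame_size=32, tumor_area_fraction_range=(0.05, 0.2),
                       boundary_harmonics=3, boundary_roughness=0.2,
                       contrast_gap=0.06, distractor_count=2, noise_sd=0.04,
                       bias_field_strength=0.1, seed=7)


@pytest.fixture
def toy_net_config():
    """Double-precision depth-2 toy network for exact gradient work."""
    return NetworkConfig(depth=2, base_channels=3, dtype="float64")


@pytest.fixture
def toy_attention_config():
    return AttentionConfig(kernel_sizes=[1, 3], reduction_ratio=2)
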