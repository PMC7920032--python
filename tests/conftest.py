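"""Shared fixtures: synthetic recordings reused across test modules."""

import logging

import numpy as np
import pytest

import neopcg as n

# the stable-run fallback warning is expected on some murmur recordings
logging.getLogger("neopcg.segmentation").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_recording():
    """Murmur-free recording at default (control-like) settings."""
    return n.simulate_recording(n.SimConfig(seed=11))


@pytest.fixture(scope="session")
def murmur_recording():
    """Strong-murmur recording (ratio 10, true SNR_sys = 20 dB)."""
    return n.simulate_recording(n.SimConfig(seed=7, murmur_ratio=10.0), group="CHD")


@pytest.fixture(scope="session")
def small_cohort():
    """A 3 vs 3 cohort for smoke-level cohort statistics."""
    return n.simulate_cohort(3, 3, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
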