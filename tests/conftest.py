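"""Shared fixtures: small synthetic recordings reused across test modules.

Session scope keeps the expensive generation and feature extraction to one
run per test session.
"""

import numpy as np
import pytest

from mibci import (
    PipelineConfig,
    SyntheticConfig,
    extract_time_features,
    extract_wpd_features,
    fuse_features,
    generate_recording,
    preprocess,
)


@pytest.fixture(scope="session")
def strong_recording_small():
    """18-channel strong-contrast recording, 20 trials/class (fast)."""
    return generate_recording(SyntheticConfig(n_trials_per_class=20, seed=0))


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def epochs_small(strong_recording_small, pipeline_config):
    return preprocess(strong_recording_small, pipeline_config)


@pytest.fixture(scope="session")
def features_small(epochs_small):
    """Fused 1836-column feature matrix for the small strong recording."""
    tb = extract_time_features(epochs_small)
    wb = extract_wpd_features(epochs_small)
    return fuse_features(tb, wb, epochs_small.labels)


@pytest.fixture(scope="session")
def recording3_small():
    """3-channel (C3, Cz, C4) strong-contrast recording, 15 trials/class."""
    return generate_recording(
        SyntheticConfig(n_trials_per_class=15, n_channels=3, seed=1))


@pytest.fixture(scope="session")
def epochs3_small(recording3_small, pipeline_config):
    return preprocess(recording3_small, pipeline_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
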