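"""Shared fixtures: small synthetic datasets and feature matrices.

The heavy datasets used by the calibration and signal-recovery checks are
session-scoped so they are generated and featurised once.
"""

import numpy as np
import pytest

from mieeg import (
    RunConfig,
    SynthParams,
    extract_matrix,
    generate_dataset,
    generate_null_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return RunConfig(seed=5)


@pytest.fixture
def small_segments():
    """Tiny 4-class dataset: 2 segments/class, 6 channels, 2 s at 250 Hz."""
    params = SynthParams(n_channels=6, n_per_class=2, duration_s=2.0, seed=11)
    return generate_dataset(params)


@pytest.fixture
def small_fm(small_segments, small_config):
    return extract_matrix(small_segments, small_config)


@pytest.fixture(scope="session")
def null_fm_replicates():
    """Four independent null datasets at the calibration size (4 x 25/class)."""
    fms = []
    for seed in (101, 102, 103, 104):
        params = SynthParams(n_per_class=25, seed=seed)
        fms.append(extract_matrix(generate_null_dataset(params)))
    return fms


@pytest.fixture(scope="session")
def effect_fm():
    """Two-class, effect_size=0.9, 100 segments/class — the recovery condition."""
    params = SynthParams(
        n_per_class=100, class_names=("LH", "RH"), effect_size=0.9, seed=77
    )
    return params, extract_matrix(generate_dataset(params))
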