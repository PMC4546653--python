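"""Shared fixtures: small synthetic datasets with known planted structure."""

import numpy as np
import pytest

from eegrsa import CVConfig, GeneratorConfig, simulate_dataset


@pytest.fixture
def small_cfg() -> GeneratorConfig:
    """Strong-signal miniature design: 6 categories x 2 exemplars x 10 trials."""
    return GeneratorConfig(
        n_electrodes=6,
        n_time_samples=16,
        n_categories=6,
        n_exemplars_per_category=2,
        n_trials_per_exemplar=10,
        var_superordinate=1.0,
        var_category=1.0,
        var_exemplar=0.5,
        var_noise=1.0,
        seed=11,
    )


@pytest.fixture
def small_ds(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture
def noise_cfg() -> GeneratorConfig:
    """Zero-signal miniature design for null-calibration checks."""
    return GeneratorConfig(
        n_electrodes=4,
        n_time_samples=8,
        n_categories=6,
        n_exemplars_per_category=2,
        n_trials_per_exemplar=10,
        var_superordinate=0.0,
        var_category=0.0,
        var_exemplar=0.0,
        var_noise=1.0,
        seed=7,
    )


@pytest.fixture
def fast_cv() -> CVConfig:
    return CVConfig(k_grid=(3, 6, 12), seed=3)
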