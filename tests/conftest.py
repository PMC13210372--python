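"""Shared fixtures: small synthetic cohorts and default configuration."""

import numpy as np
import pytest

from neopain.concepts import ThresholdTable
from neopain.synthetic_data import SynthConfig, concept_dataset


@pytest.fixture(scope="session")
def table() -> ThresholdTable:
    return ThresholdTable.default()


@pytest.fixture(scope="session")
def small_dataset():
    """30-infant cohort at default noise with detector outputs."""
    return concept_dataset(SynthConfig(n_infants=30, seed=42))


@pytest.fixture(scope="session")
def clean_dataset():
    """15-infant cohort at zero measurement noise."""
    return concept_dataset(SynthConfig(n_infants=15, seed=43, noise_scale=0.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
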