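"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import pytest

from painvol.pipeline import prepare_dataset
from painvol.synthetic_data import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60 users, default regimes and missingness — fast shared cohort."""
    cfg = GeneratorConfig(n_users=60, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    users, records, _states = small_cohort
    return prepare_dataset(users, records, seed=11)


@pytest.fixture(scope="session")
def medium_cohort():
    """400 users with a moderate planted signal, for prediction tests."""
    cfg = GeneratorConfig(n_users=400, seed=5, signal_strength=0.6)
    return generate_cohort(cfg)
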