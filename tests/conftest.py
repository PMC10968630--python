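"""Shared fixtures: small, fast synthetic objects built per test session."""

from __future__ import annotations

import numpy as np
import pytest

from attnmark.pipeline import PipelineConfig, validate_config
from attnmark.synthcohort import CohortSpec, SubjectProfile, make_cohort


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return validate_config({})


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A scaled-down cohort for fast unit tests (2 min resting, 12+12 trials)."""
    return CohortSpec(
        n_subjects=3,
        seed=11,
        duration_resting_s=120.0,
        n_trials_per_condition=12,
    )


@pytest.fixture(scope="session")
def small_profiles(small_spec) -> list[SubjectProfile]:
    return make_cohort(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
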