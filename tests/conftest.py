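"""Shared fixtures: tiny phantoms for unit tests and the session-scoped
desk-scale study (fivefold CV training plus test-set prediction) reused by
the end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from tongueseg import PhantomSpec, generate_phantom
from tongueseg.pipeline import run_desk_experiment, run_group_study

# small, fast phantom settings used across unit tests
TINY_SPEC = PhantomSpec(
    grid_shape=16, spacing_mm=2.0, tongue_semiaxes_mm=(8.0, 6.0, 7.0), seed=0
)
SMALL_SPEC = PhantomSpec(grid_shape=32, spacing_mm=2.0, volume_scale=0.4, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_phantom():
    return generate_phantom(TINY_SPEC)


@pytest.fixture
def small_phantom():
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def desk_result():
    """The scaled-down development study: 20 phantoms at 64^3, 70/30 split,
    fivefold cross-validation, all-variant prediction on the test subjects."""
    return run_desk_experiment(seed=1)


@pytest.fixture(scope="session")
def group_result(desk_result):
    """The application study: 19-vs-19 cohort segmented with the trained
    ensemble from the development study."""
    return run_group_study(desk_result.ensemble, seed=1)
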