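"""Shared fixtures: scaled-down and full-size synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from uroftir.preprocess import preprocess_chain
from uroftir.synthetic import CohortSpec, cohort_to_set, generate_cohort


def small_spec(**overrides) -> CohortSpec:
    """A fast cohort: 40/20 patients on a 2300-1000 cm^-1 grid (1301 pts).

    The grid still covers both planted bands (1773 and 2093 cm^-1); the
    water O-H stretch at 3350 cm^-1 falls off-grid, which only removes an
    inert background feature.
    """
    defaults = dict(n_control=40, n_cancer=20, grid_max=2300.0, grid_min=1000.0)
    defaults.update(overrides)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def small_set():
    return cohort_to_set(generate_cohort(small_spec()))


@pytest.fixture(scope="session")
def small_proc(small_set):
    return preprocess_chain(small_set)


@pytest.fixture(scope="session")
def default_set():
    """The full study-structure cohort (206/103, seed 333)."""
    return cohort_to_set(generate_cohort())


@pytest.fixture(scope="session")
def default_proc(default_set):
    return preprocess_chain(default_set)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
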