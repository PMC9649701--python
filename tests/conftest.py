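"""Shared fixtures: filter parameter sets and canonical structure fixtures."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from lsilearn.structure_filters import FilterParams, default_thresholds
from lsilearn.synthetic import make_blob, make_step_edge, make_t_corner, make_toy_dataset

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> FilterParams:
    """Default filter bank: sigma = rho = sqrt(1.5), P = 64."""
    return FilterParams()


@pytest.fixture(scope="session")
def thresholds(params):
    return default_thresholds(params)


@pytest.fixture(scope="session")
def edge_fixture():
    return make_step_edge()


@pytest.fixture(scope="session")
def corner_fixture():
    return make_t_corner()


@pytest.fixture(scope="session")
def blob_fixture():
    return make_blob()


@pytest.fixture(scope="session")
def toy_dataset():
    return make_toy_dataset(n_classes=5, n_per_class=10, size=48, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
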