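"""Shared fixtures.

The session-scoped fixtures carry the expensive end-to-end benchmark
artefacts (synthetic cohort images and the cross-validated models) so the
acceptance tests that grade classification and explanation recovery share
one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from cfsimage.benchmark import benchmark_images, run_benchmark
from cfsimage.imaging import build_feature_mask, make_grid, project_montage
from cfsimage.montage import default_montage

#: One fixed seed drives every stochastic fixture in the suite.
SUITE_SEED = 1


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def projected(montage):
    return project_montage(montage)


@pytest.fixture(scope="session")
def grid(projected):
    return make_grid(projected)


@pytest.fixture(scope="session")
def feature_mask(projected):
    return build_feature_mask(projected)


@pytest.fixture(scope="session")
def bench_data():
    """Separable synthetic benchmark: 33 + 15 subjects as image sequences."""
    return benchmark_images(SUITE_SEED)


@pytest.fixture(scope="session")
def bench_cv(bench_data):
    """Five-fold cross-validation results (with fitted fold models)."""
    return run_benchmark(seed=SUITE_SEED, data=bench_data)


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)
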