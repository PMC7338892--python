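"""Shared fixtures: small synthetic datasets and their exact solutions."""

import numpy as np
import pytest

import neurocca as nc


@pytest.fixture(scope="session")
def gaussian_ds():
    """The 5+5-dimensional joint-Gaussian benchmark dataset."""
    return nc.make_gaussian(n_x=5, n_y=5, T=10_000, scale_divisor=100.0, seed=1)


@pytest.fixture(scope="session")
def gaussian_oracle(gaussian_ds):
    return nc.solve_cca(gaussian_ds, d=3)


@pytest.fixture(scope="session")
def planted_ds():
    """Gaussian dataset with a dominant, well-separated top canonical pair."""
    return nc.make_planted_gaussian(n_x=5, n_y=5, T=10_000, rhos=(0.9, 0.2), seed=5)


@pytest.fixture(scope="session")
def svdmax():
    """svd-max multiview dataset with its analytic ground truth."""
    return nc.make_svdmax(dims=(4, 5, 6), T=10_000, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
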