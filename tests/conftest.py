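"""Shared fixtures: small seeded regression and CCA problems."""

import logging

import numpy as np
import pytest

from rscca import LTSConfig


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    caplog.set_level(logging.ERROR, logger="rscca")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Cheap LTS search configuration for unit tests."""
    return LTSConfig(n_elemental_subsets=100, n_keep=5, seed=7)


def make_regression(rng, n=40, p=3, beta=None, noise=0.1, n_outliers=0):
    """Linear model data with optional gross response outliers."""
    Z = rng.normal(size=(n, p))
    if beta is None:
        beta = np.zeros(p)
        beta[0] = 1.5
        if p > 1:
            beta[1] = -2.0
    y = Z @ beta + noise * rng.normal(size=n)
    if n_outliers:
        y[:n_outliers] += 25.0
    return Z, y, np.asarray(beta, dtype=float)


@pytest.fixture
def regression(rng):
    return make_regression(rng)
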