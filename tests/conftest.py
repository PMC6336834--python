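import numpy as np
import pytest

import itemselect as its


@pytest.fixture(scope="session")
def fixtures():
    return its.make_fixtures()


@pytest.fixture(scope="session")
def f1(fixtures):
    return fixtures["F1"]


@pytest.fixture(scope="session")
def f2(fixtures):
    return fixtures["F2"]


@pytest.fixture(scope="session")
def small_params():
    return its.item_bank("small")


@pytest.fixture(scope="session")
def small_moments(small_params):
    return its.theoretical_moments(small_params, its.LatentDist())


@pytest.fixture(scope="session")
def all_moments():
    return {
        level: its.theoretical_moments(its.item_bank(level), its.LatentDist())
        for level in its.VARIANCE_LEVELS
    }


@pytest.fixture(scope="session")
def big_sample(small_params):
    """One large (N = 100k) sample from the small-variance bank."""
    return its.generate_scores(small_params, 100_000, 987_654_321)


def random_binary_matrix(rng, n, j):
    """A random 0/1 matrix guaranteed to have no constant column."""
    while True:
        x = (rng.random((n, j)) < rng.uniform(0.2, 0.8, size=j)).astype(int)
        if ((x.sum(axis=0) > 0) & (x.sum(axis=0) < n)).all():
            return x
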