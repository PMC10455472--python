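import numpy as np
import pytest

import egakit as ek


@pytest.fixture(scope="session")
def three_dim_spec():
    return ek.wisc_like_preset("three_dim")


@pytest.fixture(scope="session")
def crossloader_spec():
    return ek.wisc_like_preset("five_dim_with_crossloaders")


@pytest.fixture(scope="session")
def clean_corr(three_dim_spec):
    """Sample correlation matrix from the clean three-cluster preset."""
    return ek.sample_scores(three_dim_spec, 400, 7).correlation()


@pytest.fixture(scope="session")
def clean_boot(clean_corr):
    """A small bootstrap run on the clean preset, shared across tests."""
    return ek.BootEGA(clean_corr).fit(n_boot=40, seed=7)


def random_correlation(rng: np.random.Generator, p: int, n: int = 200) -> np.ndarray:
    """Well-conditioned sample correlation matrix of random Gaussian data."""
    x = rng.standard_normal((n, p)) + 0.5 * rng.standard_normal((n, 1))
    return np.corrcoef(x, rowvar=False)
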