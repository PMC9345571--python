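import numpy as np
import pytest

from msesim.synthetic import FrequencyTable, GeneratorSpec, simulate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_928)


@pytest.fixture
def petersen_table():
    """Two-list table with the classical ratio-estimator closed form."""
    return FrequencyTable(2, {(1, 0): 20, (0, 1): 30, (1, 1): 10})


@pytest.fixture
def mh_sample():
    """One heterogeneous sample at the well-observed design cell."""
    spec = GeneratorSpec("Mh", N=1000, mean_p=0.2, seed=424242)
    return simulate_sample(spec)


def random_table(rng, K=3, lam=8.0):
    """A random frequency table with strictly positive total."""
    while True:
        counts = rng.poisson(lam, size=2**K - 1)
        if counts.sum() > 0:
            return FrequencyTable(K, counts)
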