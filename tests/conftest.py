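import numpy as np
import pytest

from famcall import simulator


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two nuclear families with two children each, mosaic pool, 4x reads."""
    pool = simulator.make_pool(60, 80, seed=11)
    truth = simulator.sample_pedigree(pool, 2, 2, seed=12)
    counts, lik = simulator.simulate_reads(truth, 4.0, 20, seed=13)
    return pool, truth, counts, lik
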