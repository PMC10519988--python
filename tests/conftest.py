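import numpy as np
import pytest

from notchtrunc.synthetic_data import SimConfig, make_gene_model, simulate_counts


@pytest.fixture(scope="session")
def config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def model(config):
    return make_gene_model(config)


@pytest.fixture(scope="session")
def plus_model():
    return make_gene_model(SimConfig(seed=11, strand="+"))


@pytest.fixture(scope="session")
def counts_matrix():
    # small matrix reused across read-only tests
    return simulate_counts(
        SimConfig(
            seed=5,
            cells_per_type={"tumour": 120, "mesangial": 80, "endothelial": 60},
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
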