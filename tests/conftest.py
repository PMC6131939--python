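import numpy as np
import pytest

from magicmap.genmap import CAUSAL_CHROM, CAUSAL_POS, GeneticMap
from magicmap.popsim import simulate_founders


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_map():
    return GeneticMap.default(200)


@pytest.fixture(scope="session")
def panel(default_map):
    return simulate_founders(
        11, default_map.n_sites, default_map, CAUSAL_CHROM, CAUSAL_POS, seed=1
    )
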