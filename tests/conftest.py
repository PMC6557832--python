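import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def masp_gene():
    """Default MaSp-like preset gene, shared across tests (read-only)."""
    from smoc.synthetic import MotifGrammar, make_gene, masp_like_params
    return make_gene(MotifGrammar(), masp_like_params(seed=7))


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))
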