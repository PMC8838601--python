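import pytest

from hrqol_miner.lexicons import bundled_lexicons
from hrqol_miner.synthetic import GeneratorSpec, bundled_dictionary, generate_corpus


@pytest.fixture(scope="session")
def lexset():
    return bundled_lexicons()


@pytest.fixture(scope="session")
def termdict():
    return bundled_dictionary()


@pytest.fixture(scope="session")
def small_synth(lexset, termdict):
    """A small noiseless synthetic corpus with known planted ground truth."""
    return generate_corpus(GeneratorSpec(n=120, noise=0.0, seed=13), lexset, termdict)
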