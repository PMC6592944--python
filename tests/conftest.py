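import numpy as np
import pytest

from rwov import SyntheticConfig, generate_corpus, normalize_corpus


@pytest.fixture(scope="session")
def small_reports():
    """A small labelled synthetic corpus shared across tests."""
    return generate_corpus(SyntheticConfig(n=80, seed=31))


@pytest.fixture(scope="session")
def small_sequences(small_reports):
    return normalize_corpus(small_reports)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
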