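import pytest

from mechsim import GeneratorConfig, make_fig1_step, make_glycosidase_pair, random_corpus


@pytest.fixture(scope="session")
def pair():
    return make_glycosidase_pair()


@pytest.fixture(scope="session")
def fig1_step():
    return make_fig1_step()


@pytest.fixture(scope="session")
def small_corpus():
    """A modest seeded corpus reused across tests."""
    return random_corpus(10, GeneratorConfig(seed=42))
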