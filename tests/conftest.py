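import numpy as np
import pytest

from priormap import synth


@pytest.fixture(scope="session")
def fixture_data():
    """Default synthetic prioritization inputs (seed 1), shared across tests."""
    return synth.generate_prioritization_fixture(synth.FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def toy_graphs():
    return synth.generate_toy_graphs()


@pytest.fixture(scope="session")
def rating_fixture():
    return synth.generate_rating_fixture(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
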