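import numpy as np
import pytest

from fusionstats import EggModel, build_null_distribution


@pytest.fixture(scope="session")
def egg():
    """The reference egg: radius 36.6 µm, chromosomes 5 µm below the membrane."""
    return EggModel()


@pytest.fixture(scope="session")
def null40k(egg):
    """One 40,000-point simulated uniform null, shared across tests."""
    return build_null_distribution(egg, n=40_000, seed=20210823)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
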