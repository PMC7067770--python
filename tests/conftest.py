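import numpy as np
import pytest

from myotomo.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A quick-to-generate phantom spec used across tests."""
    return PhantomSpec(shape=(16, 64, 64), n_fibers=12, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
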