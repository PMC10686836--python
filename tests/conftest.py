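import numpy as np
import pytest

from swarmspec.basis import build_inner_product, gram_schmidt_basis


@pytest.fixture(scope="session")
def inner():
    return build_inner_product(T=2.0, n_nodes=(64, 64))


@pytest.fixture(scope="session")
def basis6(inner):
    return gram_schmidt_basis(inner, M=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
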