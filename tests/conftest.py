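import numpy as np
import pytest

from conjgrid import network1d as n1


@pytest.fixture(scope="session")
def small_manifold():
    """12-unit manifold for brute-force weight checks."""
    return n1.build_manifold_1d(4, 3, 1.0)


@pytest.fixture(scope="session")
def test_manifold():
    """20 x 5 manifold used by the low-rank/dense equivalence checks."""
    return n1.build_manifold_1d(20, 5, 0.5)


@pytest.fixture(scope="session")
def default_wp():
    return n1.WeightParams1D()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
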