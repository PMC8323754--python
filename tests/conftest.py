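import numpy as np
import pytest

from neuromodes.domain import SpatialDomain


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def unit_domain():
    """10-point domain with unit area weights (plain matrix algebra)."""
    return SpatialDomain.uniform(10, total_area=10.0)


def random_symmetric_ec(K, spectral_radius, rng):
    """Symmetric raw EC kernel scaled to the requested spectral radius."""
    A = rng.standard_normal((K, K))
    A = 0.5 * (A + A.T)
    A *= spectral_radius / np.abs(np.linalg.eigvals(A)).max()
    return A
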