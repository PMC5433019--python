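import pytest

from iacflow import (BoundaryConditions, NetworkVariantConfig,
                     generate_network)


@pytest.fixture(scope="session")
def network_a():
    """Case-A-like geometry: no PAA or MMA, ~2 mm lingual artery."""
    return generate_network(NetworkVariantConfig(
        case="A", include_PAA=False, include_MMA=False, seed=0))


@pytest.fixture(scope="session")
def network_b():
    """Case-B-like geometry: full branch set, ~3 mm lingual artery."""
    return generate_network(NetworkVariantConfig(case="B", seed=1))


@pytest.fixture(scope="session")
def boundary_a():
    return BoundaryConditions(cca_mean_velocity=0.38)


@pytest.fixture(scope="session")
def boundary_b():
    return BoundaryConditions(cca_mean_velocity=0.43)
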