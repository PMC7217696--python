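import numpy as np
import pytest

from crosnet import (
    ConnectivityParams,
    GridSpec,
    SynapticWeights,
    build_connections,
)


@pytest.fixture(scope="session")
def small_spec():
    """10x10 grid: cheap but large enough for interior neighbourhoods."""
    return GridSpec(side_length=10, seed=7)


@pytest.fixture(scope="session")
def small_network(small_spec):
    return build_connections(
        small_spec, ConnectivityParams(CE=60.0, CI=75.0), SynapticWeights(), seed=7
    )


@pytest.fixture(scope="session")
def default_network():
    """Full-size 50x50 network at the critical-line connectivity."""
    return build_connections(
        GridSpec(seed=11), ConnectivityParams(CE=60.0, CI=75.0),
        SynapticWeights(), seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
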