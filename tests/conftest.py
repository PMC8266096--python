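import numpy as np
import pytest

from angiosim import (Parameters, build_hex_domain, generate_tissue_grid,
                      make_initial_network)


@pytest.fixture(scope="session")
def params():
    return Parameters()


@pytest.fixture(scope="session")
def domain():
    return build_hex_domain(150.0, 500.0)


@pytest.fixture(scope="session")
def reference_grid(domain):
    return generate_tissue_grid(domain, 20.0)


@pytest.fixture()
def initial_network(params):
    return make_initial_network(params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
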