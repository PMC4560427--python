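import numpy as np
import pytest

from fluxadapt import (
    MetabolicNetwork,
    load_ecoli_core,
    make_random_network,
    make_toy_network,
)


@pytest.fixture
def toy():
    return make_toy_network()


@pytest.fixture
def toy_branched():
    return make_toy_network(branched=True)


@pytest.fixture
def degenerate_net():
    """Two routes to biomass with different lengths: the FBA optimum is a
    whole face (any split between the routes), but only the short route
    minimises total flux, so pFBA resolves the degeneracy uniquely."""
    return MetabolicNetwork(
        reaction_ids=("UPT", "DIRECT", "LONG1", "LONG2"),
        metabolite_ids=("A", "B"),
        S=np.array([
            [1.0, -1.0, -1.0, 0.0],
            [0.0, 0.0, 1.0, -1.0],
        ]),
        lower_bounds=np.zeros(4),
        upper_bounds=np.array([10.0, 10.0, 10.0, 10.0]),
        biomass_coeffs=np.array([0.0, 1.0, 0.0, 1.0]),
    )


@pytest.fixture(params=[3, 4, 5])
def random_net(request):
    return make_random_network(n_reactions=5, seed=request.param)


@pytest.fixture(scope="session")
def ecoli_core():
    return load_ecoli_core()
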