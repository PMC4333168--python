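import numpy as np
import pytest

import biomediv as bd


@pytest.fixture(scope="session")
def cherry():
    return bd.parse_newick("(A:1.0,B:1.0);")


@pytest.fixture(scope="session")
def three_tip():
    return bd.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def balanced_rates():
    return bd.GeoSSEParams(sA=0.3, sB=0.25, sAB=0.1, xA=0.1, xB=0.1,
                           dA=0.2, dB=0.2)


def random_geosse_instance(seed, n_lo=4, n_hi=8, rate_hi=0.5, random_rho=True):
    """A small simulated tree with states plus random rates and sampling."""
    rng = np.random.default_rng(seed)
    sim = bd.GeoSSEParams(0.3, 0.25, 0.1, 0.1, 0.1, 0.2, 0.2)
    tree, states = bd.sim_geosse_tree(bd.SimConfig(
        seed=seed, n_taxa=int(rng.integers(n_lo, n_hi + 1)),
        geosse_params=sim, root_state=0))
    rates = rng.uniform(0.0, rate_hi, 7)
    rho = tuple(rng.uniform(0.5, 1.0, 3)) if random_rho else (1.0, 1.0, 1.0)
    return tree, states, rates, rho
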