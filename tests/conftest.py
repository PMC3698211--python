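import numpy as np
import pytest

from bistacert.network_model import (
    GAL_EQUILIBRIUM_HIGH,
    GAL_EQUILIBRIUM_LOW,
    MultistartSpec,
    find_equilibria,
    gal_model,
    newton_refine,
    toy_models,
)


@pytest.fixture(scope="session")
def gal():
    """(network, nominal parameter vector) for the packaged GAL model."""
    return gal_model()


@pytest.fixture(scope="session")
def gal_equilibria(gal):
    """The three GAL equilibria (low stable, saddle, high stable), found by
    a seeded multistart search."""
    net, p = gal
    spec = MultistartSpec(
        n_random=300, seed=11,
        guesses=[GAL_EQUILIBRIUM_LOW, GAL_EQUILIBRIUM_HIGH],
    )
    eqs = find_equilibria(net, p, spec)
    assert len(eqs) == 3
    return eqs


@pytest.fixture(scope="session")
def gal_xe(gal):
    """Newton-polished (low, high) stable states."""
    net, p = gal
    x1 = newton_refine(net, p, GAL_EQUILIBRIUM_LOW)[0]
    x2 = newton_refine(net, p, GAL_EQUILIBRIUM_HIGH)[0]
    return x1, x2


@pytest.fixture(scope="session")
def toys():
    return toy_models()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
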