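import numpy as np
import pytest

import brcnet as b


@pytest.fixture(scope="session")
def toy():
    """The 7-node synthetic toy walkthrough model (A..G, node 0 = A)."""
    return b.load_model("toy_synthetic").network


@pytest.fixture(scope="session")
def toy_beta(toy):
    att, transient = b.find_attractor(toy, b.string_to_state("1011110"))
    assert transient == 0
    return att


@pytest.fixture(scope="session")
def toy_basin(toy, toy_beta):
    return b.basin_of_attractor(toy, toy_beta)


def make_net(seed: int, n: int = 10, **kw) -> b.BooleanNetwork:
    kw.setdefault("k_max", 3)
    kw.setdefault("p_deterministic", 0.4)
    kw.setdefault("n_peelable", 2)
    return b.random_boolean_network(b.GeneratorSpec(n=n, seed=seed, **kw))


def brute_force_basins(net):
    """Exhaustive forward classification: (attractors, per-state index)."""
    return b.enumerate_attractors_exhaustive(net)
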