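import numpy as np
import pytest

import fptcme as f


def assembled(bundle):
    """Network + enumerated space + CME generator for a model bundle."""
    space = f.enumerate_states(bundle.network)
    A = f.build_transition_matrix(bundle.network, space)
    return bundle.network, space, A


@pytest.fixture(scope="session")
def bd2():
    """Simple birth-death, K=2, with its generator (3-state oracle model)."""
    return assembled(f.simple_bd(K=2.0))


@pytest.fixture(scope="session")
def tiny_bd():
    """Birth-death truncated to {0, 1, 2} with symbolic-checkable entries."""
    K = 3.0
    net = f.ReactionNetwork(
        [f.SpeciesSpec("P", 0, 2)],
        [
            f.Reaction([0], [1], K, label="birth"),
            f.Reaction([1], [0], 1.0, label="death"),
        ],
        name="tiny_bd",
    )
    return K, net


@pytest.fixture(scope="session")
def pure_birth():
    """Pure birth at rate K on {0, 1}: single-exponential FPT to 1."""
    K = 4.0
    net = f.ReactionNetwork(
        [f.SpeciesSpec("P", 0, 1)],
        [f.Reaction([0], [1], K, label="birth")],
        name="pure_birth",
    )
    space = f.enumerate_states(net)
    A = f.build_transition_matrix(net, space)
    return K, net, space, A
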