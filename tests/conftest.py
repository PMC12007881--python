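"""Shared fixtures: tiny networks and an independent lac operon rule oracle."""

import numpy as np
import pytest

from boolnoise import parse_network
from boolnoise.fixtures import lac_operon_network

#: master seed for every seeded test in the suite
SEED = 1234


# Hand-coded re-statement of the packaged lac operon rules as plain Python,
# written against the model source independently of the parser/evaluator.
LAC_ORACLE = {
    "M": lambda s: s["C"] and not s["R"] and not s["Rm"],
    "P": lambda s: s["M"],
    "B": lambda s: s["M"],
    "C": lambda s: not s["Ge"],
    "R": lambda s: not s["A"] and not s["Am"],
    "Rm": lambda s: (not s["A"] and not s["Am"]) or s["R"],
    "A": lambda s: s["L"] and s["B"],
    "Am": lambda s: s["A"] or s["L"] or s["Lm"],
    "L": lambda s: s["P"] and s["Le"] and not s["Ge"],
    "Lm": lambda s: ((s["Lem"] and s["P"]) or s["Le"]) and not s["Ge"],
    "Ge": lambda s: s["Ge"],
    "Le": lambda s: s["Le"],
    "Lem": lambda s: s["Lem"],
}


def lac_oracle_step(network, state):
    """Deterministic synchronous successor via the hand-coded rules."""
    named = {name: bool(state[network.index[name]]) for name in network.nodes}
    return np.array([int(LAC_ORACLE[name](named)) for name in network.nodes])


@pytest.fixture(scope="session")
def lac():
    return lac_operon_network()


@pytest.fixture()
def negation_loop():
    """Two-node loop: A copies B, B negates A."""
    return parse_network("targets, factors\nA, B\nB, !A")


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
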