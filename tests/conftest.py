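import pytest

from cardiobool.logic import BooleanNetwork, parse_expression
from cardiobool.models import load_model


def make_net(rules: dict[str, str], clamps: dict[str, int] | None = None) -> BooleanNetwork:
    """Build a network from {node: rule-string} in insertion order."""
    nodes = list(rules)
    functions = {n: parse_expression(r, nodes) for n, r in rules.items()}
    return BooleanNetwork(nodes, functions, clamps)


@pytest.fixture(scope="session")
def cm_model():
    return load_model("cm_subtype")


@pytest.fixture(scope="session")
def hf_model():
    return load_model("heart_field")


@pytest.fixture(scope="session")
def unified_model():
    return load_model("unified")


@pytest.fixture
def swap_net():
    """Two-node swap: x' = y, y' = x."""
    return make_net({"X": "Y", "Y": "X"})


@pytest.fixture
def negation_net():
    """One-node oscillator: x' = !x (a two-state cyclic attractor)."""
    return make_net({"X": "!X"})


@pytest.fixture
def or_absorb_net():
    """a' = a | b, b' = 0: two absorbing states, (0,0) and (1,0)."""
    return make_net({"A": "A | B", "B": "0"})
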