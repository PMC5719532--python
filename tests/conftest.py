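import pytest

from logicbackbone import build_causal_graph, fixture, generate_rbn, RBNSpec


@pytest.fixture(scope="session")
def mediator_demo():
    """Four real nodes, one mediator; B is the signal, D the output."""
    return fixture("mediator_demo")


@pytest.fixture(scope="session")
def chain_demo():
    return fixture("chain_demo")


@pytest.fixture(scope="session")
def motif_demo():
    return fixture("motif_demo")


@pytest.fixture(scope="session")
def example_a():
    return fixture("example_a")


def rbn_graph(seed, n=12, k_in=1.5):
    rules = generate_rbn(RBNSpec(n=n, k_in=k_in, seed=seed))
    return rules, build_causal_graph(rules)
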