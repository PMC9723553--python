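import pytest

from mixs_sa import build_graph, fig1a_study, fig1b_study, load_registry
from mixs_sa.relgraph import RelationshipEdge


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture()
def fig1a_table():
    return fig1a_study()


@pytest.fixture()
def fig1b_table():
    return fig1b_study()


@pytest.fixture()
def fig1a_graph(fig1a_table):
    return build_graph(fig1a_table)


@pytest.fixture()
def fig1b_graph(fig1b_table):
    return build_graph(fig1b_table)


def edge(subject, predicate, object):
    return RelationshipEdge(subject=subject, predicate=predicate, object=object)


# The published trematode design declares: S1 within H1, S2 within E2,
# S3 within H2, S4 within H3, H1 next to E1, H1 within E2, H2 within E2,
# H3 within E2, E1 next to E2. Canonical form orients symmetric edges with
# the lexicographically smaller endpoint first.
FIG1A_CANONICAL_EDGES = frozenset(
    {
        edge("S1", "within", "H1"),
        edge("S2", "within", "E2"),
        edge("S3", "within", "H2"),
        edge("S4", "within", "H3"),
        edge("E1", "next_to", "H1"),
        edge("H1", "within", "E2"),
        edge("H2", "within", "E2"),
        edge("H3", "within", "E2"),
        edge("E1", "next_to", "E2"),
    }
)

# The parasitic-plant design declares: S6 within P1, S5 next to S6,
# P1 next to P2, P1 next to P3, P2 next to P3, P1 within E3, P3 within E4,
# E3 next to E4.
FIG1B_CANONICAL_EDGES = frozenset(
    {
        edge("S6", "within", "P1"),
        edge("S5", "next_to", "S6"),
        edge("P1", "next_to", "P2"),
        edge("P1", "next_to", "P3"),
        edge("P2", "next_to", "P3"),
        edge("P1", "within", "E3"),
        edge("P3", "within", "E4"),
        edge("E3", "next_to", "E4"),
    }
)
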