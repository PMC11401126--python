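import networkx as nx
import pytest


def graph_from(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for e in edges:
        if len(e) == 3:
            g.add_edge(e[0], e[1], weight=e[2])
        else:
            g.add_edge(e[0], e[1], weight=1.0)
    return g


def net_from_synthetic(edge_triples):
    return graph_from(edge_triples)


@pytest.fixture
def k5():
    return nx.relabel_nodes(nx.complete_graph(5), {i: f"N{i}" for i in range(5)})


@pytest.fixture
def path_abc():
    return graph_from([("A", "B"), ("B", "C")])


@pytest.fixture
def star4():
    """Centre C with leaves L1..L3."""
    return graph_from([("C", "L1"), ("C", "L2"), ("C", "L3")])
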