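import itertools
import random
from collections import Counter

import networkx as nx
import pytest

import motifkey as mk


def random_digraph(n: int, p: float, rng: random.Random) -> mk.DirectedGraph:
    """Erdos-Renyi style random simple digraph over labelled gene nodes."""
    g = mk.DirectedGraph(nodes=[f"n{i:02d}" for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.add_edge(f"n{i:02d}", f"n{j:02d}")
    return g


def brute_force_census(graph: mk.DirectedGraph, k: int):
    """Independent oracle: test every C(n, k) node subset for weak
    connectivity and classify via networkx, without touching ESU."""
    counts: Counter = Counter()
    n_instances = 0
    for sub in itertools.combinations(sorted(graph.nodes), k):
        adj = graph.induced_adjacency(sub)
        g = nx.DiGraph()
        g.add_nodes_from(range(k))
        g.add_edges_from(
            (i, j) for i in range(k) for j in range(k) if adj[i, j]
        )
        if nx.is_weakly_connected(g):
            counts[mk.encode_motif_id(adj)] += 1
            n_instances += 1
    return counts, n_instances


@pytest.fixture
def three_cycle():
    g = mk.DirectedGraph()
    g.add_edge("a", "b")
    g.add_edge("b", "c")
    g.add_edge("c", "a")
    return g


@pytest.fixture
def four_star():
    """Hub gene regulating three targets (single input module)."""
    g = mk.DirectedGraph()
    for leaf in ("t1", "t2", "t3"):
        g.add_edge("hub", leaf)
    return g
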