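import itertools
import random

import networkx as nx
import numpy as np
import pytest

import motifkey as mk
from motifkey.graph_model import GraphModelError, ParseError

from conftest import random_digraph


class TestDirectedGraph:
    def test_rejects_self_loops_and_tracks_types(self):
        g = mk.DirectedGraph()
        g.add_edge("a", "b", "activation")
        assert g.edge_type("a", "b") == "activation"
        with pytest.raises(GraphModelError):
            g.add_edge("a", "a")
        with pytest.raises(GraphModelError):
            g.add_edge("a", "b", "frobnication")

    def test_binding_stored_as_antiparallel_pair(self):
        g = mk.DirectedGraph()
        g.add_edge("a", "b", "binding")
        assert g.edges == {("a", "b"), ("b", "a")}


class TestParseEdgeList:
    def test_two_column_transcription(self):
        g = mk.parse_edge_list("a\tb\nb\tc\n")
        assert g.nodes == {"a", "b", "c"}
        assert g.edges == {("a", "b"), ("b", "c")}

    def test_sif_self_loop_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="motifkey"):
            g = mk.parse_edge_list("a\tactivation\ta\nb\tactivation\tc\n", "sif")
        assert g.edges == {("b", "c")}
        assert any("self-loop" in rec.message for rec in caplog.records)

    def test_duplicate_lines_collapse(self):
        g = mk.parse_edge_list("a\tb\na\tb\nb\tc\n")
        assert len(g.edges) == 2

    @pytest.mark.parametrize(
        "text", ["", "# only a comment\n", "a\tb\tc\n", "a\n", "a\tweird\tb\n"]
    )
    def test_malformed_or_empty_input_raises(self, text):
        dialect = "sif" if text.count("\t") == 2 else "two-column"
        with pytest.raises(ParseError):
            mk.parse_edge_list(text, dialect)

    def test_round_trip_through_writer(self):
        g = mk.parse_edge_list("a\tactivation\tb\nb\tinhibition\tc\n", "sif")
        again = mk.parse_edge_list(mk.write_edge_list(g, "sif"), "sif")
        assert again == g


class TestMotifIDCodec:
    def test_decode_row_major_chain(self):
        # published 4-node identifier '4a': rows 0010 / 0001 / 1000 pattern
        adj = mk.decode_motif_id("0000001000011000")
        edges = {(i, j) for i in range(4) for j in range(4) if adj[i, j]}
        assert edges == {(1, 2), (2, 3), (3, 0)}

    def test_decode_single_source_fan(self):
        adj = mk.decode_motif_id("0000000000001110")
        edges = {(i, j) for i in range(4) for j in range(4) if adj[i, j]}
        assert edges == {(3, 0), (3, 1), (3, 2)}

    @pytest.mark.parametrize(
        "bits",
        [
            "0000",  # k=2: below minimum size and disconnected
            "000000100",  # self-loop on the diagonal
            "000000000",  # k=3 edgeless: disconnected
            "00000",  # not a perfect square
            "000011000110000001000011100100110",  # not a perfect square
        ],
    )
    def test_invalid_identifiers_rejected(self, bits):
        with pytest.raises(GraphModelError):
            mk.decode_motif_id(bits)

    def test_encode_decode_round_trip_is_isomorphic(self):
        rng = random.Random(11)
        for _ in range(25):
            g = random_digraph(4, 0.5, rng)
            sub = tuple(sorted(g.nodes))
            adj = g.induced_adjacency(sub)
            if not nx.is_connected(nx.from_numpy_array(
                    np.maximum(adj, adj.T), create_using=nx.Graph)):
                continue
            motif = mk.encode_motif_id(adj)
            back = motif.adjacency()
            a = nx.from_numpy_array(adj, create_using=nx.DiGraph)
            b = nx.from_numpy_array(back, create_using=nx.DiGraph)
            assert nx.is_isomorphic(a, b)

    def test_isomorphic_fans_share_one_id(self):
        a = np.zeros((3, 3), dtype=int)
        a[0, 1] = a[0, 2] = 1  # edges from node 1
        b = np.zeros((3, 3), dtype=int)
        b[1, 0] = b[1, 2] = 1  # same fan rooted at node 2
        assert mk.encode_motif_id(a) == mk.encode_motif_id(b)

    def test_chain_has_one_id_under_all_node_orders(self):
        ids = set()
        for perm in itertools.permutations(range(3)):
            adj = np.zeros((3, 3), dtype=int)
            adj[perm[0], perm[1]] = adj[perm[1], perm[2]] = 1
            ids.add(mk.encode_motif_id(adj))
        assert len(ids) == 1


class TestCanonicalForm:
    def test_idempotent(self):
        bits = "0000001000011000"
        canon = mk.canonical_form(bits)
        assert mk.canonical_form(canon) == canon

    def test_permutation_invariance_k3_exhaustive(self):
        """All connected 3-node digraphs: canonical form constant within an
        isomorphism class and distinct across classes (networkx oracle)."""
        by_canon = {}
        for mask in range(64):
            adj = np.zeros((3, 3), dtype=int)
            positions = [(i, j) for i in range(3) for j in range(3) if i != j]
            for b, (i, j) in enumerate(positions):
                adj[i, j] = (mask >> b) & 1
            g = nx.from_numpy_array(adj, create_using=nx.DiGraph)
            if not nx.is_connected(nx.Graph(g)):
                continue
            canon = mk.encode_motif_id(adj).bits
            by_canon.setdefault(canon, []).append(g)
        # 13 connected 3-node digraph isomorphism classes exist
        assert len(by_canon) == 13
        reps = list(by_canon.items())
        for (c1, gs1), (c2, gs2) in itertools.combinations(reps, 2):
            assert not nx.is_isomorphic(gs1[0], gs2[0])
        for _, gs in reps:
            for a, b in itertools.combinations(gs, 2):
                assert nx.is_isomorphic(a, b)

    @pytest.mark.parametrize("k", [4, 5, 6])
    def test_random_permutation_pairs_agree(self, k):
        rng = random.Random(100 + k)
        trials = 0
        while trials < 20:
            adj = np.zeros((k, k), dtype=int)
            for i in range(k):
                for j in range(k):
                    if i != j and rng.random() < 0.4:
                        adj[i, j] = 1
            if not nx.is_connected(
                nx.from_numpy_array(np.maximum(adj, adj.T), create_using=nx.Graph)
            ):
                continue
            trials += 1
            perm = list(range(k))
            rng.shuffle(perm)
            permuted = adj[np.ix_(perm, perm)]
            assert mk.encode_motif_id(adj) == mk.encode_motif_id(permuted)

    def test_chain_and_feedforward_distinct(self):
        chain = np.zeros((3, 3), dtype=int)
        chain[0, 1] = chain[1, 2] = 1
        ffl = chain.copy()
        ffl[0, 2] = 1
        assert mk.encode_motif_id(chain) != mk.encode_motif_id(ffl)


class TestNamedMotifs:
    @pytest.mark.parametrize(
        "motif, expected",
        [
            (mk.MotifID.from_bits("0000000000001110"), "SIM"),
            (mk.bifan_motif(), "bifan"),
            (mk.chain_motif(4), "chain"),
            (mk.chain_motif(3), "chain"),
            (mk.sim_motif(5), "SIM"),
        ],
    )
    def test_archetypes(self, motif, expected):
        assert mk.classify_named_motif(motif) == expected

    def test_mim_is_mirrored_sim(self):
        adj = mk.sim_motif(4).adjacency().T
        assert mk.classify_named_motif(mk.encode_motif_id(adj)) == "MIM"

    def test_biparallel_and_diamond(self):
        bp = np.zeros((4, 4), dtype=int)
        bp[0, 1] = bp[0, 2] = bp[1, 3] = bp[2, 3] = 1
        assert mk.classify_named_motif(mk.encode_motif_id(bp)) == "biparallel"
        dm = bp.copy()
        dm[0, 3] = 1
        assert mk.classify_named_motif(mk.encode_motif_id(dm)) == "diamond"

    def test_dense_class_is_unnamed(self):
        adj = np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)
        assert mk.classify_named_motif(mk.encode_motif_id(adj)) == "unnamed"


def test_reference_table_identifiers_all_valid():
    """Every packaged reference bitstring parses as a weakly connected motif
    of the size implied by its label group (4-8)."""
    df = mk.load_reference_table()
    for row in df.itertuples(index=False):
        motif = mk.MotifID.from_bits(row.motif_id)
        assert motif.k == int(row.label[0])
        motif.canonical()  # must not raise
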