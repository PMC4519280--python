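"""Directed pathway-graph data model and canonical motif identifiers.

A pathway is represented as a simple directed graph over gene labels, with
an optional interaction type on every edge (activation, inhibition, ...).
Small connected subgraph classes ("network motifs") are identified by a
canonical bitstring: the row-major adjacency matrix of a canonical
representative of the isomorphism class, written as a string of ``k*k``
characters over ``{0, 1}``, where character ``i*k + j`` is ``'1'`` iff the
motif has the directed edge ``i -> j``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional

import networkx as nx
import numpy as np

logger = logging.getLogger("motifkey")

#: Interaction vocabulary accepted in SIF input. ``binding`` is undirected
#: and is stored as two antiparallel directed edges.
EDGE_TYPES = frozenset(
    {"activation", "inhibition", "expression", "phosphorylation", "binding", "unknown"}
)
UNDIRECTED_TYPES = frozenset({"binding"})

MIN_MOTIF_SIZE = 3
MAX_MOTIF_SIZE = 8


class GraphModelError(ValueError):
    """Invalid graph, motif identifier or input file."""


class ParseError(GraphModelError):
    """Malformed edge-list input; carries the offending line number."""


# ---------------------------------------------------------------------------
# DirectedGraph
# ---------------------------------------------------------------------------

class DirectedGraph:
    """A simple directed graph over gene labels.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is a
    node. Backed by :class:`networkx.DiGraph`; use :meth:`to_networkx` for
    interoperability.
    """

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple] = (),
        edge_types: Optional[dict] = None,
    ) -> None:
        self._g = nx.DiGraph()
        for n in nodes:
            self.add_node(n)
        edge_types = edge_types or {}
        for e in edges:
            u, v = e
            self.add_edge(u, v, edge_types.get((u, v), "unknown"))

    # -- construction -------------------------------------------------------

    def add_node(self, label: str) -> None:
        if not isinstance(label, str) or not label:
            raise GraphModelError(f"node labels must be non-empty strings, got {label!r}")
        self._g.add_node(label)

    def add_edge(self, source: str, target: str, edge_type: str = "unknown") -> None:
        if source == target:
            raise GraphModelError(f"self-loop {source!r} -> {target!r} not allowed")
        if edge_type not in EDGE_TYPES:
            raise GraphModelError(f"unknown edge type {edge_type!r}")
        self.add_node(source)
        self.add_node(target)
        self._g.add_edge(source, target, edge_type=edge_type)
        if edge_type in UNDIRECTED_TYPES:
            self._g.add_edge(target, source, edge_type=edge_type)

    # -- views --------------------------------------------------------------

    @property
    def nodes(self) -> set:
        return set(self._g.nodes)

    @property
    def edges(self) -> set:
        return set(self._g.edges)

    def edge_type(self, source: str, target: str) -> str:
        return self._g.edges[source, target]["edge_type"]

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_edge(self, source: str, target: str) -> bool:
        return self._g.has_edge(source, target)

    def successors(self, node: str) -> set:
        return set(self._g.successors(node))

    def predecessors(self, node: str) -> set:
        return set(self._g.predecessors(node))

    def neighbors(self, node: str) -> set:
        """Undirected-skeleton neighbourhood (union of in- and out-)."""
        return set(self._g.successors(node)) | set(self._g.predecessors(node))

    def in_degree(self, node: str) -> int:
        return self._g.in_degree(node)

    def out_degree(self, node: str) -> int:
        return self._g.out_degree(node)

    def degree_sequences(self) -> dict:
        """Per-node (in, out) degrees, the quantity null models must preserve."""
        return {n: (self._g.in_degree(n), self._g.out_degree(n)) for n in self._g.nodes}

    def copy(self) -> "DirectedGraph":
        new = DirectedGraph()
        new._g = self._g.copy()
        return new

    def to_networkx(self) -> nx.DiGraph:
        return self._g.copy()

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "DirectedGraph":
        new = cls()
        for n in g.nodes:
            new.add_node(str(n))
        for u, v, data in g.edges(data=True):
            new.add_edge(str(u), str(v), data.get("edge_type", "unknown"))
        return new

    def induced_adjacency(self, members: tuple) -> np.ndarray:
        """Adjacency matrix of the induced subgraph, rows in ``members`` order."""
        k = len(members)
        adj = np.zeros((k, k), dtype=np.uint8)
        for i, u in enumerate(members):
            for j, v in enumerate(members):
                if i != j and self._g.has_edge(u, v):
                    adj[i, j] = 1
        return adj

    def __eq__(self, other) -> bool:
        if not isinstance(other, DirectedGraph):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"DirectedGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


# ---------------------------------------------------------------------------
# Edge-list parsing / writing
# ---------------------------------------------------------------------------

def parse_edge_list(text: str, dialect: str = "two-column") -> DirectedGraph:
    """Parse a tab-separated edge list into a :class:`DirectedGraph`.

    ``dialect`` is ``"two-column"`` (source<TAB>target) or ``"sif"``
    (source<TAB>interaction<TAB>target). Lines starting with ``#`` and blank
    lines are skipped. Duplicate edges collapse silently; self-loop records
    are dropped with a logged warning reporting how many were discarded.
    """
    if dialect not in {"two-column", "sif"}:
        raise GraphModelError(f"unknown dialect {dialect!r}")
    graph = DirectedGraph()
    n_fields = 2 if dialect == "two-column" else 3
    dropped = 0
    seen_any = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip("\n\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != n_fields or any(not f.strip() for f in fields):
            raise ParseError(
                f"line {lineno}: expected {n_fields} tab-separated fields, got {len(fields)}"
            )
        seen_any = True
        if dialect == "two-column":
            source, target = fields[0].strip(), fields[1].strip()
            etype = "unknown"
        else:
            source, etype, target = (f.strip() for f in fields)
            if etype not in EDGE_TYPES:
                raise ParseError(f"line {lineno}: unknown interaction type {etype!r}")
        if source == target:
            dropped += 1
            continue
        graph.add_edge(source, target, etype)
    if not seen_any:
        raise ParseError("empty input: no edge records found")
    if dropped:
        logger.warning("dropped %d self-loop record(s) while parsing edge list", dropped)
    return graph


def write_edge_list(graph: DirectedGraph, dialect: str = "two-column") -> str:
    """Serialize a graph back to the formats :func:`parse_edge_list` reads."""
    lines = []
    for u, v in sorted(graph.edges):
        if dialect == "two-column":
            lines.append(f"{u}\t{v}")
        elif dialect == "sif":
            lines.append(f"{u}\t{graph.edge_type(u, v)}\t{v}")
        else:
            raise GraphModelError(f"unknown dialect {dialect!r}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Motif identifiers
# ---------------------------------------------------------------------------

def _bits_to_tuples(bits: str) -> tuple:
    k = math.isqrt(len(bits))
    if k * k != len(bits):
        raise GraphModelError(f"bitstring length {len(bits)} is not a perfect square")
    if not set(bits) <= {"0", "1"}:
        raise GraphModelError("bitstring must contain only '0' and '1'")
    return tuple(tuple(int(bits[i * k + j]) for j in range(k)) for i in range(k))


def _weakly_connected(adj) -> bool:
    k = len(adj)
    if k == 0:
        return False
    seen = {0}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in range(k):
            if j not in seen and (adj[i][j] or adj[j][i]):
                seen.add(j)
                stack.append(j)
    return len(seen) == k


def decode_motif_id(bits: str) -> np.ndarray:
    """Decode a motif bitstring into its ``k x k`` 0/1 adjacency matrix.

    Raises :class:`GraphModelError` for a non-square length, a size outside
    [3, 8], a nonzero diagonal, or a weakly disconnected graph.
    """
    adj = _bits_to_tuples(bits)
    k = len(adj)
    if not (MIN_MOTIF_SIZE <= k <= MAX_MOTIF_SIZE):
        raise GraphModelError(f"motif size {k} outside [{MIN_MOTIF_SIZE}, {MAX_MOTIF_SIZE}]")
    if any(adj[i][i] for i in range(k)):
        raise GraphModelError("motif adjacency has a nonzero diagonal (self-loop)")
    if not _weakly_connected(adj):
        raise GraphModelError("motif adjacency is not weakly connected")
    return np.array(adj, dtype=np.uint8)


@lru_cache(maxsize=1 << 18)
def _canonical_form_cached(bits: str) -> tuple:
    adj = _bits_to_tuples(bits)
    k = len(adj)
    best = None
    best_perm = None
    for perm in itertools.permutations(range(k)):
        cand = "".join(
            "1" if adj[perm[i]][perm[j]] else "0" for i in range(k) for j in range(k)
        )
        if best is None or cand < best:
            best = cand
            best_perm = perm
    return best, best_perm


def canonical_form(bits: str) -> str:
    """Lexicographically smallest bitstring over all simultaneous row/column
    permutations — the canonical representative of the isomorphism class."""
    decode_motif_id(bits)  # validate
    return _canonical_form_cached(bits)[0]


def canonical_form_with_perm(bits: str) -> tuple:
    """Canonical bits plus the permutation ``perm`` such that canonical row
    ``r`` corresponds to original row ``perm[r]``."""
    decode_motif_id(bits)
    return _canonical_form_cached(bits)


@dataclass(frozen=True, order=True)
class MotifID:
    """Identifier of a motif isomorphism class (canonical adjacency bitstring).

    ``bits`` is validated for shape and connectivity but is *not* forced to
    be canonical, so published identifiers produced by other canonical
    labelings can be represented verbatim; :meth:`canonical` maps any valid
    identifier onto this package's canonical representative.
    """

    k: int = field(compare=False)
    bits: str

    def __post_init__(self):
        adj = decode_motif_id(self.bits)
        if adj.shape[0] != self.k:
            raise GraphModelError(
                f"declared size {self.k} inconsistent with bits length {len(self.bits)}"
            )

    @classmethod
    def from_bits(cls, bits: str) -> "MotifID":
        return cls(k=math.isqrt(len(bits)), bits=bits)

    def canonical(self) -> "MotifID":
        return MotifID(self.k, canonical_form(self.bits))

    @property
    def n_edges(self) -> int:
        return self.bits.count("1")

    def adjacency(self) -> np.ndarray:
        return decode_motif_id(self.bits)

    def is_isomorphic_to(self, other: "MotifID") -> bool:
        return self.k == other.k and canonical_form(self.bits) == canonical_form(other.bits)

    def __str__(self) -> str:
        return self.bits


def encode_motif_id(adjacency) -> MotifID:
    """Encode a 0/1 adjacency matrix as the canonical :class:`MotifID`."""
    adj = np.asarray(adjacency, dtype=np.uint8)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise GraphModelError("adjacency must be a square matrix")
    k = adj.shape[0]
    bits = "".join("1" if adj[i, j] else "0" for i in range(k) for j in range(k))
    return MotifID(k, canonical_form(bits))


@dataclass(frozen=True)
class MotifInstance:
    """One occurrence of a motif class: ``members[r]`` plays canonical row ``r``."""

    motif: MotifID
    members: tuple

    def __post_init__(self):
        if len(self.members) != self.motif.k:
            raise GraphModelError("member count must equal motif size")
        if len(set(self.members)) != len(self.members):
            raise GraphModelError("members must be distinct")

    @property
    def node_set(self) -> frozenset:
        return frozenset(self.members)


# ---------------------------------------------------------------------------
# Named motif archetypes
# ---------------------------------------------------------------------------

def _is_chain(adj: np.ndarray) -> bool:
    # simple directed path: k-1 edges, out-degrees/in-degrees all <=1,
    # exactly one source and one sink, weakly connected (already guaranteed)
    k = adj.shape[0]
    if adj.sum() != k - 1:
        return False
    outd, ind = adj.sum(axis=1), adj.sum(axis=0)
    return (
        outd.max() <= 1
        and ind.max() <= 1
        and int((outd == 0).sum()) == 1
        and int((ind == 0).sum()) == 1
    )


def _is_sim(adj: np.ndarray) -> bool:
    # single input module: one master regulating all other nodes, no other edges
    k = adj.shape[0]
    for hub in range(k):
        if adj[hub].sum() == k - 1 and adj.sum() == k - 1:
            return True
    return False


def _is_mim(adj: np.ndarray) -> bool:
    return _is_sim(adj.T)


def _is_bifan(adj: np.ndarray) -> bool:
    # 2 regulators x 2 targets, complete bipartite, no other edges
    if adj.shape[0] != 4 or adj.sum() != 4:
        return False
    outd, ind = adj.sum(axis=1), adj.sum(axis=0)
    sources = [i for i in range(4) if outd[i] == 2 and ind[i] == 0]
    sinks = [i for i in range(4) if ind[i] == 2 and outd[i] == 0]
    return len(sources) == 2 and len(sinks) == 2


def _is_biparallel(adj: np.ndarray) -> bool:
    # two parallel 2-step paths from one regulator to one target:
    # x -> m1 -> w, x -> m2 -> w (4 edges)
    if adj.shape[0] != 4 or adj.sum() != 4:
        return False
    outd, ind = adj.sum(axis=1), adj.sum(axis=0)
    src = [i for i in range(4) if outd[i] == 2 and ind[i] == 0]
    snk = [i for i in range(4) if ind[i] == 2 and outd[i] == 0]
    mid = [i for i in range(4) if outd[i] == 1 and ind[i] == 1]
    if not (len(src) == 1 and len(snk) == 1 and len(mid) == 2):
        return False
    x, w = src[0], snk[0]
    return all(adj[x, m] and adj[m, w] for m in mid)


def _is_diamond(adj: np.ndarray) -> bool:
    # biparallel plus the direct regulator -> target shortcut (5 edges),
    # the 4-node generalization of the feed-forward loop
    if adj.shape[0] != 4 or adj.sum() != 5:
        return False
    for x, w in itertools.permutations(range(4), 2):
        if not adj[x, w]:
            continue
        mids = [m for m in range(4) if m not in (x, w)]
        if all(adj[x, m] and adj[m, w] for m in mids):
            other = sum(
                adj[i, j]
                for i in range(4)
                for j in range(4)
                if (i, j) not in {(x, w)} | {(x, m) for m in mids} | {(m, w) for m in mids}
            )
            if other == 0:
                return True
    return False


def classify_named_motif(motif: MotifID) -> str:
    """Map a motif class onto the field's named archetypes.

    Returns one of ``chain``, ``SIM``, ``MIM``, ``bifan``, ``diamond``,
    ``biparallel`` or ``unnamed``. SIM = single input module (one master
    gene regulating every other node); MIM = multiple input module (its
    mirror); bifan = 2x2 complete bipartite regulation; chain = simple
    directed path; biparallel = two parallel regulator->middle->target
    paths; diamond = biparallel plus the direct regulator->target edge.
    """
    adj = motif.adjacency()
    if _is_chain(adj):
        return "chain"
    if _is_sim(adj):
        return "SIM"
    if _is_mim(adj):
        return "MIM"
    if _is_bifan(adj):
        return "bifan"
    if _is_diamond(adj):
        return "diamond"
    if _is_biparallel(adj):
        return "biparallel"
    return "unnamed"
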