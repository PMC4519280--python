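"""Synthetic pathway graphs with planted motifs and planted enrichment.

Real disease pathways are sparse directed gene graphs (tens to hundreds of
nodes, mixed activation/inhibition edges, a few high-out-degree regulator
hubs) in which a handful of genes recur across many copies of the same
wiring pattern. The generators here emulate exactly that, so the whole
pipeline — enumeration, null statistics, FN/FTN/FT, enrichment — can be
exercised and validated without any database download:

* a sparse random background (uniform, or preferential-attachment
  out-degree for hub-like structure),
* planted copies of a chosen motif class, optionally overlapping so that
  a small gene set recurs across instances (low FT, the signal the
  key-gene analysis is built to recover),
* ranked 0/1 label vectors with term genes concentrated at the top of the
  list (the signal the mHG statistic is built to recover).

Planting adds the motif's edges on chosen node tuples rather than rewiring
the background; on dense backgrounds an instance's induced subgraph may
then gain extra edges and fall into a larger class — every such collision
is logged, and the defaults keep the background sparse enough to make them
rare.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field, asdict
from typing import Optional

from .enrichment import RankedLabels
from .graph_model import DirectedGraph, MotifID, MotifInstance, encode_motif_id

logger = logging.getLogger("motifkey")

#: Gene symbols that can be stamped onto planted nodes for demonstration runs.
DEMO_GENE_NAMES = ("kras", "araf", "pik3r5", "ralgds", "akt3", "jun", "fos")


def bifan_motif() -> MotifID:
    """2 regulators x 2 targets, complete bipartite (the bifan)."""
    return encode_motif_id(
        [[0, 0, 1, 1], [0, 0, 1, 1], [0, 0, 0, 0], [0, 0, 0, 0]]
    )


def sim_motif(k: int = 4) -> MotifID:
    """Single input module: one master gene regulating k-1 targets."""
    adj = [[0] * k for _ in range(k)]
    for j in range(1, k):
        adj[0][j] = 1
    return encode_motif_id(adj)


def chain_motif(k: int = 4) -> MotifID:
    """Simple directed path on k genes."""
    adj = [[0] * k for _ in range(k)]
    for i in range(k - 1):
        adj[i][i + 1] = 1
    return encode_motif_id(adj)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic pathway + ranked-list draw.

    Defaults emulate a single KEGG-scale disease pathway: 60 genes, 70
    background edges (density just under 0.02), five planted copies of the
    bifan, and a 200-gene ranked list with a 20-gene term set whose members
    sit mostly in the top decile.
    """

    n_nodes: int = 60
    n_edges: int = 70
    background_model: str = "uniform"
    planted_motif: MotifID = field(default_factory=bifan_motif)
    copies: int = 5
    overlap_fraction: float = 0.0
    seed: Optional[int] = None
    list_length: int = 200
    term_size: int = 20
    enrichment_strength: float = 0.9

    def __post_init__(self):
        if self.n_edges > self.n_nodes * (self.n_nodes - 1):
            raise ValueError("n_edges exceeds the simple-digraph maximum")
        if self.copies < 0:
            raise ValueError("copies must be >= 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if not 0.0 <= self.enrichment_strength <= 1.0:
            raise ValueError("enrichment_strength must lie in [0, 1]")


def _gene_labels(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_background(
    n_nodes: int,
    n_edges: int,
    model: str = "uniform",
    seed: Optional[int] = None,
) -> DirectedGraph:
    """A simple random directed graph over synthetic gene labels.

    ``model='uniform'`` draws edges uniformly without replacement;
    ``model='scale-free-out'`` grows edges by preferential attachment on
    out-degree, producing regulator hubs with heavy-tailed out-degree.
    Edges carry activation (70%) or inhibition (30%) tags.
    """
    if model not in {"uniform", "scale-free-out"}:
        raise ValueError(f"unknown background model {model!r}")
    max_edges = n_nodes * (n_nodes - 1)
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges infeasible for {n_nodes} nodes")
    rng = random.Random(seed)
    labels = _gene_labels(n_nodes)
    graph = DirectedGraph(nodes=labels)
    if n_edges == 0:
        return graph

    def etype() -> str:
        return "activation" if rng.random() < 0.7 else "inhibition"

    if model == "uniform":
        picks = rng.sample(range(max_edges), n_edges)
        for idx in picks:
            i, r = divmod(idx, n_nodes - 1)
            j = r if r < i else r + 1
            graph.add_edge(labels[i], labels[j], etype())
    else:
        out_deg = [0] * n_nodes
        edge_set: set = set()
        attempts_cap = 200 * n_edges
        attempts = 0
        while len(edge_set) < n_edges:
            attempts += 1
            if attempts > attempts_cap:
                raise RuntimeError("preferential-attachment sampling stalled")
            src = rng.choices(range(n_nodes), weights=[d + 1 for d in out_deg], k=1)[0]
            tgt = rng.randrange(n_nodes)
            if tgt == src or (src, tgt) in edge_set:
                continue
            edge_set.add((src, tgt))
            out_deg[src] += 1
            graph.add_edge(labels[src], labels[tgt], etype())
    return graph


def plant_motifs(
    graph: DirectedGraph,
    motif: MotifID,
    copies: int,
    overlap_fraction: float = 0.0,
    seed: Optional[int] = None,
    gene_names: Optional[tuple] = None,
) -> tuple:
    """Add ``copies`` instances of a motif class onto a graph.

    Returns ``(planted_graph, instances)`` where each instance records its
    intended member tuple in canonical slot order. Overlapping copies
    (``round(overlap_fraction * (copies - 1))`` of them, the first copy can
    never overlap) reuse the *regulator* genes of a previously planted
    instance — the slots with outgoing motif edges — and draw fresh genes
    for the remaining target slots (when every slot regulates, one random
    slot is refreshed instead so copies stay distinct). This emulates the
    structure behind recurrent pathway genes: a small set of upstream
    regulators reused across many copies of one wiring pattern, each time
    acting on different targets. Because a gene occupies the
    same slot in every copy containing it, planted edges can never
    contaminate another planted instance's induced subgraph. Member tuples
    are drawn so that no background edge falls inside a tuple (each copy
    then realizes its class exactly, and enumeration finds at least
    ``copies`` instances of it); when no background-free tuple remains the
    copy is placed anyway and the collision (induced subgraph a strict
    superclass of the motif) is logged.

    ``gene_names`` optionally relabels planted nodes with real gene symbols
    (e.g. :data:`DEMO_GENE_NAMES`) for demonstration output.
    """
    motif = motif.canonical()
    k = motif.k
    adj = motif.adjacency()
    rng = random.Random(seed)
    out = graph.copy()
    if copies == 0:
        return out, []

    n_overlap = round(overlap_fraction * (copies - 1))
    regulator_slots = [i for i in range(k) if adj[i].any()]
    if len(regulator_slots) == k:
        regulator_slots = regulator_slots[:-1]
    n_fresh_overlap = k - len(regulator_slots)
    fresh_needed = (copies - n_overlap) * k + n_overlap * n_fresh_overlap
    pool = sorted(out.nodes)
    rng.shuffle(pool)
    if fresh_needed > len(pool):
        raise ValueError(
            f"planting needs {fresh_needed} unused nodes but the graph has {len(pool)}"
        )

    def background_free(members: list) -> bool:
        # a copy realizes its class exactly iff no background edge lies
        # inside the chosen tuple (planted edges are slot-consistent and
        # cannot interfere, see docstring)
        return not any(
            graph.has_edge(u, v) for u in members for v in members if u != v
        )

    def draw(n_fresh: int, fixed: list) -> list:
        # prefer tuples whose induced background subgraph is empty so the
        # planted instance list matches what enumeration will find
        for start in range(len(pool) - n_fresh + 1):
            cand = fixed + pool[start : start + n_fresh]
            if background_free(cand):
                chosen = pool[start : start + n_fresh]
                del pool[start : start + n_fresh]
                return chosen
        chosen = pool[:n_fresh]
        del pool[:n_fresh]
        return chosen

    instances: list = []
    collisions = 0
    for c in range(copies):
        if c > 0 and c >= copies - n_overlap:
            prev = rng.choice(instances)
            shared_slots = list(regulator_slots)
            if n_fresh_overlap == 1 and len(shared_slots) == k - 1:
                # fully-regulatory motif: refresh one random slot instead
                drop = rng.randrange(k)
                shared_slots = [i for i in range(k) if i != drop]
            members = [None] * k
            for i in shared_slots:
                members[i] = prev.members[i]
            fixed = [m for m in members if m is not None]
            fresh = draw(k - len(shared_slots), fixed)
            for i in range(k):
                if members[i] is None:
                    members[i] = fresh.pop()
        else:
            members = draw(k, [])
        for i in range(k):
            for j in range(k):
                if adj[i, j] and not out.has_edge(members[i], members[j]):
                    out.add_edge(members[i], members[j], "activation")
        instances.append(MotifInstance(motif, tuple(members)))

    if gene_names:
        mapping: dict = {}
        names = iter(gene_names)
        for inst in instances:
            for g in inst.members:
                if g not in mapping:
                    mapping[g] = next(names, g)
        renamed = DirectedGraph(nodes={mapping.get(n, n) for n in out.nodes})
        for (u, v) in out.edges:
            renamed.add_edge(mapping.get(u, u), mapping.get(v, v), out.edge_type(u, v))
        out = renamed
        instances = [
            MotifInstance(motif, tuple(mapping.get(g, g) for g in inst.members))
            for inst in instances
        ]

    for inst in instances:
        induced = out.induced_adjacency(inst.members)
        if int(induced.sum()) != int(adj.sum()):
            collisions += 1
    if collisions:
        logger.warning(
            "%d planted instance(s) absorbed background edges; their induced "
            "subgraphs belong to a denser class",
            collisions,
        )
    return out, instances


def generate_ranked_labels(
    N: int,
    K: int,
    enrichment_strength: float = 0.9,
    seed: Optional[int] = None,
) -> RankedLabels:
    """A 0/1 label vector of length N with K ones, enrichment at the top.

    ``round(enrichment_strength * K)`` ones are placed uniformly within the
    top decile (ranks 1..ceil(N/10)); the remaining ones are placed
    uniformly over the still-unoccupied ranks of the whole list. Strength 0
    therefore yields a uniform scatter, strength 1 a fully top-concentrated
    term.
    """
    if K > N:
        raise ValueError(f"term size K={K} exceeds list length N={N}")
    if not 0.0 <= enrichment_strength <= 1.0:
        raise ValueError("enrichment_strength must lie in [0, 1]")
    rng = random.Random(seed)
    top_block = math.ceil(N / 10)
    m = round(enrichment_strength * K)
    if m > top_block:
        raise ValueError(
            f"cannot place {m} term genes in a top decile of {top_block} ranks"
        )
    ones = set(rng.sample(range(top_block), m))
    remaining = [i for i in range(N) if i not in ones]
    ones.update(rng.sample(remaining, K - m))
    return RankedLabels(tuple(1 if i in ones else 0 for i in range(N)))


def synthesize(config: SyntheticConfig) -> dict:
    """Generate one full study: background + planted motifs + ranked labels.

    All randomness derives from ``config.seed`` (split deterministically per
    stage). Returns a dict with the graph, planted instances, label vector
    and a manifest recording the exact configuration.
    """
    root = random.Random(config.seed)
    seeds = {stage: root.randrange(2**31) for stage in ("background", "plant", "labels")}
    graph = generate_background(
        config.n_nodes, config.n_edges, config.background_model, seed=seeds["background"]
    )
    graph, instances = plant_motifs(
        graph,
        config.planted_motif,
        config.copies,
        config.overlap_fraction,
        seed=seeds["plant"],
    )
    labels = generate_ranked_labels(
        config.list_length, config.term_size, config.enrichment_strength,
        seed=seeds["labels"],
    )
    manifest = asdict(config)
    manifest["planted_motif"] = config.planted_motif.bits
    manifest["stage_seeds"] = seeds
    return {
        "graph": graph,
        "planted_instances": instances,
        "ranked_labels": labels,
        "manifest": manifest,
    }
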