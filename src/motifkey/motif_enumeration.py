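"""Enumeration of connected induced k-node subgraphs (ESU / RAND-ESU).

The exhaustive enumerator visits every k-node subset whose induced subgraph
is weakly connected exactly once, using Wernicke's ESU tree: vertices are
ordered (lexicographically by label), each subgraph is grown only from its
minimum vertex, and candidate extensions are restricted to the *exclusive*
neighbourhood of the newly added vertex so that no subset is reached twice.
The sampling variant prunes each ESU tree edge at depth ``d`` with
probability ``1 - p_d``, so every leaf (every subgraph) is visited with
probability ``prod(p_d)`` — dividing observed class counts by that product
gives unbiased estimates of the exhaustive counts.
"""

from __future__ import annotations

import logging
import random
from collections import Counter
from dataclasses import dataclass
from typing import Optional

from .graph_model import (
    MAX_MOTIF_SIZE,
    MIN_MOTIF_SIZE,
    DirectedGraph,
    MotifID,
    MotifInstance,
    canonical_form_with_perm,
)

logger = logging.getLogger("motifkey")


@dataclass
class EnumerationResult:
    """Outcome of one (exhaustive or sampled) subgraph census."""

    k: int
    instances: list
    class_counts: dict
    sampled: bool = False
    sampling_probabilities: tuple = ()

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    @property
    def visit_probability(self) -> float:
        prob = 1.0
        for p in self.sampling_probabilities:
            prob *= p
        return prob

    def estimated_counts(self) -> dict:
        """Class counts scaled to unbiased estimates of the exhaustive census."""
        prob = self.visit_probability
        return {m: c / prob for m, c in self.class_counts.items()}

    def to_tsv(self) -> str:
        lines = ["motif_id\tmembers"]
        for inst in self.instances:
            lines.append(f"{inst.motif.bits}\t{','.join(inst.members)}")
        return "\n".join(lines) + "\n"


def _classify_subset(graph: DirectedGraph, members: tuple) -> MotifInstance:
    """Canonical class and canonically ordered members for one node subset."""
    k = len(members)
    bits_chars = []
    for u in members:
        succ = graph.successors(u)
        bits_chars.append("".join("1" if (v in succ and v != u) else "0" for v in members))
    raw = "".join(bits_chars)
    canon, perm = canonical_form_with_perm(raw)
    ordered = tuple(members[perm[r]] for r in range(k))
    return MotifInstance(MotifID(k, canon), ordered)


def _esu(
    graph: DirectedGraph,
    k: int,
    rng: Optional[random.Random],
    probs: Optional[tuple],
) -> list:
    order = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(order)}
    nbrs = {n: graph.neighbors(n) for n in order}

    subsets: list = []

    def extend(sub: list, extension: set, root_idx: int, sub_nbrs: set) -> None:
        depth = len(sub) + 1  # depth at which the next vertex would be added
        if len(sub) == k:
            subsets.append(tuple(sub))
            return
        ext = sorted(extension)
        for w in ext:
            extension.discard(w)
            if probs is not None and rng.random() > probs[depth - 1]:
                continue
            # exclusive neighbourhood of w w.r.t. the current subgraph
            new_ext = set(extension)
            for u in nbrs[w]:
                if index[u] > root_idx and u not in sub_nbrs and u not in sub:
                    new_ext.add(u)
            extend(sub + [w], new_ext, root_idx, sub_nbrs | nbrs[w])

    for v in order:
        if probs is not None and rng.random() > probs[0]:
            continue
        root_idx = index[v]
        ext = {u for u in nbrs[v] if index[u] > root_idx}
        extend([v], ext, root_idx, set(nbrs[v]) | {v})
    return subsets


def enumerate_subgraphs(graph: DirectedGraph, k: int) -> EnumerationResult:
    """Exhaustively enumerate all connected induced k-node subgraphs.

    Connectivity is assessed on the undirected skeleton. Every qualifying
    node subset appears exactly once; output order is deterministic
    (lexicographic node ordering drives the search).
    """
    if not (MIN_MOTIF_SIZE <= k <= MAX_MOTIF_SIZE):
        raise ValueError(f"motif size k={k} outside [{MIN_MOTIF_SIZE}, {MAX_MOTIF_SIZE}]")
    if graph.n_nodes < k:
        logger.warning("graph has %d nodes < k=%d; empty enumeration", graph.n_nodes, k)
        return EnumerationResult(k=k, instances=[], class_counts={})
    subsets = _esu(graph, k, rng=None, probs=None)
    instances = [_classify_subset(graph, s) for s in subsets]
    return EnumerationResult(k=k, instances=instances, class_counts=dict(count_motif_classes(instances, k=k)))


def sample_subgraphs(
    graph: DirectedGraph,
    k: int,
    depth_probabilities,
    seed: Optional[int] = None,
) -> EnumerationResult:
    """RAND-ESU: sample connected induced k-subgraphs.

    ``depth_probabilities`` holds one probability per tree depth (length k,
    each in (0, 1]); each subgraph is visited with probability equal to
    their product. With all probabilities 1 the result equals
    :func:`enumerate_subgraphs`. Reproducible under a fixed ``seed``.
    """
    if not (MIN_MOTIF_SIZE <= k <= MAX_MOTIF_SIZE):
        raise ValueError(f"motif size k={k} outside [{MIN_MOTIF_SIZE}, {MAX_MOTIF_SIZE}]")
    probs = tuple(float(p) for p in depth_probabilities)
    if len(probs) != k:
        raise ValueError(f"need {k} depth probabilities, got {len(probs)}")
    if any(p <= 0.0 or p > 1.0 for p in probs):
        raise ValueError("depth probabilities must lie in (0, 1]")
    if graph.n_nodes < k:
        logger.warning("graph has %d nodes < k=%d; empty enumeration", graph.n_nodes, k)
        return EnumerationResult(k=k, instances=[], class_counts={}, sampled=True,
                                 sampling_probabilities=probs)
    rng = random.Random(seed)
    subsets = _esu(graph, k, rng=rng, probs=probs)
    instances = [_classify_subset(graph, s) for s in subsets]
    return EnumerationResult(
        k=k,
        instances=instances,
        class_counts=dict(count_motif_classes(instances, k=k)),
        sampled=True,
        sampling_probabilities=probs,
    )


def count_motif_classes(instances, k: Optional[int] = None) -> Counter:
    """Aggregate motif instances into per-class counts.

    All instances must share one motif size; counts sum to ``len(instances)``.
    """
    counts: Counter = Counter()
    for inst in instances:
        if k is None:
            k = inst.motif.k
        elif inst.motif.k != k:
            raise ValueError(
                f"mixed motif sizes in instance list: {inst.motif.k} != {k}"
            )
        counts[inst.motif] += 1
    return counts
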