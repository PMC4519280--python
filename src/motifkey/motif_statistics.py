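"""Null-model randomization and motif significance statistics.

Over-representation of a motif class is judged against an ensemble of
degree-preserving randomizations of the input graph (directed edge
switching). For each class the ensemble yields a mean and standard
deviation of the random count, from which the z-score

    z(m_i) = (N_real(m_i) - mean_rand(m_i)) / sd_rand(m_i)

an add-one empirical one-sided p-value, and the significance profile

    SP(m_i) = z(m_i) / sqrt(sum_j z(m_j)^2)

(normalized z-scores with unit Euclidean norm per normalization group)
are computed. Classes with z > 2 and p < 0.05 are called significant.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field, replace
from typing import Optional

from .graph_model import DirectedGraph, MotifID
from .motif_enumeration import enumerate_subgraphs

logger = logging.getLogger("motifkey")

Z_THRESHOLD = 2.0
P_THRESHOLD = 0.05
DEFAULT_ENSEMBLE_SIZE = 1000
DEFAULT_SWITCHES_PER_EDGE = 3


@dataclass
class MotifStats:
    """Per-class real count, null mean/sd, z, empirical p and SP."""

    motif: MotifID
    count_real: int
    rand_mean: float
    rand_sd: float
    z: Optional[float]  # None when the null ensemble has zero variance
    p: float
    sp: Optional[float] = None
    ensemble_size: int = 0

    @property
    def z_defined(self) -> bool:
        return self.z is not None


@dataclass
class NullEnsemble:
    """Class-count maps from R independent degree-preserving randomizations."""

    k: int
    counts: list  # one dict MotifID -> count per replicate
    switch_counts: list = field(default_factory=list)
    seed: Optional[int] = None

    @property
    def size(self) -> int:
        return len(self.counts)

    def class_counts(self, motif: MotifID) -> list:
        return [c.get(motif, 0) for c in self.counts]

    def all_classes(self) -> set:
        classes: set = set()
        for c in self.counts:
            classes.update(c)
        return classes


# ---------------------------------------------------------------------------
# Degree-preserving randomization
# ---------------------------------------------------------------------------

def randomize_network(
    graph: DirectedGraph,
    switches_per_edge: int = DEFAULT_SWITCHES_PER_EDGE,
    seed: Optional[int] = None,
) -> DirectedGraph:
    """Randomize a graph by directed edge switching.

    ``switches_per_edge * |E|`` switch attempts are made; each picks two
    directed edges (a->b, c->d) and rewires them to (a->d, c->b) unless
    that would create a self-loop or a duplicate edge. Every node's in- and
    out-degree is preserved exactly. Edge types travel with the source
    endpoint. Reproducible under a fixed seed.
    """
    if switches_per_edge < 1:
        raise ValueError("switches_per_edge must be >= 1")
    if graph.n_edges < 2:
        logger.warning("graph has <2 edges; returning it unchanged")
        return graph.copy()
    rng = random.Random(seed)
    edges = sorted(graph.edges)
    types = {e: graph.edge_type(*e) for e in edges}
    edge_set = set(edges)
    n_attempts = switches_per_edge * len(edges)
    n_switched = 0
    for _ in range(n_attempts):
        i, j = rng.randrange(len(edges)), rng.randrange(len(edges))
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        if a == d or c == b:
            continue  # would create a self-loop
        if (a, d) in edge_set or (c, b) in edge_set:
            continue  # would create a duplicate edge
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        t_ab, t_cd = types.pop((a, b)), types.pop((c, d))
        types[(a, d)], types[(c, b)] = t_ab, t_cd
        edges[i], edges[j] = (a, d), (c, b)
        n_switched += 1
    if n_switched == 0:
        logger.warning("no legal edge switches found; returning an unchanged copy")
    out = DirectedGraph(nodes=graph.nodes)
    for (u, v) in edges:
        t = types[(u, v)]
        # re-adding a 'binding' edge would also insert its mirror and break
        # the switched edge set; store switched edges with their tag verbatim
        out._g.add_edge(u, v, edge_type=t)
    return out


def build_null_ensemble(
    graph: DirectedGraph,
    k: int,
    R: int = DEFAULT_ENSEMBLE_SIZE,
    switches_per_edge: int = DEFAULT_SWITCHES_PER_EDGE,
    seed: Optional[int] = None,
) -> NullEnsemble:
    """Enumerate motif classes in R independent randomized replicates."""
    if R < 2:
        raise ValueError("ensemble size R must be >= 2")
    if graph.n_edges == 0:
        raise ValueError("cannot build a null ensemble for an edgeless graph")
    root = random.Random(seed)
    counts = []
    for _ in range(R):
        rep_seed = root.randrange(2**31)
        rep = randomize_network(graph, switches_per_edge, seed=rep_seed)
        res = enumerate_subgraphs(rep, k)
        counts.append(dict(res.class_counts))
    return NullEnsemble(k=k, counts=counts, seed=seed)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def motif_zscore(count_real: int, ensemble_counts) -> Optional[float]:
    """z = (real - mean) / sd with the sample (R-1) standard deviation.

    Returns ``None`` (undefined) when the ensemble variance is zero.
    """
    counts = list(ensemble_counts)
    if not counts:
        raise ValueError("ensemble is empty")
    n = len(counts)
    mean = sum(counts) / n
    if n < 2:
        return None
    var = sum((c - mean) ** 2 for c in counts) / (n - 1)
    if var == 0.0:
        return None
    return (count_real - mean) / math.sqrt(var)


def motif_pvalue(count_real: int, ensemble_counts) -> float:
    """Add-one empirical one-sided over-representation p-value.

    p = (1 + #{replicates with count >= real}) / (R + 1); never 0, at most 1.
    """
    counts = list(ensemble_counts)
    if not counts:
        raise ValueError("ensemble is empty")
    ge = sum(1 for c in counts if c >= count_real)
    return (1 + ge) / (len(counts) + 1)


def compute_motif_stats(
    real_counts: dict,
    ensemble: NullEnsemble,
) -> list:
    """Assemble :class:`MotifStats` for every class seen in the real graph
    or in any replicate (absent counts are 0)."""
    classes = set(real_counts) | ensemble.all_classes()
    stats = []
    for motif in sorted(classes, key=lambda m: (m.k, m.bits)):
        counts = ensemble.class_counts(motif)
        n = len(counts)
        mean = sum(counts) / n
        var = sum((c - mean) ** 2 for c in counts) / (n - 1) if n > 1 else 0.0
        real = real_counts.get(motif, 0)
        stats.append(
            MotifStats(
                motif=motif,
                count_real=real,
                rand_mean=mean,
                rand_sd=math.sqrt(var),
                z=motif_zscore(real, counts),
                p=motif_pvalue(real, counts),
                ensemble_size=n,
            )
        )
    return stats


def filter_significant(
    stats,
    z_threshold: float = Z_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> list:
    """Keep classes with z > z_threshold and p < p_threshold (strict);
    classes with undefined z are excluded."""
    return [
        s
        for s in stats
        if s.z is not None and s.z > z_threshold and s.p < p_threshold
    ]


def significance_profile(stats, scope: str = "per-size") -> list:
    """Attach SP values: z-scores normalized to unit Euclidean norm.

    ``scope='per-size'`` normalizes within each motif size k (the default,
    matching size-by-size profiles); ``scope='pooled'`` normalizes across
    the whole list. Classes with undefined z get SP ``None`` and do not
    contribute to the norm; an all-zero group gets SP 0 with a warning.
    """
    if scope not in {"per-size", "pooled"}:
        raise ValueError(f"unknown SP scope {scope!r}")
    groups: dict = {}
    for s in stats:
        key = s.motif.k if scope == "per-size" else None
        groups.setdefault(key, []).append(s)
    out = []
    for key, group in groups.items():
        norm = math.sqrt(sum(s.z**2 for s in group if s.z is not None))
        if norm == 0.0:
            logger.warning("all z-scores zero/undefined in SP group %r; SP set to 0", key)
        for s in group:
            if s.z is None:
                sp = None
            elif norm == 0.0:
                sp = 0.0
            else:
                sp = s.z / norm
            out.append(replace(s, sp=sp))
    out.sort(key=lambda s: (s.motif.k, s.motif.bits))
    return out


def motif_report_tsv(stats) -> str:
    """TSV report: motif_id, k, count_real, rand_mean, rand_sd, z, p, sp,
    significant(0/1); z/p/SP printed with 4 significant digits."""

    def fmt(x):
        if x is None:
            return "NA"
        return f"{x:.4g}"

    sig = {id(s) for s in filter_significant(stats)}
    lines = ["motif_id\tk\tcount_real\trand_mean\trand_sd\tz\tp\tsp\tsignificant"]
    for s in stats:
        lines.append(
            "\t".join(
                [
                    s.motif.bits,
                    str(s.motif.k),
                    str(s.count_real),
                    fmt(s.rand_mean),
                    fmt(s.rand_sd),
                    fmt(s.z),
                    fmt(s.p),
                    fmt(s.sp),
                    "1" if id(s) in sig else "0",
                ]
            )
        )
    return "\n".join(lines) + "\n"
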