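"""Hypergeometric and minimum-hypergeometric (mHG) enrichment statistics.

For a population of N genes of which A carry a term, the probability that a
sample of n genes contains ``a`` or more term genes is the hypergeometric
upper tail

    p = 1 - sum_{i=0}^{a-1} C(A, i) C(N-A, n-i) / C(N, n) = P(X >= a).

When no fixed cutoff n is given, a ranked gene list with binary labels
``lambda_1..lambda_N`` is scored with the minimum hypergeometric statistic

    mHG(lambda) = min_{1 <= n <= N} HGT(N, K, n, k_n),   k_n = sum_{i<=n} lambda_i,

the best tail attainable over all prefix cutoffs. The mHG score is not
itself a p-value (it is minimized over N dependent tests); a permutation
p-value over random label vectors with the same K calibrates it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import stats as sps

#: Largest population size for which the tail is evaluated with exact
#: integer arithmetic; beyond it the scipy survival function (log-space
#: internally) is used.
EXACT_N_LIMIT = 170


@dataclass(frozen=True)
class EnrichmentQuery:
    """Hypergeometric setup: population N with A term genes; sample n with a."""

    N: int
    A: int
    n: int
    a: int

    def __post_init__(self):
        if not (0 <= self.A <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"need 0 <= A, n <= N, got {self}")
        if not (0 <= self.a <= min(self.A, self.n)):
            raise ValueError(f"need 0 <= a <= min(A, n), got {self}")


@lru_cache(maxsize=1 << 20)
def _tail_cached(N: int, A: int, n: int, a: int) -> float:
    if a == 0:
        return 1.0
    if N <= EXACT_N_LIMIT:
        total = math.comb(N, n)
        acc = sum(math.comb(A, i) * math.comb(N - A, n - i) for i in range(a, min(A, n) + 1))
        return float(Fraction(acc, total))
    return float(sps.hypergeom.sf(a - 1, N, A, n))


def hypergeometric_tail(N: int, A: int, n: int, a: int) -> float:
    """Upper-tail P(X >= a) for X ~ Hypergeometric(N, A, n).

    Exact rational arithmetic for N <= 170; never negative; 1 when a = 0.
    """
    EnrichmentQuery(N, A, n, a)  # validate
    return _tail_cached(N, A, n, a)


@dataclass(frozen=True)
class RankedLabels:
    """Binary term-membership labels over a ranked gene list (rank 1 first)."""

    labels: tuple

    def __post_init__(self):
        if len(self.labels) < 1:
            raise ValueError("label vector must be non-empty")
        if not set(self.labels) <= {0, 1}:
            raise ValueError("labels must be 0/1")

    @property
    def N(self) -> int:
        return len(self.labels)

    @property
    def K(self) -> int:
        return int(sum(self.labels))

    def prefix_counts(self) -> list:
        """k_n = number of term genes among the top n ranks, n = 1..N."""
        out, acc = [], 0
        for lam in self.labels:
            acc += lam
            out.append(acc)
        return out


def mhg_score(ranked: RankedLabels) -> tuple:
    """Minimum hypergeometric score and its (smallest) optimal cutoff n*.

    Returns ``(score, n_star)`` with score = min over n of
    ``hypergeometric_tail(N, K, n, k_n)``.
    """
    N, K = ranked.N, ranked.K
    best, best_n = 1.0, 1
    for n, k_n in enumerate(ranked.prefix_counts(), start=1):
        tail = hypergeometric_tail(N, K, n, k_n)
        if tail < best:
            best, best_n = tail, n
    return best, best_n


def mhg_permutation_pvalue(
    score: float,
    N: int,
    K: int,
    permutations: int = 1000,
    seed: Optional[int] = None,
) -> float:
    """Permutation p-value for an observed mHG score.

    Draws ``permutations`` random label vectors with K ones over N ranks;
    p = (1 + #{vectors with mHG <= observed}) / (permutations + 1).
    """
    if permutations < 1:
        raise ValueError("need at least one permutation")
    if not 0 <= K <= N:
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    rng = np.random.default_rng(seed)
    base = np.zeros(N, dtype=int)
    base[:K] = 1
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(base)
        s, _ = mhg_score(RankedLabels(tuple(int(x) for x in perm)))
        if s <= score:
            hits += 1
    return (1 + hits) / (permutations + 1)


def enrich_ranked_list(
    ranked: RankedLabels,
    permutations: int = 1000,
    seed: Optional[int] = None,
) -> dict:
    """Score a ranked label vector: mHG score, optimal cutoff, permutation p."""
    score, n_star = mhg_score(ranked)
    p = mhg_permutation_pvalue(score, ranked.N, ranked.K, permutations, seed)
    return {
        "N": ranked.N,
        "K": ranked.K,
        "mhg_score": score,
        "n_star": n_star,
        "k_at_n_star": ranked.prefix_counts()[n_star - 1],
        "permutation_p": p,
        "permutations": permutations,
    }


def enrichment_report_tsv(result: dict) -> str:
    lines = ["N\tK\tmhg_score\tn_star\tk_at_n_star\tpermutation_p\tpermutations"]
    lines.append(
        f"{result['N']}\t{result['K']}\t{result['mhg_score']:.4g}\t"
        f"{result['n_star']}\t{result['k_at_n_star']}\t"
        f"{result['permutation_p']:.4g}\t{result['permutations']}"
    )
    return "\n".join(lines) + "\n"
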