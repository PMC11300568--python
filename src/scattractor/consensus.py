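"""Cross-sample consensus of ranked gene lists and hypergeometric overlap tests.

Per-sample attractor runs yield independently derived ranked gene lists;
a signature is credible when the same genes are consistently top ranked
across samples. :func:`consensus_rank` aggregates the lists by support
(number of samples placing a gene inside the top k) first and median rank
second. :func:`hypergeometric_overlap` gives the one-sided upper-tail
probability of observing at least the seen intersection between two gene
lists drawn from a common background universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .matrix_io import GeneList

__all__ = [
    "ConsensusEntry",
    "ConsensusRanking",
    "OverlapTest",
    "consensus_rank",
    "hypergeometric_overlap",
    "overlap",
]


@dataclass(frozen=True)
class ConsensusEntry:
    gene: str
    median_rank: float
    support: int


@dataclass(frozen=True)
class ConsensusRanking:
    """Aggregated ordering: support descending, median rank ascending,
    then gene id."""

    entries: tuple[ConsensusEntry, ...]
    num_samples: int
    top_k: int

    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]


@dataclass(frozen=True)
class OverlapTest:
    """Hypergeometric upper-tail test of a k-gene intersection between
    lists of sizes n1 and n2 drawn from a universe of N genes."""

    universe: int
    n1: int
    n2: int
    overlap: int
    p_value: float


def consensus_rank(
    rankings: list[list[str]] | list[GeneList], top_k: int = 100
) -> ConsensusRanking:
    """Aggregate per-sample ranked gene lists into a consensus ordering.

    For every gene inside any sample's top ``top_k``: support counts the
    samples placing it there; its rank in a sample where it is absent from
    the top k is penalized as ``top_k + 1``, and the median of these ranks
    breaks support ties. Result is invariant to sample order.
    """
    lists = [list(r.genes) if isinstance(r, GeneList) else list(r) for r in rankings]
    if not lists:
        raise ValueError("need at least one ranking")
    for i, lst in enumerate(lists):
        if len(set(lst)) != len(lst):
            raise ValueError(f"ranking {i} contains duplicate genes")
    tops = [lst[:top_k] for lst in lists]
    universe = sorted(set().union(*[set(t) for t in tops]))
    penalty = top_k + 1
    entries = []
    for gene in universe:
        ranks = [t.index(gene) + 1 if gene in t else penalty for t in tops]
        support = sum(r <= top_k for r in ranks)
        entries.append(
            ConsensusEntry(gene, float(np.median(ranks)), support)
        )
    entries.sort(key=lambda e: (-e.support, e.median_rank, e.gene))
    return ConsensusRanking(tuple(entries), num_samples=len(lists), top_k=top_k)


def hypergeometric_overlap(N: int, n1: int, n2: int, k: int) -> OverlapTest:
    """P(intersection >= k) for two lists of sizes n1, n2 from N genes.

    Computed in log space as logsumexp of hypergeometric log-pmf terms
    over i = k .. min(n1, n2), so p-values far below float underflow of a
    single term (e.g. 1e-30) remain accurate.
    """
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ValueError("list sizes must be within the universe")
    if not 0 <= k <= min(n1, n2):
        raise ValueError("overlap must be within [0, min(n1, n2)]")
    lower = max(0, n1 + n2 - N)
    if k <= lower:
        p = 1.0
    else:
        i = np.arange(k, min(n1, n2) + 1)
        p = float(np.exp(logsumexp(hypergeom.logpmf(i, N, n2, n1))))
    return OverlapTest(
        universe=N, n1=n1, n2=n2, overlap=k, p_value=min(max(p, 0.0), 1.0)
    )


def overlap(list1: GeneList, list2: GeneList) -> GeneList:
    """Intersection of two gene lists, preserving ``list1`` order."""
    in2 = set(list2.genes)
    genes = tuple(g for g in list1.genes if g in in2)
    return GeneList(name=f"{list1.name} & {list2.name}", genes=genes)
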