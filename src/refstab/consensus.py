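"""Rank-consensus aggregation of the four stability estimators.

The web tool RefFinder popularized a simple consensus: take each
method's rank position for a gene and report the geometric mean of
those ranks as a "comprehensive stability value" (lower = more
stable).  Two conventions matter for reproducing published tables:

* GeNorm's final two genes are tied — *both* contribute rank 1 (not
  1 and 2, and not 1.5 each).
* Ordering uses the unrounded geometric mean; display is rounded to
  two decimals.

The module also implements the V-statistic rule for how many reference
genes to use (smallest n with V(n/n+1) below a cutoff, 0.15 by
default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .stability import (
    BestkeeperResult,
    DeltaCtResult,
    GenormResult,
    NormfinderResult,
)

logger = logging.getLogger(__name__)

METHODS = ("GeNorm", "NormFinder", "BestKeeper", "DeltaCT")

V_CUTOFF = 0.15


@dataclass
class MethodRanking:
    """One method's gene -> rank map (GeNorm final pair both rank 1)."""

    method: str
    rank: dict[str, float]

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")

    @staticmethod
    def from_order(method: str, order: list[str]) -> "MethodRanking":
        """Ranks 1..G from a most-stable-first gene order."""
        return MethodRanking(method, {g: float(i) for i, g in enumerate(order, start=1)})

    @staticmethod
    def from_genorm(r: GenormResult) -> "MethodRanking":
        return MethodRanking("GeNorm", {g: float(k) for g, k in r.exclusion_rank.items()})

    @staticmethod
    def from_normfinder(r: NormfinderResult) -> "MethodRanking":
        return MethodRanking.from_order("NormFinder", r.ranking())

    @staticmethod
    def from_bestkeeper(r: BestkeeperResult) -> "MethodRanking":
        return MethodRanking.from_order("BestKeeper", r.ranking())

    @staticmethod
    def from_deltact(r: DeltaCtResult) -> "MethodRanking":
        return MethodRanking.from_order("DeltaCT", r.ranking())


@dataclass
class ConsensusRanking:
    """Geometric-mean-of-ranks consensus over the available methods."""

    genes: list[str]
    geomean_rank: dict[str, float]
    order: list[str]          # most stable first
    n_methods: int

    def top(self, n: int) -> list[str]:
        return self.order[:n]

    def least_stable(self) -> str:
        return self.order[-1]

    def display(self) -> dict[str, float]:
        return {g: round(self.geomean_rank[g], 2) for g in self.order}


def reffinder(rankings: list[MethodRanking]) -> ConsensusRanking:
    """Aggregate per-method ranks into a consensus ranking.

    geomean_rank(gene) = (prod of ranks)^(1/n_methods).  All rankings
    must cover the same gene set; a method that errored upstream is
    simply omitted by the caller and the mean adjusts (logged).
    Ordering ties are broken by first-method rank, then gene order.
    """
    if not rankings:
        raise ValueError("need at least one method ranking")
    gene_set = set(rankings[0].rank)
    for r in rankings[1:]:
        if set(r.rank) != gene_set:
            diff = sorted(gene_set.symmetric_difference(r.rank))
            raise ValueError(f"gene sets differ between methods: {diff}")
    if len(rankings) < len(METHODS):
        logger.info("consensus over %d method(s): %s",
                    len(rankings), [r.method for r in rankings])

    genes = list(rankings[0].rank)
    n = len(rankings)
    geomean = {}
    for g in genes:
        prod = 1.0
        for r in rankings:
            prod *= r.rank[g]
        geomean[g] = prod ** (1.0 / n)
    order = sorted(genes, key=lambda g: (geomean[g], rankings[0].rank[g], genes.index(g)))
    return ConsensusRanking(genes, geomean, order, n)


def recommended_count(v_values: list[float], cutoff: float = V_CUTOFF) -> int:
    """Optimal number of reference genes from GeNorm pairwise variation.

    ``v_values[i]`` is V(n/n+1) for n = i + 2.  Returns the smallest n
    whose V is below the cutoff; if none qualifies, returns the full
    gene count G = len(v_values) + 2 with a warning.
    """
    if not v_values:
        raise ValueError("v_values is empty")
    for i, v in enumerate(v_values):
        if v < cutoff:
            return i + 2
    g = len(v_values) + 2
    logger.warning("no V(n/n+1) below %.2f; recommending all %d genes", cutoff, g)
    return g


def recommend(consensus: ConsensusRanking, n: int) -> dict[str, object]:
    """Top-n reference genes plus the single least stable gene."""
    g = len(consensus.genes)
    if not 2 <= n <= g:
        raise ValueError(f"n must be in [2, {g}], got {n}")
    return dict(
        most_stable=consensus.top(n),
        least_stable=consensus.least_stable(),
        n=n,
    )
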