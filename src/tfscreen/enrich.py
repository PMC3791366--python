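"""Gene-set overlap enrichment: Venn partitions and hypergeometric tails.

The overlap of a query set (e.g. stimulus-induced genes) with the bound
set is scored by the exact one-sided hypergeometric tail: drawing n query
genes without replacement from a universe of N genes containing K bound
ones, the upper tail P(X >= k) measures over-representation and the lower
tail P(X <= k) under-representation. Tails are accumulated in log space so
extreme enrichments at genome scale do not underflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Set

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom


@dataclass(frozen=True)
class EnrichmentResult:
    N: int  # universe size
    K: int  # bound genes in universe
    n: int  # query-set size
    k: int  # overlap
    percent: float  # 100 * k / n
    p_over: float  # P(X >= k)
    p_under: float  # P(X <= k)


@dataclass(frozen=True)
class VennPartition:
    """Disjoint region counts for three sets A, B, C."""

    a_only: int
    b_only: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int
    c_only: int

    def total(self) -> int:
        return (
            self.a_only + self.b_only + self.ab_only + self.ac_only
            + self.bc_only + self.abc + self.c_only
        )


def hypergeom_pvalue(k: int, n: int, K: int, N: int, tail: str = "over") -> float:
    """Exact one-sided hypergeometric tail probability.

    over: P(X >= k); under: P(X <= k) for X ~ Hypergeom(N, K, n).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: n={n}, K={K}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"inconsistent counts: k={k} outside [0, min(n={n}, K={K})]")
    if tail not in ("over", "under"):
        raise ValueError(f"tail must be 'over' or 'under', got {tail!r}")
    lo = max(0, n + K - N)
    hi = min(n, K)
    if (tail == "over" and k <= lo) or (tail == "under" and k >= hi):
        return 1.0  # tail covers the whole support
    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, N, K, n)
    mask = support >= k if tail == "over" else support <= k
    if not mask.any():
        return 0.0
    return float(min(1.0, np.exp(logsumexp(logpmf[mask]))))


def overlap_report(query: Set[str], bound: Set[str], universe: Set[str]) -> EnrichmentResult:
    """Score the overlap of a query gene set with the bound set.

    Members of query or bound outside the universe are dropped with a
    warning; an empty universe is an error.
    """
    if not universe:
        raise ValueError("empty universe")
    stray = (query | bound) - universe
    if stray:
        warnings.warn(
            f"{len(stray)} gene(s) outside the universe dropped from the overlap test",
            stacklevel=2,
        )
    q = query & universe
    b = bound & universe
    N, K, n = len(universe), len(b), len(q)
    k = len(q & b)
    percent = 100.0 * k / n if n else 0.0
    return EnrichmentResult(
        N=N,
        K=K,
        n=n,
        k=k,
        percent=percent,
        p_over=hypergeom_pvalue(k, n, K, N, "over"),
        p_under=hypergeom_pvalue(k, n, K, N, "under"),
    )


def venn_partition(A: Set[str], B: Set[str], C: Set[str]) -> VennPartition:
    """Counts of the seven disjoint regions of a three-set Venn diagram."""
    return VennPartition(
        a_only=len(A - B - C),
        b_only=len(B - A - C),
        ab_only=len((A & B) - C),
        ac_only=len((A & C) - B),
        bc_only=len((B & C) - A),
        abc=len(A & B & C),
        c_only=len(C - A - B),
    )


def enrichment_to_dict(r: EnrichmentResult) -> Dict[str, float]:
    return {
        "N": r.N,
        "K": r.K,
        "n": r.n,
        "k": r.k,
        "percent": r.percent,
        "p_over": r.p_over,
        "p_under": r.p_under,
    }
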