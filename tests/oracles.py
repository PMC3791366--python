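"""Independent brute-force oracles used to cross-check the implementation.

Each oracle deliberately avoids the code path it checks: assignments are
scored by scanning every (peak, gene) pair, hypergeometric tails by
enumerating every possible draw, BH by the literal min-over-suffix
definition, and region construction by per-base coverage sets.
"""

from itertools import combinations
from typing import Dict, List, Optional, Sequence, Set, Tuple


def brute_force_assign(peak, genes, window: int) -> Dict[str, Optional[str]]:
    """Best gene per strand by scoring every (peak, gene) pair directly."""
    out: Dict[str, Optional[str]] = {"+": None, "-": None}
    best_key = {}
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        gap = max(0, max(g.start, peak.start) - min(g.end, peak.end))
        if gap > window:
            continue
        key = (gap, g.start, g.gene_id)
        if g.strand not in best_key or key < best_key[g.strand]:
            best_key[g.strand] = key
            out[g.strand] = g.gene_id
    return out


def enumerate_hypergeom(k: int, n: int, K: int, N: int, tail: str) -> float:
    """Tail probability by enumerating all C(N, n) equally likely draws."""
    universe = range(N)
    special = set(range(K))
    hits = 0
    total = 0
    for draw in combinations(universe, n):
        total += 1
        overlap = sum(1 for x in draw if x in special)
        if (tail == "over" and overlap >= k) or (tail == "under" and overlap <= k):
            hits += 1
    return hits / total


def bh_suffix(pvalues: Sequence[float]) -> List[float]:
    """Literal min-over-suffix step-up definition, mapped to input order."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    for rank, i in enumerate(indexed, start=1):
        adjusted[i] = min(
            min(m * pvalues[j] / (r + 1) for r, j in enumerate(indexed) if r + 1 >= rank),
            1.0,
        )
    return adjusted


def per_base_union(peak_sets) -> Set[Tuple[str, int]]:
    """Set of covered (chrom, base) pairs across every factor's peaks."""
    covered: Set[Tuple[str, int]] = set()
    for ps in peak_sets:
        for p in ps:
            for b in range(p.start, p.end):
                covered.add((p.chrom, b))
    return covered


def factor_covers_region(ps, region) -> bool:
    chrom, start, end = region
    return any(
        p.chrom == chrom and max(p.start, start) < min(p.end, end) for p in ps
    )
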