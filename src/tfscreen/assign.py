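"""Strand-aware peak-to-gene assignment.

Each peak is associated with up to two genes: the most proximal gene on
each strand, searching 50 kb up- and downstream of the peak. Distance is
the edge-to-edge gap between the peak interval and the gene body, so a
gene overlapping the peak has distance 0 and always wins on its strand.
Ties break by smaller gap, then leftmost gene start, then gene_id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Set, Tuple

import pandas as pd

from .genome import GeneRecord, GenomeAnnotation, Peak, PeakSet, interval_gap


@dataclass(frozen=True)
class AssignmentConfig:
    window_bp: int = 50_000

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


@dataclass(frozen=True)
class PeakAssignment:
    peak: Peak
    plus_gene: Optional[str] = None
    minus_gene: Optional[str] = None
    plus_distance: Optional[int] = None
    minus_distance: Optional[int] = None

    @property
    def genes(self) -> Set[str]:
        return {g for g in (self.plus_gene, self.minus_gene) if g is not None}


def assign_peak(peak: Peak, annotation: GenomeAnnotation, config: AssignmentConfig = AssignmentConfig()) -> PeakAssignment:
    """Assign a peak to the nearest gene on each strand within the window.

    An absent chromosome or an empty window yields an empty assignment.
    """
    w = config.window_bp
    lo = max(0, peak.start - w)
    # +1 so genes abutting the window edge (gap exactly w) are retrieved
    candidates = annotation.query(peak.chrom, lo, peak.end + w + 1)
    best: dict = {}
    for g in candidates:
        gap = interval_gap(g, peak)
        if gap > w:
            continue
        key = (gap, g.start, g.gene_id)
        if g.strand not in best or key < best[g.strand][0]:
            best[g.strand] = (key, g)
    plus = best.get("+")
    minus = best.get("-")
    return PeakAssignment(
        peak=peak,
        plus_gene=plus[1].gene_id if plus else None,
        minus_gene=minus[1].gene_id if minus else None,
        plus_distance=plus[0][0] if plus else None,
        minus_distance=minus[0][0] if minus else None,
    )


def bound_genes(
    peak_set: PeakSet,
    annotation: GenomeAnnotation,
    config: AssignmentConfig = AssignmentConfig(),
) -> Tuple[Set[str], pd.DataFrame]:
    """Union of assigned gene ids over all peaks, plus a per-row audit table.

    The audit table has one row per (peak, assigned gene): peak coordinates,
    strand slot, gene_id and distance in bp.
    """
    rows = []
    bound: Set[str] = set()
    for p in peak_set:
        a = assign_peak(p, annotation, config)
        for strand, gene_id, dist in (
            ("+", a.plus_gene, a.plus_distance),
            ("-", a.minus_gene, a.minus_distance),
        ):
            if gene_id is None:
                continue
            bound.add(gene_id)
            rows.append(
                {
                    "chrom": p.chrom,
                    "peak_start": p.start,
                    "peak_end": p.end,
                    "peak_name": p.name,
                    "strand": strand,
                    "gene_id": gene_id,
                    "distance_bp": dist,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["chrom", "peak_start", "peak_end", "peak_name", "strand", "gene_id", "distance_bp"],
    )
    return bound, table
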