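"""Multi-factor co-occupancy: binary peak matrix, Pearson/phi, UPGMA tree.

Rows of the binary matrix are the maximal merged intervals of the union of
all factors' peaks; entry (r, f) is 1 iff factor f has a peak sharing at
least one base with region r. Binding profiles are compared by Pearson
correlation of the binary columns (the phi coefficient) and clustered by
average linkage on distance d = 1 - r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree

from .genome import PeakSet

Region = Tuple[str, int, int]


@dataclass
class BinaryPeakMatrix:
    regions: List[Region]
    matrix: pd.DataFrame  # rows align with regions, columns are factors

    @property
    def factors(self) -> List[str]:
        return list(self.matrix.columns)


@dataclass
class CorrelationMatrix:
    values: pd.DataFrame  # factors x factors, NaN where undefined
    defined: pd.DataFrame  # boolean


@dataclass
class Dendrogram:
    labels: List[str]
    merges: np.ndarray  # scipy linkage matrix, heights in d = 1 - r units

    def cut(self, n_clusters: int) -> Dict[str, int]:
        flat = fcluster(self.merges, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def merge_union_regions(peak_sets: Sequence[PeakSet]) -> List[Region]:
    """Maximal merged intervals of the union of all peaks across factors."""
    intervals = sorted(
        (p.chrom, p.start, p.end) for ps in peak_sets for p in ps
    )
    if not intervals:
        raise ValueError("no peaks in any factor")
    merged: List[Region] = []
    cur_chrom, cur_start, cur_end = intervals[0]
    for chrom, start, end in intervals[1:]:
        if chrom == cur_chrom and start < cur_end:  # shared base required to merge
            cur_end = max(cur_end, end)
        else:
            merged.append((cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = chrom, start, end
    merged.append((cur_chrom, cur_start, cur_end))
    return merged


def build_binary_matrix(peak_sets: Sequence[PeakSet]) -> BinaryPeakMatrix:
    """Regions x factors 0/1 co-occupancy matrix over the union regions."""
    if len(peak_sets) < 2:
        raise ValueError("at least 2 factors required")
    names = [ps.factor for ps in peak_sets]
    if len(set(names)) != len(names):
        raise ValueError("factor labels must be unique")
    regions = merge_union_regions(peak_sets)
    starts: Dict[str, np.ndarray] = {}
    region_by_chrom: Dict[str, List[int]] = {}
    for i, (chrom, _s, _e) in enumerate(regions):
        region_by_chrom.setdefault(chrom, []).append(i)
    for chrom, idx in region_by_chrom.items():
        starts[chrom] = np.array([regions[i][1] for i in idx])

    data = np.zeros((len(regions), len(peak_sets)), dtype=int)
    for j, ps in enumerate(peak_sets):
        for p in ps:
            idx = region_by_chrom.get(p.chrom)
            if not idx:
                continue
            # regions are disjoint and sorted: the covering region is the
            # last one starting at or before p.start
            pos = int(np.searchsorted(starts[p.chrom], p.start, side="right")) - 1
            i = idx[pos]
            assert regions[i][1] <= p.start and p.end <= regions[i][2]
            data[i, j] = 1
    matrix = pd.DataFrame(data, columns=names)
    assert (matrix.sum(axis=1) >= 1).all()
    return BinaryPeakMatrix(regions=regions, matrix=matrix)


def pearson_matrix(bpm: BinaryPeakMatrix) -> CorrelationMatrix:
    """Pairwise Pearson correlation of the binary columns (phi coefficient).

    Cells involving a constant column are undefined (NaN) except the
    diagonal, which is 1 by convention.
    """
    if len(bpm.matrix) < 2:
        raise ValueError("at least 2 regions required")
    arr = bpm.matrix.to_numpy(dtype=float)
    constant = arr.std(axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    defined = ~np.isnan(corr)
    factors = bpm.factors
    return CorrelationMatrix(
        values=pd.DataFrame(corr, index=factors, columns=factors),
        defined=pd.DataFrame(defined, index=factors, columns=factors),
    )


def upgma_cluster(corr: CorrelationMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of factors on d = 1 - r."""
    factors = list(corr.values.columns)
    off_diag = ~np.eye(len(factors), dtype=bool)
    undefined = ~corr.defined.to_numpy() & off_diag
    if undefined.any():
        i = int(np.argwhere(undefined.any(axis=1))[0][0])
        raise ValueError(
            f"correlation undefined for factor {factors[i]!r} (constant binding column)"
        )
    if len(factors) < 2:
        raise ValueError("at least 2 factors required")
    d = 1.0 - corr.values.to_numpy()
    condensed = d[np.triu_indices(len(factors), k=1)]
    merges = linkage(condensed, method="average")
    return Dendrogram(labels=factors, merges=merges)


def to_newick(dend: Dendrogram) -> str:
    """Newick string with ultrametric branch lengths (height / 2 to leaves)."""
    tree = to_tree(dend.merges)

    def fmt(x: float) -> str:
        return f"{x:.10g}"

    # branch length from a node at height h_c to its parent at height h_p is
    # (h_p - h_c) / 2 under the half-height ultrametric convention;
    # children are ordered by their smallest leaf input index
    def render(node, parent_height) -> Tuple[str, int]:
        if node.is_leaf():
            return f"{dend.labels[node.id]}:{fmt(parent_height / 2)}", node.id
        (s1, m1), (s2, m2) = render(node.left, node.dist), render(node.right, node.dist)
        if m2 < m1:
            s1, s2, m1, m2 = s2, s1, m2, m1
        body = f"({s1},{s2})"
        if parent_height is None:
            return body, m1
        return f"{body}:{fmt((parent_height - node.dist) / 2)}", m1

    return render(tree, None)[0] + ";"


def write_matrix_tsv(bpm: BinaryPeakMatrix, path: str) -> None:
    out = bpm.matrix.copy()
    out.insert(0, "chrom", [r[0] for r in bpm.regions])
    out.insert(1, "start", [r[1] for r in bpm.regions])
    out.insert(2, "end", [r[2] for r in bpm.regions])
    out.to_csv(path, sep="\t", index=False)


def write_correlation_tsv(corr: CorrelationMatrix, path: str) -> None:
    corr.values.rename_axis("factor").to_csv(path, sep="\t")
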