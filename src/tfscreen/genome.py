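"""Genomic interval types and readers/writers for BED / GFF3 / side tables.

All coordinates are 0-based half-open internally. GFF3 (1-based closed) is
converted at the I/O boundary; BED is native. Genes carry strand and a
functional-class label; peaks are unstranded.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from intervaltree import IntervalTree

STRANDS = ("+", "-")


class ParseError(ValueError):
    """Malformed input file; message names the file and line number."""


@dataclass(frozen=True)
class GeneRecord:
    """A stranded gene-body interval with a functional-class label."""

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str
    func_class: str = "other"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """An unstranded binding interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"peak: require 0 <= start < end, got [{self.start}, {self.end})")


@dataclass
class PeakSet:
    """Ordered peaks for one factor."""

    factor: str
    peaks: List[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.factor:
            raise ValueError("factor label must be non-empty")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)


class GenomeAnnotation:
    """Gene records grouped by chromosome, queryable by window.

    Window queries return exactly the genes whose half-open interval
    intersects the half-open query window (shared base required; abutting
    intervals do not intersect).
    """

    def __init__(self, genes: Iterable[GeneRecord]):
        self._genes: List[GeneRecord] = list(genes)
        self._by_id: Dict[str, GeneRecord] = {}
        self._trees: Dict[str, IntervalTree] = {}
        for g in self._genes:
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene_id: {g.gene_id}")
            self._by_id[g.gene_id] = g
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    @property
    def genes(self) -> List[GeneRecord]:
        return list(self._genes)

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    @property
    def chroms(self) -> List[str]:
        return sorted(self._trees)

    def query(self, chrom: str, start: int, end: int) -> List[GeneRecord]:
        """Genes intersecting [start, end) on chrom, in positional order."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda g: (g.start, g.end, g.gene_id))
        return hits

    def with_func_class(self, mapping: Dict[str, str]) -> "GenomeAnnotation":
        """New annotation with func_class replaced from a gene_id -> label map."""
        return GenomeAnnotation(
            replace(g, func_class=mapping.get(g.gene_id, g.func_class)) for g in self._genes
        )


def interval_gap(a: Tuple[str, int, int], b: Tuple[str, int, int]) -> int:
    """Base-pair gap between two half-open intervals on the same chromosome.

    Zero iff the intervals overlap or abut. Accepts any objects with
    ``chrom``/``start``/``end`` attributes or ``(chrom, start, end)`` tuples.
    """
    ca, sa, ea = _as_triple(a)
    cb, sb, eb = _as_triple(b)
    if ca != cb:
        raise ValueError(f"interval_gap: different chromosomes ({ca!r} vs {cb!r})")
    return max(0, max(sa, sb) - min(ea, eb))


def _as_triple(x) -> Tuple[str, int, int]:
    if isinstance(x, tuple):
        return x
    return (x.chrom, x.start, x.end)


# ---------------------------------------------------------------------------
# Readers / writers


def read_bed(path: str, factor: Optional[str] = None) -> PeakSet:
    """Read a >=3-column BED file of peaks (0-based half-open, preserved).

    ``track``/``browser``/``#`` lines are skipped; record order is preserved.
    The factor label defaults to the file basename without extension.
    """
    if factor is None:
        factor = os.path.splitext(os.path.basename(path))[0]
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not (0 <= start < end):
                raise ParseError(f"{path}:{lineno}: require 0 <= start < end, got {start}, {end}")
            name = fields[3] if len(fields) > 3 else None
            peaks.append(Peak(chrom, start, end, name))
    return PeakSet(factor=factor, peaks=peaks)


def write_bed(peak_set: PeakSet, path: str, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        for i, p in enumerate(peak_set.peaks):
            name = p.name if p.name is not None else f"{peak_set.factor}_{i}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\n")


def read_gff3(path: str, feature_type: str = "gene") -> GenomeAnnotation:
    """Read gene records from a GFF3 file.

    Only rows of ``feature_type`` are loaded. 1-based closed GFF coordinates
    become internal 0-based half-open ``(start-1, end)``. gene_id is the
    ``ID`` attribute; ``func_class`` is taken from the attribute of that name
    when present, else "other".
    """
    genes: List[GeneRecord] = []
    seen: set = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-delimited columns, got {len(cols)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype != feature_type:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr = _parse_attributes(attrs)
            gene_id = attr.get("ID")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: missing ID attribute")
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            if strand not in STRANDS:
                raise ParseError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
            try:
                genes.append(
                    GeneRecord(
                        gene_id=gene_id,
                        chrom=chrom,
                        start=start1 - 1,
                        end=end1,
                        strand=strand,
                        func_class=attr.get("func_class", "other"),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return GenomeAnnotation(genes)


def write_gff3(annotation: GenomeAnnotation, path: str, header: Optional[str] = None) -> None:
    """Write genes as GFF3; internal (s, e) re-emits as 1-based (s+1, e)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        for g in annotation.genes:
            attrs = f"ID={g.gene_id};func_class={g.func_class}"
            fh.write(
                f"{g.chrom}\ttfscreen\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def _parse_attributes(attrs: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_func_class(path: str) -> Dict[str, str]:
    """Read a two-column TSV side table ``gene_id<TAB>func_class``."""
    mapping: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-delimited columns")
            if fields[0] == "gene_id":  # optional header
                continue
            mapping[fields[0]] = fields[1]
    return mapping


def write_func_class(mapping: Dict[str, str], path: str, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        fh.write("gene_id\tfunc_class\n")
        for gene_id, label in mapping.items():
            fh.write(f"{gene_id}\t{label}\n")
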