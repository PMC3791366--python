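"""Synthetic regulon simulator with planted ground truth.

Emulates the statistical structure of a two-genotype (wild-type vs
knockout) stimulation experiment read out by RNA-seq counts and factor
ChIP-seq peaks:

* a single-chromosome annotation with log-normal gene lengths and a
  configurable fraction of transcription-regulator genes;
* stimulus-induced genes present only in the wild-type genotype, plus a
  small genotype-independent induced set;
* factor peaks enriched within 50 kb of induced genes (default 39% bound)
  over a 17% background bound rate, plus far-from-gene decoy peaks;
* NB counts with planted log2 fold-changes and library-size variation;
* block-structured co-binding across multiple factors sharing a site pool.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .assign import AssignmentConfig, assign_peak
from .candidates import REGULATOR_CLASS
from .diffexpr import CountMatrix, SampleDesign, write_counts_tsv, write_design_tsv
from .genome import (
    GeneRecord,
    GenomeAnnotation,
    Peak,
    PeakSet,
    write_bed,
    write_func_class,
    write_gff3,
)


@dataclass
class CobindBlocks:
    """Planted co-binding structure: factor blocks over a shared site pool."""

    blocks: Dict[str, List[str]] = field(
        default_factory=lambda: {"blockA": ["TF1", "TF2"], "blockB": ["TF3", "TF4"]}
    )
    n_sites: int = 400
    site_len: int = 400
    within_rate: float = 0.8
    between_rate: float = 0.1

    def validate(self) -> None:
        if len(self.blocks) < 2 or any(len(v) < 1 for v in self.blocks.values()):
            raise ValueError("need >= 2 blocks with >= 1 factor each")
        if not (0 <= self.between_rate < self.within_rate <= 1):
            raise ValueError(
                "within_rate must exceed between_rate (blocks would not be recoverable)"
            )


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 500
    chrom: str = "chr1"
    chrom_len: int = 50_000_000
    gene_len_mean: float = 8.5  # natural-log scale (median ~4.9 kb)
    gene_len_sd: float = 0.8
    frac_regulators: float = 0.10
    n_induced_wt: int = 40
    n_induced_null: int = 5
    background_bound_rate: float = 0.17
    induced_bound_rate: float = 0.39
    lfc_range: Tuple[float, float] = (1.0, 3.0)
    dispersion: float = 0.1
    n_reps: int = 2
    baseline_mean_range: Tuple[float, float] = (20.0, 500.0)
    libsize_factor_range: Tuple[float, float] = (0.7, 1.4)
    decoy_frac: float = 0.10  # decoy peaks as a fraction of n_genes
    peak_len_range: Tuple[int, int] = (200, 1000)
    window_bp: int = 50_000
    cobind: CobindBlocks = field(default_factory=CobindBlocks)

    def validate(self) -> None:
        for name in ("frac_regulators", "background_bound_rate", "induced_bound_rate", "decoy_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_induced_wt + self.n_induced_null > self.n_genes:
            raise ValueError("n_induced_wt + n_induced_null must not exceed n_genes")
        if not (0 <= self.lfc_range[0] <= self.lfc_range[1]) or self.lfc_range[1] < 0:
            raise ValueError("lfc_range must be non-negative and ordered")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        self.cobind.validate()


@dataclass
class SimTruth:
    induced_wt: Set[str] = field(default_factory=set)
    induced_null: Set[str] = field(default_factory=set)
    bound: Set[str] = field(default_factory=set)
    planted_top_candidate: Optional[str] = None
    block_assignment: Dict[str, str] = field(default_factory=dict)
    baseline_mean: Dict[str, float] = field(default_factory=dict)
    log2fc: Dict[str, float] = field(default_factory=dict)
    n_decoys: int = 0

    def to_json(self, path: str) -> None:
        payload = {
            "induced_wt": sorted(self.induced_wt),
            "induced_null": sorted(self.induced_null),
            "bound": sorted(self.bound),
            "planted_top_candidate": self.planted_top_candidate,
            "block_assignment": self.block_assignment,
            "baseline_mean": self.baseline_mean,
            "log2fc": self.log2fc,
            "n_decoys": self.n_decoys,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            induced_wt=set(d["induced_wt"]),
            induced_null=set(d["induced_null"]),
            bound=set(d["bound"]),
            planted_top_candidate=d["planted_top_candidate"],
            block_assignment=d["block_assignment"],
            baseline_mean=d["baseline_mean"],
            log2fc=d["log2fc"],
            n_decoys=d["n_decoys"],
        )


@dataclass
class SimData:
    config: SimConfig
    annotation: GenomeAnnotation
    truth: SimTruth
    peaks: PeakSet
    counts: CountMatrix
    cobind_sets: List[PeakSet]


# ---------------------------------------------------------------------------
# Generators

# independent seed streams per generator so adding one stage never
# perturbs another stage's draws
_STREAM = {"annotation": 1, "truth": 2, "binding": 3, "counts": 4, "cobind": 5}


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stream], config.seed])


def make_annotation(config: SimConfig) -> GenomeAnnotation:
    """Non-overlapping genes on both strands with log-normal lengths."""
    config.validate()
    rng = _rng(config, "annotation")
    lengths = np.maximum(
        200, rng.lognormal(config.gene_len_mean, config.gene_len_sd, config.n_genes).astype(int)
    )
    if lengths.sum() * 2 > config.chrom_len:
        raise ValueError("chrom_len too small for n_genes; increase chrom_len")
    placed: List[Tuple[int, int]] = []
    starts = np.empty(config.n_genes, dtype=int)
    occupied_sorted: List[Tuple[int, int]] = []
    for i, L in enumerate(lengths):
        for attempt in range(1000):
            s = int(rng.integers(0, config.chrom_len - L))
            e = s + int(L)
            if not _overlaps_any(occupied_sorted, s, e):
                _insort(occupied_sorted, (s, e))
                starts[i] = s
                break
        else:
            raise ValueError("gene placement failed after bounded retries; increase chrom_len")
    strands = rng.choice(["+", "-"], size=config.n_genes)
    is_reg = rng.random(config.n_genes) < config.frac_regulators
    width = len(str(config.n_genes))
    genes = [
        GeneRecord(
            gene_id=f"g{i + 1:0{width}d}",
            chrom=config.chrom,
            start=int(starts[i]),
            end=int(starts[i] + lengths[i]),
            strand=str(strands[i]),
            func_class=REGULATOR_CLASS if is_reg[i] else "other",
        )
        for i in range(config.n_genes)
    ]
    return GenomeAnnotation(genes)


def _overlaps_any(sorted_ivals: List[Tuple[int, int]], s: int, e: int) -> bool:
    import bisect

    i = bisect.bisect_left(sorted_ivals, (s, e))
    if i > 0 and sorted_ivals[i - 1][1] > s:
        return True
    if i < len(sorted_ivals) and sorted_ivals[i][0] < e:
        return True
    return False


def _insort(sorted_ivals: List[Tuple[int, int]], iv: Tuple[int, int]) -> None:
    import bisect

    bisect.insort(sorted_ivals, iv)


def plant_induced_sets(annotation: GenomeAnnotation, config: SimConfig) -> SimTruth:
    """Choose disjoint wt-only and genotype-independent induced gene sets.

    Also designates the planted top candidate: one wt-induced gene whose
    functional class will be forced to transcription_regulator and which
    make_binding forces bound and make_counts makes the most abundant
    regulator-class induced gene.
    """
    rng = _rng(config, "truth")
    ids = [g.gene_id for g in annotation.genes]
    chosen = rng.choice(len(ids), size=config.n_induced_wt + config.n_induced_null, replace=False)
    induced_wt = {ids[i] for i in chosen[: config.n_induced_wt]}
    induced_null = {ids[i] for i in chosen[config.n_induced_wt:]}
    truth = SimTruth(induced_wt=induced_wt, induced_null=induced_null)
    if config.n_induced_wt > 0:
        truth.planted_top_candidate = ids[int(rng.choice(chosen[: config.n_induced_wt]))]
    return truth


def apply_candidate_class(annotation: GenomeAnnotation, truth: SimTruth) -> GenomeAnnotation:
    """Force the planted candidate's functional class to regulator."""
    if truth.planted_top_candidate is None:
        return annotation
    return annotation.with_func_class({truth.planted_top_candidate: REGULATOR_CLASS})


def make_binding(
    annotation: GenomeAnnotation, truth: SimTruth, config: SimConfig, factor: str = "TF"
) -> PeakSet:
    """Plant one recoverable peak per bound gene, plus far-from-gene decoys.

    Each gene is bound with probability ``induced_bound_rate`` if wt-induced
    else ``background_bound_rate``; the planted candidate is always bound.
    Peaks are placed within +/-50 kb of their source gene and re-drawn (or
    finally placed inside the gene body) until the assignment rule recovers
    the source gene, so truth.bound is a subset of the assigned bound set.
    Decoys are sampled from positions more than window_bp from every gene;
    if the eligible space is exhausted fewer decoys are emitted.
    """
    rng = _rng(config, "binding")
    genes = annotation.genes
    acfg = AssignmentConfig(window_bp=config.window_bp)
    bound_flags = {}
    for g in genes:
        rate = (
            config.induced_bound_rate
            if g.gene_id in truth.induced_wt
            else config.background_bound_rate
        )
        bound_flags[g.gene_id] = rng.random() < rate
    if truth.planted_top_candidate is not None:
        bound_flags[truth.planted_top_candidate] = True

    peaks: List[Peak] = []
    lo_len, hi_len = config.peak_len_range
    for g in genes:
        if not bound_flags[g.gene_id]:
            continue
        width = int(rng.integers(lo_len, hi_len + 1))
        peak = None
        for _ in range(50):
            lo = max(0, g.start - config.window_bp)
            hi = min(config.chrom_len - width, g.end + config.window_bp - width)
            s = int(rng.integers(lo, max(lo + 1, hi)))
            cand = Peak(g.chrom, s, s + width, name=f"peak_{g.gene_id}")
            a = assign_peak(cand, annotation, acfg)
            if g.gene_id in a.genes:
                peak = cand
                break
        if peak is None:
            # inside the gene body: gap 0 to the source, genes never overlap
            width = min(width, g.length_bp)
            s = g.start + int(rng.integers(0, g.length_bp - width + 1))
            peak = Peak(g.chrom, s, s + width, name=f"peak_{g.gene_id}")
        peaks.append(peak)
    truth.bound = {gid for gid, b in bound_flags.items() if b}

    n_decoys = int(round(config.decoy_frac * config.n_genes))
    decoys = _place_decoys(annotation, config, rng, n_decoys)
    truth.n_decoys = len(decoys)
    peaks.extend(decoys)
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return PeakSet(factor=factor, peaks=peaks)


def _place_decoys(
    annotation: GenomeAnnotation, config: SimConfig, rng: np.random.Generator, n: int
) -> List[Peak]:
    """Sample peaks whose gap to every gene exceeds window_bp."""
    margin = config.window_bp
    blocked = sorted((g.start - margin, g.end + margin) for g in annotation.genes)
    free: List[Tuple[int, int]] = []
    cursor = 0
    for s, e in blocked:
        if s > cursor:
            free.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < config.chrom_len:
        free.append((cursor, config.chrom_len))
    lo_len, _ = config.peak_len_range
    # a decoy must fit with strict clearance on both sides
    free = [(s + 1, e - 1) for s, e in free if (e - 1) - (s + 1) >= lo_len]
    if not free:
        return []
    sizes = np.array([e - s for s, e in free], dtype=float)
    out: List[Peak] = []
    for i in range(n):
        idx = int(rng.choice(len(free), p=sizes / sizes.sum()))
        s0, e0 = free[idx]
        width = int(rng.integers(config.peak_len_range[0], config.peak_len_range[1] + 1))
        width = min(width, e0 - s0)
        s = int(rng.integers(s0, e0 - width + 1))
        out.append(Peak(config.chrom, s, s + width, name=f"decoy_{i}"))
    return out


def make_counts(
    annotation: GenomeAnnotation, truth: SimTruth, config: SimConfig
) -> CountMatrix:
    """NB counts under the 2 genotype x 2 treatment x n_reps design.

    Planted log2 fold-changes apply to wt-induced genes in the wild-type
    stimulated samples only, and to genotype-independent induced genes in
    both genotypes' stimulated samples. The planted top candidate's
    baseline is set so that it dominates every other regulator-class
    induced gene in both mean and length-normalized (RPKM) terms.
    """
    config.validate()
    rng = _rng(config, "counts")
    genes = annotation.genes
    ids = [g.gene_id for g in genes]
    G = len(genes)

    lo, hi = config.baseline_mean_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=G))
    lfc = np.zeros(G)
    induced_any = [gid in truth.induced_wt or gid in truth.induced_null for gid in ids]
    for i, gid in enumerate(ids):
        if induced_any[i]:
            lfc[i] = rng.uniform(config.lfc_range[0], config.lfc_range[1])

    if truth.planted_top_candidate is not None:
        # the anchor emulates a robustly induced, highly abundant regulator:
        # strongest planted fold-change, and baseline chosen to dominate every
        # other regulator-class gene in both mean and per-kilobase (RPKM) terms
        cand_i = ids.index(truth.planted_top_candidate)
        lfc[cand_i] = config.lfc_range[1]
        lengths = np.array([g.length_bp for g in genes], dtype=float)
        rivals = [
            i
            for i, g in enumerate(genes)
            if g.func_class == REGULATOR_CLASS and i != cand_i
        ]
        target = baseline.max()
        if rivals:
            max_density = max(baseline[i] / lengths[i] for i in rivals)
            target = max(target, 2.0 * max_density * lengths[cand_i])
        baseline[cand_i] = 1.5 * target

    truth.baseline_mean = {gid: float(b) for gid, b in zip(ids, baseline)}
    truth.log2fc = {gid: float(f) for gid, f in zip(ids, lfc) if f != 0.0}

    design: List[SampleDesign] = []
    for genotype in ("wt", "null"):
        for treatment in ("untreated", "stimulated"):
            for r in range(config.n_reps):
                design.append(SampleDesign(f"{genotype}_{treatment}_{r + 1}", genotype, treatment))
    f_lo, f_hi = config.libsize_factor_range
    libfac = np.exp(rng.uniform(np.log(f_lo), np.log(f_hi), size=len(design)))

    mu = np.empty((G, len(design)))
    for j, s in enumerate(design):
        fold = np.ones(G)
        if s.treatment == "stimulated":
            for i, gid in enumerate(ids):
                if gid in truth.induced_null or (gid in truth.induced_wt and s.genotype == "wt"):
                    fold[i] = 2.0 ** lfc[i]
        mu[:, j] = baseline * fold * libfac[j]

    a = config.dispersion
    if a < 1e-6:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / a
        counts = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(counts, index=pd.Index(ids, name="gene_id"), columns=[s.sample_id for s in design])
    return CountMatrix(df, design)


def make_cobinding_sets(config: SimConfig) -> Tuple[List[PeakSet], Dict[str, str]]:
    """Block-structured factor peak sets over a shared site pool.

    Every candidate site is owned by one block; a factor carries a peak at
    a site with the within rate if it belongs to the owning block, else
    with the (lower) between rate.
    """
    cb = config.cobind
    cb.validate()
    rng = _rng(config, "cobind")
    n = cb.n_sites
    gap = cb.site_len  # disjoint sites separated by one site length
    starts = np.arange(n) * (cb.site_len + gap)
    block_names = list(cb.blocks)
    owners = rng.choice(len(block_names), size=n)
    block_assignment = {f: b for b in block_names for f in cb.blocks[b]}
    sets: List[PeakSet] = []
    for b_idx, b in enumerate(block_names):
        for factor in cb.blocks[b]:
            rate = np.where(owners == b_idx, cb.within_rate, cb.between_rate)
            take = rng.random(n) < rate
            peaks = [
                Peak("chrC", int(s), int(s + cb.site_len), name=f"site_{i}")
                for i, (s, t) in enumerate(zip(starts, take))
                if t
            ]
            sets.append(PeakSet(factor=factor, peaks=peaks))
    return sets, block_assignment


def simulate(config: Optional[SimConfig] = None) -> SimData:
    """Run every generator in order and return the full planted dataset."""
    config = config or SimConfig()
    config.validate()
    annotation = make_annotation(config)
    truth = plant_induced_sets(annotation, config)
    annotation = apply_candidate_class(annotation, truth)
    peaks = make_binding(annotation, truth, config)
    counts = make_counts(annotation, truth, config)
    cobind_sets, block_assignment = make_cobinding_sets(config)
    truth.block_assignment = block_assignment
    return SimData(
        config=config,
        annotation=annotation,
        truth=truth,
        peaks=peaks,
        counts=counts,
        cobind_sets=cobind_sets,
    )


def write_fixtures(data: SimData, outdir: str) -> Dict[str, str]:
    """Write GFF3 + BED + counts/design TSV + func_class TSV + truth JSON."""
    os.makedirs(outdir, exist_ok=True)
    header = f"tfscreen-simulate seed={data.config.seed}"
    paths = {
        "annotation": os.path.join(outdir, "genes.gff3"),
        "peaks": os.path.join(outdir, "peaks.bed"),
        "counts": os.path.join(outdir, "counts.tsv"),
        "design": os.path.join(outdir, "design.tsv"),
        "func_class": os.path.join(outdir, "func_class.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_gff3(data.annotation, paths["annotation"], header=header)
    write_bed(data.peaks, paths["peaks"], header=header)
    write_counts_tsv(data.counts, paths["counts"], header=header)
    write_design_tsv(data.counts.design, paths["design"], header=header)
    write_func_class(
        {g.gene_id: g.func_class for g in data.annotation.genes},
        paths["func_class"],
        header=header,
    )
    data.truth.to_json(paths["truth"])
    for factor_set in data.cobind_sets:
        p = os.path.join(outdir, f"cobind_{factor_set.factor}.bed")
        write_bed(factor_set, p, header=header)
        paths[f"cobind_{factor_set.factor}"] = p
    return paths
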