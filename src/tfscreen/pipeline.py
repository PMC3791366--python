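"""End-to-end orchestration: DE -> binding -> enrichment -> candidates (-> co-binding).

A declarative config (YAML or constructed in Python) names the input
files; the pipeline runs differential calling per genotype, peak-to-gene
assignment, the three overlap enrichment queries (wt-induced, null-induced
and wt-downregulated vs the bound set), candidate selection, and — when at
least two factor BED files are listed — the co-binding clustering stage.
All stage outputs are written as TSV/JSON with a provenance header, and a
machine-readable report summarizes every stage.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import yaml

from . import __version__
from .assign import AssignmentConfig, bound_genes
from .candidates import expression_summary, select_candidates
from .cobinding import (
    build_binary_matrix,
    pearson_matrix,
    to_newick,
    upgma_cluster,
    write_correlation_tsv,
    write_matrix_tsv,
)
from .diffexpr import DEConfig, call_de, genes_with_call, read_counts_tsv
from .enrich import enrichment_to_dict, overlap_report, venn_partition
from .genome import read_bed, read_func_class, read_gff3


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    annotation: str = ""
    counts: str = ""
    design: str = ""
    func_class: Optional[str] = None
    peaks: str = ""  # single-factor BED driving the binding stage
    cobind_factors: Dict[str, str] = field(default_factory=dict)  # name -> BED path
    outdir: str = "results"
    window_bp: int = 50_000
    alpha: float = 0.05
    min_total_count: int = 1
    require_bound: bool = False
    exclude_null_induced: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for label, p in [("annotation", self.annotation), ("counts", self.counts),
                         ("design", self.design), ("peaks", self.peaks)]:
            if not p:
                raise ConfigError(f"config field {label!r} is required")
            if not os.path.exists(p):
                raise ConfigError(f"{label} file not found: {p}")
        if self.func_class and not os.path.exists(self.func_class):
            raise ConfigError(f"func_class file not found: {self.func_class}")
        for name, p in self.cobind_factors.items():
            if not os.path.exists(p):
                raise ConfigError(f"co-binding BED for factor {name!r} not found: {p}")

    def content_hash(self) -> str:
        # outdir is a run location, not an analytic parameter
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "outdir"},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute every stage; returns the report dict (also written to disk)."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)
    header = f"tfscreen {__version__} config={config.content_hash()} seed={config.seed}"

    # ---------------- inputs
    try:
        annotation = read_gff3(config.annotation)
        if config.func_class:
            annotation = annotation.with_func_class(read_func_class(config.func_class))
        counts = read_counts_tsv(config.counts, config.design)
        peak_set = read_bed(config.peaks)
    except Exception as exc:
        raise PipelineError("load_inputs", str(exc)) from exc

    # ---------------- differential expression per genotype
    de_cfg = DEConfig(alpha=config.alpha, min_total_count=config.min_total_count)
    try:
        de_wt = call_de(counts, "wt", de_cfg)
        de_null = call_de(counts, "null", de_cfg)
    except Exception as exc:
        raise PipelineError("diffexpr", str(exc)) from exc
    _write_tsv(de_wt, out("de_wt.tsv"), header)
    _write_tsv(de_null, out("de_null.tsv"), header)

    induced_wt = genes_with_call(de_wt, "up")
    induced_null = genes_with_call(de_null, "up")
    down_wt = genes_with_call(de_wt, "down")

    # ---------------- binding
    try:
        bound, audit = bound_genes(peak_set, annotation, AssignmentConfig(config.window_bp))
    except Exception as exc:
        raise PipelineError("peak_assignment", str(exc)) from exc
    _write_tsv(audit, out("assignments.tsv"), header)
    with open(out("bound_genes.txt"), "w") as fh:
        fh.write(f"#{header}\n")
        fh.writelines(f"{g}\n" for g in sorted(bound))

    # ---------------- enrichment: universe = genes that entered DE testing
    universe = set(de_wt.loc[de_wt["tested"], "gene_id"])
    try:
        queries = {
            "induced_wt_vs_bound": overlap_report(induced_wt, bound, universe),
            "induced_null_vs_bound": overlap_report(induced_null, bound, universe),
            "down_wt_vs_bound": overlap_report(down_wt, bound, universe),
        }
        venn = venn_partition(induced_wt, induced_null, bound & universe)
    except Exception as exc:
        raise PipelineError("enrichment", str(exc)) from exc
    with open(out("enrichment.json"), "w") as fh:
        json.dump({k: enrichment_to_dict(v) for k, v in queries.items()}, fh, indent=1)
    with open(out("venn.tsv"), "w") as fh:
        fh.write(f"#{header}\n#A=induced_wt B=induced_null C=bound\nregion\tcount\n")
        for name, value in venn.__dict__.items():
            fh.write(f"{name}\t{value}\n")

    # ---------------- candidates
    try:
        expr = expression_summary(counts, annotation)
        cand = select_candidates(
            de_wt,
            de_null,
            bound,
            annotation,
            expr,
            require_bound=config.require_bound,
            exclude_null_induced=config.exclude_null_induced,
        )
    except Exception as exc:
        raise PipelineError("candidates", str(exc)) from exc
    _write_tsv(cand, out("candidates.tsv"), header)

    # ---------------- optional co-binding
    cobind_summary = None
    if len(config.cobind_factors) >= 2:
        try:
            sets = [read_bed(p, factor=name) for name, p in config.cobind_factors.items()]
            bpm = build_binary_matrix(sets)
            corr = pearson_matrix(bpm)
            dend = upgma_cluster(corr)
            newick = to_newick(dend)
        except Exception as exc:
            raise PipelineError("cobinding", str(exc)) from exc
        write_matrix_tsv(bpm, out("cobind_matrix.tsv"))
        write_correlation_tsv(corr, out("cobind_correlation.tsv"))
        with open(out("cobind_tree.nwk"), "w") as fh:
            fh.write(newick + "\n")
        cobind_summary = {
            "n_factors": len(sets),
            "n_regions": len(bpm.regions),
            "newick": newick,
        }

    report = {
        "tool_version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "input_checksums": {
            "annotation": _checksum(config.annotation),
            "counts": _checksum(config.counts),
            "design": _checksum(config.design),
            "peaks": _checksum(config.peaks),
        },
        "set_sizes": {
            "universe": len(universe),
            "induced_wt": len(induced_wt),
            "induced_null": len(induced_null),
            "down_wt": len(down_wt),
            "bound": len(bound),
        },
        "venn": dict(venn.__dict__),
        "enrichment": {k: enrichment_to_dict(v) for k, v in queries.items()},
        "n_candidates": int(len(cand)),
        "top_candidates": cand["gene_id"].head(5).tolist(),
        "cobinding": cobind_summary,
    }
    with open(out("report.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def _write_tsv(df, path: str, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#{header}\n")
        df.to_csv(fh, sep="\t", index=False)
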