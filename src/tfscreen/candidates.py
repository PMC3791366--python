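"""Candidate effector selection: induction x binding x function, ranked by RPKM.

Genes induced in the wild-type genotype are filtered to the
transcription-regulator class (optionally also requiring binding and
excluding genotype-independent responders) and ranked by baseline
abundance in RPKM — reads per kilobase of gene per million mapped reads —
in the unstimulated reference condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Set, Tuple

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix, genes_with_call
from .genome import GenomeAnnotation

REGULATOR_CLASS = "transcription_regulator"


def rpkm(count: float, gene_length: int, library_size: float) -> float:
    """count / ((gene_length/1e3) * (library_size/1e6))."""
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count / ((gene_length / 1e3) * (library_size / 1e6))


@dataclass
class ExpressionSummary:
    """Per-gene mean RPKM per (genotype, treatment) condition."""

    table: pd.DataFrame  # index gene_id, one column per "genotype:treatment"
    baseline_condition: Tuple[str, str]

    @property
    def baseline_rpkm(self) -> pd.Series:
        g, t = self.baseline_condition
        return self.table[f"{g}:{t}"].rename("baseline_rpkm")


def expression_summary(
    counts: CountMatrix,
    annotation: GenomeAnnotation,
    baseline_condition: Tuple[str, str] = ("wt", "untreated"),
) -> ExpressionSummary:
    """Per-condition mean of per-sample RPKM.

    library_size of a sample is its total assigned counts. Genes absent
    from the annotation are an error listing the offenders.
    """
    missing = [g for g in counts.gene_ids if g not in annotation]
    if missing:
        raise ValueError(f"genes missing from annotation: {missing[:10]}" + ("..." if len(missing) > 10 else ""))
    lengths = np.array([annotation[g].length_bp for g in counts.gene_ids], dtype=float)
    arr = counts.counts.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have positive total counts")
    per_sample = arr / (lengths[:, None] / 1e3) / (lib[None, :] / 1e6)
    cols = {}
    conditions = [(s.genotype, s.treatment) for s in counts.design]
    for cond in dict.fromkeys(conditions):
        sel = np.array([c == cond for c in conditions])
        cols[f"{cond[0]}:{cond[1]}"] = per_sample[:, sel].mean(axis=1)
    table = pd.DataFrame(cols, index=pd.Index(counts.gene_ids, name="gene_id"))
    key = f"{baseline_condition[0]}:{baseline_condition[1]}"
    if key not in table.columns:
        raise ValueError(f"baseline condition {baseline_condition} not present in the design")
    return ExpressionSummary(table=table, baseline_condition=baseline_condition)


def select_candidates(
    de_wt: pd.DataFrame,
    de_null: pd.DataFrame,
    bound: Set[str],
    annotation: GenomeAnnotation,
    expression: ExpressionSummary,
    require_bound: bool = False,
    exclude_null_induced: bool = False,
    regulator_class: str = REGULATOR_CLASS,
) -> pd.DataFrame:
    """Candidate table: induced-in-wt regulator-class genes ranked by RPKM.

    Base filter: called up in the wild-type contrast AND functional class
    ``regulator_class``. ``require_bound`` additionally demands membership
    in the bound set; ``exclude_null_induced`` drops genes also called up
    in the knockout genotype. Survivors are sorted by baseline RPKM
    descending (ties by gene_id) and ranked from 1.
    """
    induced_wt = genes_with_call(de_wt, "up")
    induced_null = genes_with_call(de_null, "up")
    baseline = expression.baseline_rpkm

    rows = []
    for gene_id in sorted(induced_wt):
        if gene_id not in annotation or annotation[gene_id].func_class != regulator_class:
            continue
        if require_bound and gene_id not in bound:
            continue
        if exclude_null_induced and gene_id in induced_null:
            continue
        rows.append(
            {
                "gene_id": gene_id,
                "induced_wt": True,
                "induced_null": gene_id in induced_null,
                "bound": gene_id in bound,
                "func_class": annotation[gene_id].func_class,
                "baseline_rpkm": float(baseline.get(gene_id, 0.0)),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "induced_wt", "induced_null", "bound", "func_class", "baseline_rpkm"],
    )
    if table.empty:
        import warnings

        warnings.warn("candidate selection produced an empty table", stacklevel=2)
        table["rank"] = pd.Series(dtype=int)
        return table
    table = table.sort_values(
        ["baseline_rpkm", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
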