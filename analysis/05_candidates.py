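#!/usr/bin/env python
"""Select and rank candidate effectors of the signalling input.

Wild-type-induced genes of the transcription-regulator class, ranked by
baseline abundance (mean RPKM in the unstimulated wild-type condition).
The top of the table is the best candidate effector; with planted data it
should be the simulation's anchor gene.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from tfscreen.candidates import expression_summary, select_candidates
from tfscreen.diffexpr import read_counts_tsv
from tfscreen.genome import read_func_class, read_gff3

SIM = os.path.join(os.path.dirname(__file__), "..", "scratch", "simulated")
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")

annotation = read_gff3(os.path.join(SIM, "genes.gff3")).with_func_class(
    read_func_class(os.path.join(SIM, "func_class.tsv"))
)
cm = read_counts_tsv(os.path.join(SIM, "counts.tsv"), os.path.join(SIM, "design.tsv"))
de_wt = pd.read_csv(os.path.join(RESULTS, "02_de_wt.tsv"), sep="\t")
de_null = pd.read_csv(os.path.join(RESULTS, "02_de_null.tsv"), sep="\t")
bound = {l.strip() for l in open(os.path.join(RESULTS, "03_bound_genes.txt")) if l.strip()}

table = select_candidates(
    de_wt, de_null, bound, annotation, expression_summary(cm, annotation)
)
table.to_csv(os.path.join(RESULTS, "05_candidates.tsv"), sep="\t", index=False)

print(f"{len(table)} candidate regulators (induced in wt, transcription-regulator class)")
print(table.head(5).to_string(index=False))
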