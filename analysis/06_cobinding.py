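#!/usr/bin/env python
"""Cluster factors by their genome-wide binding profiles.

Binary co-occupancy matrix over the merged union regions of all factors'
peaks, pairwise Pearson (phi) correlation, UPGMA tree on d = 1 - r.
Cutting the tree into two clusters should recover the planted blocks.
"""

import os
import sys
from glob import glob

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from tfscreen.cobinding import (
    build_binary_matrix,
    pearson_matrix,
    to_newick,
    upgma_cluster,
    write_correlation_tsv,
    write_matrix_tsv,
)
from tfscreen.genome import read_bed

SIM = os.path.join(os.path.dirname(__file__), "..", "scratch", "simulated")
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")

beds = sorted(glob(os.path.join(SIM, "cobind_*.bed")))
sets = [read_bed(p, factor=os.path.basename(p)[len("cobind_"):-len(".bed")]) for p in beds]

bpm = build_binary_matrix(sets)
corr = pearson_matrix(bpm)
dend = upgma_cluster(corr)
newick = to_newick(dend)

write_matrix_tsv(bpm, os.path.join(RESULTS, "06_cobind_matrix.tsv"))
write_correlation_tsv(corr, os.path.join(RESULTS, "06_cobind_correlation.tsv"))
with open(os.path.join(RESULTS, "06_cobind_tree.nwk"), "w") as fh:
    fh.write(newick + "\n")

print(f"{len(sets)} factors over {len(bpm.regions)} union regions")
print("pairwise Pearson (phi):")
print(corr.values.round(3).to_string())
print(f"UPGMA tree: {newick}")
print(f"2-cluster cut: {dend.cut(2)}")
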