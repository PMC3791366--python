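#!/usr/bin/env python
"""Overlap the induction calls with the bound set (Venn + hypergeometric tails).

Expected pattern: binding strongly over-represented among wild-type-induced
genes, and not over-represented among knockout-induced or repressed genes.
"""

import json
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from tfscreen.enrich import enrichment_to_dict, overlap_report, venn_partition

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")

de_wt = pd.read_csv(os.path.join(RESULTS, "02_de_wt.tsv"), sep="\t")
de_null = pd.read_csv(os.path.join(RESULTS, "02_de_null.tsv"), sep="\t")
bound = {l.strip() for l in open(os.path.join(RESULTS, "03_bound_genes.txt")) if l.strip()}

universe = set(de_wt.loc[de_wt["tested"], "gene_id"])
sets = {
    "induced_wt": set(de_wt.loc[de_wt["call"] == "up", "gene_id"]),
    "induced_null": set(de_null.loc[de_null["call"] == "up", "gene_id"]),
    "down_wt": set(de_wt.loc[de_wt["call"] == "down", "gene_id"]),
}

report = {}
for name, genes in sets.items():
    r = overlap_report(genes, bound, universe)
    report[name] = enrichment_to_dict(r)
    print(f"{name}: {r.k}/{r.n} bound ({r.percent:.1f}%; background {100 * r.K / r.N:.1f}%) "
          f"p_over={r.p_over:.3g} p_under={r.p_under:.3g}")

venn = venn_partition(sets["induced_wt"], sets["induced_null"], bound & universe)
report["venn_induced_wt__induced_null__bound"] = venn.__dict__

with open(os.path.join(RESULTS, "04_enrichment.json"), "w") as fh:
    json.dump(report, fh, indent=1)
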