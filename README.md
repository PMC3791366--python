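# tfscreen

Identify transcription-factor effectors downstream of a signalling input
by intersecting genotype-resolved differential induction with factor
binding, then ranking candidates by abundance.

The screen targets a classic regulatory-genomics design: a cytokine (or
other stimulus) acts through a transcription factor; cells carrying a
knockout of that factor reveal which acutely induced genes require it.
Intersecting the induced genes with the factor's ChIP-seq binding map
yields putative *direct* targets, and among those, highly expressed
transcription regulators are the best candidate effectors. `tfscreen`
implements every computational step of that screen, plus a synthetic
regulon simulator with planted ground truth so the whole chain is
testable end to end.

## The statistics at the core

* **Induction calling** — counts are modelled NB(µ, α) with µ_j = s_j·q
  (s_j: median-of-ratios size factors). A likelihood-ratio test compares
  a shared concentration q against per-treatment concentrations, with
  Λ = 2(ℓ_alt − ℓ_null) ~ χ²(1) and per-gene moment dispersion pooled
  with the across-genes median. Genes pass Benjamini–Hochberg step-up
  selection at adjusted P < 0.05.
* **Peak-to-gene assignment** — each peak is assigned up to two genes:
  the most proximal gene on each strand within 50 kb (edge-to-edge gap;
  an overlapped gene always wins on its strand).
* **Overlap enrichment** — for a query set of n genes with k bound among
  a universe of N containing K bound genes, the exact one-sided
  hypergeometric tails P(X ≥ k) / P(X ≤ k) measure over/under-
  representation (computed in log space).
* **Candidate ranking** — RPKM = count / ((length/10³)·(library/10⁶));
  induced transcription-regulator genes are ranked by baseline RPKM.
* **Co-binding clustering** — a binary regions × factors co-occupancy
  matrix over merged union regions, pairwise Pearson/phi correlation, and
  UPGMA on d = 1 − r, exported as an ultrametric Newick tree.

## Worked example

Generate a synthetic dataset and run the screen (seed 1):

```sh
python analysis/01_simulate.py 1
python analysis/02_differential_expression.py
python analysis/03_peak_assignment.py
python analysis/04_enrichment.py
python analysis/05_candidates.py
python analysis/06_cobinding.py
```

which prints (abridged):

```
simulated 500 genes (seed 1): 40 wt-induced, 5 genotype-independent, 87 bound,
  137 peaks (50 decoys); planted top candidate g059
wt: 28 induced, 0 repressed (of 500 tested genes at BH-adjusted P < 0.05)
null: 3 induced, 0 repressed (of 500 tested genes at BH-adjusted P < 0.05)
137 peaks -> 124 peak-gene links -> 118 bound genes (23.6% of 500 annotated genes)
induced_wt: 10/28 bound (35.7%; background 23.6%) p_over=0.096
3 candidate regulators (induced in wt, transcription-regulator class)
gene_id  induced_wt  induced_null  bound              func_class  baseline_rpkm  rank
   g059        True         False   True transcription_regulator    5571.336547     1
UPGMA tree: ((TF1:0.28,TF2:0.28):0.48,(TF3:0.27,TF4:0.27):0.49);
2-cluster cut: {'TF1': 2, 'TF2': 2, 'TF3': 1, 'TF4': 1}
```

Reading the output: the knockout abolishes most induction (28 induced
genes in wild-type vs 3 in the knockout), the planted anchor gene `g059`
is recovered as the top-ranked candidate (it is induced, bound, a
transcription regulator, and by far the most abundant at baseline), and
the two planted co-binding blocks {TF1, TF2} and {TF3, TF4} fall out of
the dendrogram cut. The induced-vs-bound over-representation
(35.7% bound among induced vs 23.6% background) lands at p_over = 0.096
for this particular seed — with only ~28 induced genes the overlap count
is small, and across many seeds the contrast is significant in roughly
nine runs out of ten (see the recovery rates below).

The same screen runs from a YAML config via the CLI
(`tfscreen run-all --config run.yaml`), and every stage is exposed as a
subcommand (`simulate`, `de`, `assign`, `enrich`, `candidates`,
`cobind`).

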