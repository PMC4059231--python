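# telenhancer

Genome-wide analysis of **tele-enhancers** — enhancers separated from
their target gene by at least one intermediate ("bystander") gene or exon
— versus **proximal** enhancers that sit inside or immediately beside
their target's locus.

The package is aimed at regulatory-genomics analysts who have an enhancer
map (p300 / H3K4me1 ChIP-seq peaks, ChromHMM segments) and a tissue
expression matrix, and want to know whether distally acting enhancers
differ from locus-resident ones in targets, motif grammar, and selective
history. It provides:

- **Assignment** — each enhancer links to its nearest tissue gene on each
  side within 500 kb; a link is *tele* iff a non-tissue gene or exon lies
  between enhancer and target TSS. Target genes partition into GeneP
  (≥1 proximal enhancer) and GeneT (tele-only).
- **Link validation** — two null models: containment of enhancers in
  DHS-based regulatory blocks (binomial test against a length-matched
  random-gene null) and depletion of evolutionary synteny breakpoints
  between enhancer and target (Poisson test against a local ±500 kb
  expectation).
- **Evolutionary constraint** — from human–chimp–macaque alignments,
  lineage-specific divergence by outlier attribution with Jukes–Cantor
  correction, the Neutrality Index
  `NI = (Dh/Nh) / ((Dc+Dm)/(Nc+Nm))` against a pseudogene neutral
  reference (NI < 1: purifying selection on the human lineage), and
  McDonald–Kreitman Fisher exact tests, class-level and per element.
- **Polymorphism** — SNPs per alignable kb and the derived-allele-
  frequency spectrum, with low-DAF (< 0.05) excess as the signature of
  ongoing purifying selection.
- **Motif signatures** — PWM scanning (log-odds, both strands), per-kb
  hit-count features, soft-margin linear SVMs separating each enhancer
  class from matched controls, per-motif enrichment folds, and the
  shared/specific positive-weight motif comparison between classes.
- **Function** — hypergeometric GO enrichment (upper tail, Bonferroni)
  with locus-length-matched control genes, and relative-expression
  contrasts between GeneT and GeneP.
- **Synthetic data** — a generator that emits every input format on a toy
  genome with known planted parameters, so the whole pipeline runs and is
  tested end-to-end with no downloads.

## Worked example

Run the full pipeline on the default synthetic dataset (200 enhancers,
half tele, on a 2×8 Mb toy genome):

```python
from telenhancer import RunConfig, run

report = run(RunConfig(outdir="demo_run", seed=1))
print(open("demo_run/summary_table.tsv").read())
```

which prints (seed 1):

```
class	human_specific_per_kb	nonhuman_specific_per_kb	NI	mk_p	snps_per_kb
proximal	5.38	56.55	0.74	6.961515341010909e-06	5.6
tele	5.58	56.35	0.78	7.486367574060607e-05	5.62
neutral	9.12	71.38	1.0		10.0
control	6.01	58.02	0.81	8.019143202362878e-05	6.15
hacns	17.24	27.55	4.9	2.6571108695356394e-80	3.92
```

Reading the table: both enhancer classes diverge far more slowly than the
pseudogene neutral reference (≈5.5 vs 9.1 human-specific substitutions
per kb) and carry NI well below 1 with significant MK p-values —
purifying selection on the human lineage — while the human-accelerated
control class (hacns) shows the opposite signature (NI ≈ 5). SNP
densities echo the divergence ordering. The run directory also contains
`links.tsv`, `validation.tsv` (82%-style block containment and breakpoint
depletion), `motifs.tsv` (SVM weights and enrichment folds per class —
the planted tele-specific and proximal-specific motifs rank at the top of
their own class), `go_enrichment.tsv` and `report.json`. The numbers are
estimates from a small simulated genome and move within sampling noise
across seeds; the planted class parameters are listed in
`demo_run/inputs/truth.json`.

The same run is available from the shell:

```sh
telenhancer run --seed 1 --outdir demo_run
telenhancer report demo_run
```

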