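# Methods

## The question and the objects

A *tele-enhancer* is an enhancer separated from its target gene by at
least one intermediate ("bystander") gene or exon; a *proximal* enhancer
sits inside its target's locus or in the clean flanking intergenic
interval. Given a genome-wide enhancer map and a ranking of tissue genes,
the pipeline (i) assigns every enhancer to its nearest tissue gene on each
side within a linking window, (ii) labels each link tele or proximal from
the intervening annotation, (iii) partitions target genes into GeneP (at
least one proximal enhancer) and GeneT (tele links only), and (iv)
contrasts the two enhancer classes on motif composition, evolutionary
constraint, polymorphism and target-gene function.

## Assignment rules

- Tissue genes are the top fraction (default 20%) of genes by *relative
  expression* — expression in the target tissue divided by the mean over
  the tissue panel — unioned with an annotated development gene list.
  Ties at the cutoff are all kept.
- Each enhancer links to at most two tissue genes, the nearest whose TSS
  lies upstream and the nearest downstream, within `max_link_distance`
  (default 500 kb). Distance is measured from the TSS to the nearest
  enhancer edge ("midpoint" mode is available); the edge convention is the
  conservative one when the enhancer is wide.
- A link is tele iff the open interval between the enhancer and the target
  TSS contains a non-target gene body or exon. The evidence scope defaults
  to non-tissue genes only (the published tele definition for a
  tissue-restricted gene set names non-tissue intermediates); a
  `non_target` scope that counts any intermediate gene is a flag. All
  exons count, UTR or coding — the annotation used here does not separate
  them.
- Enhancer-level class: proximal wins when links disagree (an element with
  a same-locus target is not tele). Equidistant candidates on one side
  resolve to the lexicographically smaller gene id, making assignment
  fully deterministic.

## Null models for link validation

**DHS regulatory-block containment.** A gene's block spans from its TSS to
the most distal DNase-I hypersensitive site connected to it on each side.
The observed statistic is the fraction of links whose enhancer midpoint
falls inside its gene's block. The null replays each link's signed
TSS-to-enhancer offset against 20 random genes whose block length lies
within ±10% of the tested gene's (widened once to ±20% when no candidate
exists); the expectation averages over all draws, and the p-value is the
upper binomial tail of the observed count at that rate.

The pooled binomial is exactly calibrated only when links are
exchangeable. Two realistic departures make it conservative, which we
verified by simulation: heterogeneous link distances give the observed
count a Poisson-binomial distribution with smaller variance than the
binomial bound (measured type-I ≈ 0.006 at α = 0.05), and with
variable-length blocks the length-matched draws correlate with the tested
gene's own geometry (type-I ≈ 0.02). The calibration study in
`simulate_dhs_null` therefore uses exchangeable geometry — fixed
link-distance magnitude with random side, constant block length with the
TSS placed uniformly inside — where the measured type-I error is ≈ 0.04.
On real data the test errs toward caution, never anti-conservatism.

**Synteny-breakpoint density.** Rearrangement breakpoints should be
depleted between an enhancer and its true target. Observed density is
breakpoints per noncoding kb in the separating interval, pooled per
class; the local expectation comes from a ±500 kb extension of each
interval with exonic bp excluded (exons proxy coding sequence; a
CDS-restricted mode can be added when CDS annotation is present). The
p-value is the lower Poisson tail of the pooled observed count at the
expected rate — counts, not Bernoulli trials, hence Poisson rather than
binomial here.

## Divergence, Neutrality Index and the MK test

From human–chimp–macaque alignments, columns with a gap or N in any row
are dropped; the remainder is the alignable length La. A substitution is
attributed to the single species that disagrees with the other two;
columns where all three differ carry no parsimony-unambiguous branch and
are dropped from the outlier counts. Per-site differences d = L/La are
corrected for multiple hits with Jukes–Cantor,
D = −(3/4)·ln(1 − (4/3)d), defined for d < 0.75.

The Neutrality Index of a region against a neutral reference
(pooled pseudogene alignments) is

    NI = (Dh / Nh) / ((Dc + Dm) / (Nc + Nm)),

NI < 1 indicating purifying and NI > 1 positive selection on the human
lineage. Significance uses a McDonald–Kreitman-style Fisher exact test on
the raw outlier counts `[[element Lh, element Lc+Lm], [neutral Lh,
neutral Lc+Lm]]` — the published analysis reports rates, but Fisher's
exact needs counts, so the contingency is built from counts with the
alignable lengths implicit in the margins. Per-element selection labels
use the one-sided p in the observed direction at α = 1e-4 (default),
against the same pooled neutral reference for every element; per-element
neutral matching is not attempted.

The outlier-attribution estimator is mildly biased downward: a human
substitution is only counted when chimp equals macaque, so the expected
measured rate is ≈ p_h(1−p_c)(1−p_m) plus two smaller terms (both
nonhuman lineages hitting the same base, and three-hit coincidences). At
primate-scale rates this bias is below 7% of p_h and under two binomial
standard errors at La = 1e5. The acceptance study checks the estimate
against both the planted rate (3 binomial SE) and the exact enumerated
expectation of the estimator (3 SE of the mean over 100 replicates).
Because the bias cancels in ratios only partially, an NI simulation in
which all three branches are scaled by a common factor has expectation
≈ 1, not < 1; the NI recovery study therefore plants the asymmetric
constraint the statistic is designed to detect (human branch reduced more
than the nonhuman branches, in the proportions of the published class
divergences).

## Polymorphism

Nucleotide diversity is SNPs per kb with the three-way-alignable length
as denominator when alignments are supplied, else the element length.
SNP-to-element membership is half-open (start inclusive). The DAF
spectrum uses 20 equal-width bins; the low-DAF fraction counts SNPs with
DAF < 0.05. Density comparisons between classes are two-sided binomial
tests at the other class's pooled rate; the directional low-DAF excess
claims use one-sided tests (purifying selection predicts an excess). The
low-DAF calibration study uses a class of 500 SNPs against a reference of
50,000 — with small references the plug-in reference rate is noisy enough
to inflate the test size above nominal.

## Motif signatures

PWMs are scored as log2 odds against the pooled control-sequence base
composition with a 0.01 pseudocount per cell; a window on either strand is
a hit when its score reaches 0.8 of the matrix's maximum attainable score
(the published scanning tool's threshold is not stated; 0.8 of max is a
common operating point for consensus-like matrices). Features are hit
counts per kb (a binary presence mode exists behind a flag); counts and
per-kb coincide up to a constant because controls are length-matched.
The classifier is a soft-margin linear SVM, min ½‖w‖² + C·Σεᵢ with hinge
loss, C picked by stratified 5-fold cross-validated accuracy over
{0.01, 0.1, 1, 10}. Motifs are ranked by signed weight, ties broken by
motif id; "positively associated" means strictly positive weight.
Per-motif enrichment folds compare pooled hits per kb between enhancers
and controls with a 0.5 pseudocount on counts, and a two-sided binomial
p on the enhancer share of pooled hits against the enhancer share of
scanned kb.

## GO enrichment and gene controls

Term enrichment is the upper-tail hypergeometric P(X ≥ m) with Bonferroni
correction over the number of terms tested, fold = (m/n)/(M/N); the gene
universe is the annotated genes intersected with the genome model. A
partial lower-tail variant (`tail="printed"`) exists for comparison with
legacy outputs but is not the default: enrichment directionality requires
the upper tail. Annotations are taken as pre-propagated; no GO-DAG
true-path expansion is performed. Because GeneT loci are systematically
shorter, function contrasts draw five control genes per group gene
matched on noncoding locus span (gene plus intronic plus flanking
intergenic bp) within ±10%, widening stepwise when candidates run short;
group-vs-control and GeneT-vs-GeneP comparisons are one-sided binomial
tests, and the tissue-specificity contrast is a two-sided Wilcoxon
rank-sum on relative expression.

## The synthetic-data generator

The generator emulates the statistical structure of the real inputs on a
cassette-structured toy genome. Each tissue gene occupies a ~1 Mb
cassette: tele enhancers are planted upstream of the TSS with a
non-tissue bystander gene in between, proximal enhancers in the clean
intergenic zone downstream of the locus, and cassettes are spaced so no
foreign tissue gene enters the 500 kb window — planted labels are
recoverable exactly by the deterministic rules, which is what makes the
classification acceptance check meaningful.

Defaults are the study conditions: 200 enhancers of 1 kb, half tele; 64%
of linked genes GeneT; GeneT loci scaled to 1/3 of the 30 kb GeneP locus
(so intronic spans differ 3.0-fold); branch substitution probabilities
scaled from the published per-kb class divergences against a
(0.009, 0.009, 0.060) neutral reference; SNP densities of 5.61, 5.48,
9.65, 5.94 and 3.68 per kb for proximal, tele, neutral, control and
HACNS classes; a Beta(0.3, 1.5) neutral DAF spectrum with extra low-DAF
mass worth +1.7 (proximal) and +2.4 (tele) percentage points; one shared
and two class-specific planted motifs over 20 random decoys; DHS blocks
spanning a gene's enhancers with probability 0.82; breakpoints at
2e-6/bp inside enhancer–target spans versus 1e-5/bp outside; and a
planted mitochondrial-like GO term at 5.1% in GeneT versus 2.9%
elsewhere. Alignments use a star phylogeny (each lineage substitutes
independently from the ancestral base, uniformly over the three
alternatives) so the outlier-attribution estimator is unbiased by
construction up to the coincidence terms above. All sampling flows
through one seeded generator and emission order is canonical, so output
is byte-identical across runs.

What the generator does *not* emulate — and hence what green tests do not
certify about real data: realistic chromosome sequence composition,
linkage disequilibrium between SNPs, alignment indels, overlapping or
nested genes, distance-dependent enhancer–promoter preferences, and
shared internal branches in the primate tree (an optional shared-branch
mode can be used to probe estimator bias).

## Problem sizes and numerics

The shipped studies use 100 replicate datasets at La = 1e5 per class for
divergence recovery, 500–1000 replicates for the two null calibrations,
20 seeds at n = 400 sequences (50 decoys) for SVM motif recovery, and
n = 1000 sequences of 1 kb for the enrichment-fold check — sizes at which
the targeted effects are resolved to roughly 3 standard errors. Degenerate
inputs are explicit: all-N sequences, saturated divergences (d ≥ 0.75),
zero-margin MK tables, elements with no alignable columns or no
conservation coverage, and classes with zero SNPs are flagged or excluded
rather than imputed. Missing conservation-track bases are excluded from
element means, not treated as zero.
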