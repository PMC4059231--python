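"""GO functional enrichment and locus-length-matched gene controls.

Enrichment of a functional category in a gene group uses the upper-tail
hypergeometric probability P(X >= m) with Bonferroni correction over the
number of categories tested. Because gene groups defined by enhancer
geometry are biased in locus length, contrasts use control genes drawn to
match each group gene's noncoding locus span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GenomeModel

log = logging.getLogger(__name__)


@dataclass
class GoAnnotation:
    term_id: str
    term_name: str
    gene_ids: frozenset[str]

    @property
    def M(self) -> int:
        return len(self.gene_ids)


def annotations_from_pairs(pairs, term_names: dict[str, str] | None = None) -> list[GoAnnotation]:
    by_term: dict[str, set[str]] = {}
    for gene_id, term_id in pairs:
        by_term.setdefault(term_id, set()).add(gene_id)
    names = term_names or {}
    return [
        GoAnnotation(t, names.get(t, t), frozenset(g)) for t, g in sorted(by_term.items())
    ]


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    m: int
    n: int
    M: int
    N: int
    raw_p: float
    corrected_p: float
    enrichment_fold: float


def hypergeom_enrichment(
    group: set[str],
    annotations: list[GoAnnotation],
    universe: set[str],
    tail: str = "upper",
) -> list[EnrichmentResult]:
    """Per-term enrichment of ``group`` within ``universe``.

    raw_p = P(X >= m) for overlap m under the hypergeometric null (``tail
    ="upper"``; ``tail="printed"`` gives the partial lower-tail sum over
    0 < k < m for comparison with legacy outputs). Bonferroni correction
    multiplies by the number of terms tested, capped at 1. Fold is
    (m/n)/(M/N); terms with no annotated gene in the universe are skipped.
    Results are sorted by corrected p then term id.
    """
    if not group:
        raise ValueError("empty gene group")
    group = set(group) & universe
    if not group:
        raise ValueError("group disjoint from universe")
    N = len(universe)
    n = len(group)
    K = len(annotations)
    out = []
    for ann in annotations:
        term_genes = ann.gene_ids & universe
        M = len(term_genes)
        if M == 0:
            continue
        m = len(group & term_genes)
        if m == 0:
            raw = 1.0
            fold = 0.0
        else:
            if tail == "upper":
                raw = float(stats.hypergeom.sf(m - 1, N, M, n))
            elif tail == "printed":
                raw = float(
                    sum(stats.hypergeom.pmf(k, N, M, n) for k in range(1, m))
                )
            else:
                raise ValueError(f"unknown tail {tail!r}")
            fold = (m / n) / (M / N)
        out.append(
            EnrichmentResult(
                term_id=ann.term_id,
                term_name=ann.term_name,
                m=m,
                n=n,
                M=M,
                N=N,
                raw_p=raw,
                corrected_p=min(1.0, K * raw),
                enrichment_fold=fold,
            )
        )
    return sorted(out, key=lambda r: (r.corrected_p, r.term_id))


def gene_locus_spans(genome: GenomeModel) -> dict[str, int]:
    """Noncoding locus span per gene: locus length plus flanking intergenic
    distance to the adjacent gene locus on each side (chromosome-bounded)."""
    spans: dict[str, int] = {}
    by_chrom: dict[str, list] = {}
    for g in genome.genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.locus_interval.start)
        for i, g in enumerate(gs):
            left = gs[i - 1].locus_interval.end if i > 0 else 0
            right = (
                gs[i + 1].locus_interval.start
                if i + 1 < len(gs)
                else genome.chromosomes[chrom]
            )
            spans[g.gene_id] = (
                len(g.locus_interval)
                + max(0, g.locus_interval.start - left)
                + max(0, right - g.locus_interval.end)
            )
    return spans


def matched_control_genes(
    group: set[str],
    spans: dict[str, int],
    rng: np.random.Generator,
    n_per_gene: int = 5,
    length_tolerance: float = 0.10,
    tolerance_step: float = 0.10,
    max_widen: int = 8,
) -> list[str]:
    """Per group gene, ``n_per_gene`` distinct non-group genes with a
    similar locus span (within ``length_tolerance``, widened stepwise and
    logged when candidates run short). Returned pooled with multiplicity;
    deterministic under a fixed RNG."""
    candidates = sorted(set(spans) - set(group))
    if not candidates:
        raise ValueError("no candidate genes outside the group")
    cand_spans = np.array([spans[g] for g in candidates], dtype=float)
    controls: list[str] = []
    for gid in sorted(group):
        if gid not in spans:
            continue
        z = spans[gid]
        for step in range(max_widen + 1):
            tol = length_tolerance + step * tolerance_step
            idx = np.flatnonzero(np.abs(cand_spans - z) <= tol * z)
            if idx.size >= n_per_gene:
                if step:
                    log.info("gene %s: tolerance widened to %.2f", gid, tol)
                break
        else:
            raise ValueError(f"gene {gid}: cannot find {n_per_gene} length-matched controls")
        pick = rng.choice(idx, size=n_per_gene, replace=idx.size < n_per_gene)
        controls.extend(candidates[i] for i in pick)
    return controls


def group_function_contrast(
    geneT: set[str],
    geneP: set[str],
    special_sets: dict[str, set[str]],
    spans: dict[str, int],
    rng: np.random.Generator,
    n_per_gene: int = 5,
) -> dict[str, dict[str, float]]:
    """Fraction of each group annotated to each special gene set, versus
    locus-length-matched controls, with one-sided binomial p-values; plus
    the direct GeneT-vs-GeneP comparison.

    Returns {set_name: {geneT_fraction, geneP_fraction, geneT_vs_control_p,
    geneP_vs_control_p, geneT_vs_geneP_p, ...}}. Empty special sets are
    skipped with a warning.
    """
    out: dict[str, dict[str, float]] = {}
    for name, members in special_sets.items():
        if not members:
            log.warning("special set %s is empty; skipped", name)
            continue
        row: dict[str, float] = {}
        fracs = {}
        for label, grp in (("geneT", geneT), ("geneP", geneP)):
            grp_in = [g for g in grp if g in spans]
            if not grp_in:
                continue
            k = sum(1 for g in grp_in if g in members)
            frac = k / len(grp_in)
            fracs[label] = (k, len(grp_in), frac)
            row[f"{label}_fraction"] = frac
            ctrl = matched_control_genes(set(grp_in), spans, rng, n_per_gene)
            ctrl_frac = sum(1 for g in ctrl if g in members) / len(ctrl)
            row[f"{label}_control_fraction"] = ctrl_frac
            if 0 < ctrl_frac < 1:
                row[f"{label}_vs_control_p"] = float(
                    stats.binomtest(k, len(grp_in), ctrl_frac, alternative="greater").pvalue
                )
        if "geneT" in fracs and "geneP" in fracs:
            kT, nT, _ = fracs["geneT"]
            _, _, fP = fracs["geneP"]
            if 0 < fP < 1:
                row["geneT_vs_geneP_p"] = float(
                    stats.binomtest(kT, nT, fP, alternative="greater").pvalue
                )
        out[name] = row
    return out


def expression_contrast(
    geneT: set[str], geneP: set[str], rel_expression: dict[str, float]
) -> dict[str, float]:
    """Group means of relative expression and a two-sided Wilcoxon
    rank-sum comparison of GeneT vs GeneP."""
    xT = [rel_expression[g] for g in geneT if g in rel_expression and np.isfinite(rel_expression[g])]
    xP = [rel_expression[g] for g in geneP if g in rel_expression and np.isfinite(rel_expression[g])]
    if len(xT) < 2 or len(xP) < 2:
        raise ValueError("each group needs >= 2 genes with defined expression")
    res = stats.mannwhitneyu(xT, xP, alternative="two-sided")
    return {
        "geneT_mean": float(np.mean(xT)),
        "geneP_mean": float(np.mean(xP)),
        "ranksum_p": float(res.pvalue),
        "n_geneT": len(xT),
        "n_geneP": len(xP),
    }
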