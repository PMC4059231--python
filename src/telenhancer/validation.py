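"""Null-model validation of enhancer-gene links.

Two independent plausibility checks:

1. *DHS regulatory-block containment* — the span from a gene's TSS to its
   most distal connected DNase-I hypersensitive site bounds where its
   enhancers plausibly lie. We measure the fraction of links whose enhancer
   falls inside its gene's block and compare with a null in which the same
   enhancer-gene distance is replayed against a random gene whose block
   length matches within +/-10%.

2. *Synteny-breakpoint density* — rearrangement breakpoints should be
   depleted between an enhancer and its target. Observed density in the
   separating interval is compared against a local expectation from a
   +/-500 kb extension with coding (exonic) bp excluded, under a Poisson
   null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GenomeModel, Interval

DEFAULT_N_REPS = 20
DEFAULT_FLANK_BP = 500_000


@dataclass
class DhsBlock:
    gene_id: str
    block_interval: Interval

    @property
    def length(self) -> int:
        return len(self.block_interval)


@dataclass
class BreakpointDensityResult:
    link_class: str
    observed_density: float  # breakpoints per kb
    expected_density: float
    observed_count: int
    observed_kb: float
    p_value: float
    n_links: int


def build_dhs_blocks(dhs_promoter_pairs, genes) -> list[DhsBlock]:
    """Per-gene regulatory block spanning the most distal connected DHS on
    each side, always containing the TSS. Genes with no connection are
    omitted."""
    by_gene: dict[str, list[Interval]] = {}
    for iv, gene_id in dhs_promoter_pairs:
        by_gene.setdefault(gene_id, []).append(iv)
    tss = {g.gene_id: (g.tss_position, g.chromosome) for g in genes}
    blocks = []
    for gene_id, ivs in sorted(by_gene.items()):
        if gene_id not in tss:
            continue
        t, chrom = tss[gene_id]
        start = min(min(iv.start for iv in ivs), t)
        end = max(max(iv.end for iv in ivs), t + 1)
        blocks.append(DhsBlock(gene_id, Interval(chrom, start, end, name=gene_id)))
    return blocks


def dhs_containment_test(
    links,
    blocks: list[DhsBlock],
    enhancers_by_id: dict[str, Interval],
    genes_by_id,
    rng: np.random.Generator,
    n_reps: int = DEFAULT_N_REPS,
    length_window: float = 0.1,
) -> tuple[float, float, float]:
    """(observed_fraction, expected_fraction, p_value).

    Observed: fraction of links (restricted to genes owning a block) whose
    enhancer midpoint lies inside the gene's block. Null: per link at signed
    TSS offset D, draw ``n_reps`` random genes with block length within
    [(1-w)z,(1+w)z] of the tested gene's z, and test whether the point at
    offset D from the drawn gene's TSS (same side) falls inside that gene's
    block; the expectation averages over all draws. When no length-matched
    gene exists the window widens once to 2w, else the link is skipped.
    The p-value is an upper-tail binomial test of the observed count at the
    expected rate.
    """
    block_by_gene = {b.gene_id: b for b in blocks}
    lengths = np.array([b.length for b in blocks])
    all_blocks = list(blocks)
    obs = 0
    n_used = 0
    null_hits = 0
    null_draws = 0
    for link in links:
        b = block_by_gene.get(link.gene_id)
        if b is None or link.enhancer_id not in enhancers_by_id:
            continue
        gene = genes_by_id[link.gene_id]
        enh = enhancers_by_id[link.enhancer_id]
        point = enh.midpoint
        offset = point - gene.tss_position  # signed: preserves the side
        n_used += 1
        if b.block_interval.contains_point(point):
            obs += 1
        z = b.length
        for w in (length_window, 2 * length_window):
            mask = (lengths >= (1 - w) * z) & (lengths <= (1 + w) * z)
            idx = np.flatnonzero(mask)
            if idx.size:
                break
        else:
            continue
        draws = rng.choice(idx, size=n_reps, replace=True)
        for j in draws:
            rb = all_blocks[j]
            rgene = genes_by_id.get(rb.gene_id)
            if rgene is None:
                continue
            null_draws += 1
            if rb.block_interval.contains_point(rgene.tss_position + offset):
                null_hits += 1
    if n_used == 0:
        raise ValueError("no links overlap the block-bearing gene set")
    observed_fraction = obs / n_used
    expected_fraction = null_hits / null_draws if null_draws else 0.0
    if expected_fraction <= 0.0:
        p = 1.0 if obs == 0 else 0.0
    elif expected_fraction >= 1.0:
        p = 1.0
    else:
        p = stats.binomtest(obs, n_used, expected_fraction, alternative="greater").pvalue
    return observed_fraction, expected_fraction, float(p)


def _coding_bp(genome: GenomeModel, chrom: str, lo: int, hi: int) -> int:
    """Exonic bp inside [lo,hi) (merged across genes)."""
    spans = sorted(
        (max(e.start, lo), min(e.end, hi))
        for g in genome.genes
        if g.chromosome == chrom
        for e in g.exon_intervals
        if e.start < hi and e.end > lo
    )
    total = 0
    cur_s = cur_e = None
    for s, e in spans:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _count_breakpoints(breakpoints, chrom: str, lo: int, hi: int) -> int:
    return sum(
        1 for bp in breakpoints if bp.chrom == chrom and lo <= bp.midpoint < hi
    )


def breakpoint_density_test(
    links,
    breakpoints: list[Interval],
    genome: GenomeModel,
    enhancers_by_id: dict[str, Interval],
    genes_by_id,
    link_classes: dict[str, str] | None = None,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> dict[str, BreakpointDensityResult]:
    """Observed vs locally-expected breakpoint density per link class.

    Observed: breakpoints per noncoding kb in the interval separating each
    enhancer from its target TSS, pooled per class. Expected: density in the
    +/-``flank_bp`` extension of that interval with exonic bp excluded. The
    p-value is the lower Poisson tail of the pooled observed count at the
    expected rate (depletion is the signal of shared synteny).
    Zero-length separating intervals are skipped and counted.
    """
    acc: dict[str, dict[str, float]] = {}
    for link in links:
        cls = link_classes.get(link.enhancer_id, link.link_class) if link_classes else link.link_class
        enh = enhancers_by_id.get(link.enhancer_id)
        gene = genes_by_id.get(link.gene_id)
        if enh is None or gene is None:
            continue
        tss = gene.tss_position
        lo, hi = (enh.end, tss) if tss >= enh.end else (tss + 1, enh.start)
        a = acc.setdefault(
            cls,
            {"obs_bp": 0.0, "obs_n": 0.0, "exp_bp": 0.0, "exp_n": 0.0, "links": 0, "skipped": 0},
        )
        if hi <= lo:
            a["skipped"] += 1
            continue
        chrom = enh.chrom
        noncoding = (hi - lo) - _coding_bp(genome, chrom, lo, hi)
        if noncoding <= 0:
            a["skipped"] += 1
            continue
        a["links"] += 1
        a["obs_bp"] += noncoding
        a["obs_n"] += _count_breakpoints(breakpoints, chrom, lo, hi)
        ext_lo = max(0, lo - flank_bp)
        ext_hi = min(genome.chromosomes[chrom], hi + flank_bp)
        ext_nc = (ext_hi - ext_lo) - _coding_bp(genome, chrom, ext_lo, ext_hi)
        a["exp_bp"] += max(ext_nc, 0)
        a["exp_n"] += _count_breakpoints(breakpoints, chrom, ext_lo, ext_hi)
    results: dict[str, BreakpointDensityResult] = {}
    for cls, a in acc.items():
        if a["obs_bp"] == 0 or a["exp_bp"] == 0:
            continue
        obs_kb = a["obs_bp"] / 1000.0
        obs_d = a["obs_n"] / obs_kb
        exp_d = a["exp_n"] / (a["exp_bp"] / 1000.0)
        lam = exp_d * obs_kb
        p = float(stats.poisson.cdf(a["obs_n"], lam)) if lam > 0 else 1.0
        results[cls] = BreakpointDensityResult(
            link_class=cls,
            observed_density=obs_d,
            expected_density=exp_d,
            observed_count=int(a["obs_n"]),
            observed_kb=obs_kb,
            p_value=p,
            n_links=int(a["links"]),
        )
    return results
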