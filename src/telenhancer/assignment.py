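"""Enhancer-to-gene assignment and tele/proximal classification.

Each enhancer is linked to at most two nearest tissue genes (one with its
TSS upstream of the enhancer, one downstream) within a maximum distance
(default 500 kb). A link is *tele* when at least one intervening gene or
exon lies strictly between the enhancer and the target TSS, otherwise
*proximal*. Genes are partitioned into GeneP (has at least one proximal
enhancer) and GeneT (linked, tele links only); genes found in the
intervening evidence of tele links are *bystanders*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneLocus, GenomeModel, Interval

DEFAULT_MAX_LINK_DISTANCE = 500_000


@dataclass
class EnhancerLink:
    enhancer_id: str
    gene_id: str
    distance_bp: int
    side: str  # TSS "upstream" or "downstream" of the enhancer
    link_class: str  # "proximal" | "tele"
    intervening_evidence: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert (self.link_class == "tele") == bool(self.intervening_evidence), (
            f"link {self.enhancer_id}->{self.gene_id}: class/evidence mismatch"
        )


@dataclass
class GenePartition:
    geneP_ids: set[str]
    geneT_ids: set[str]
    unlinked_gene_ids: set[str]
    bystander_gene_ids: set[str]


def select_tissue_genes(
    expression: pd.DataFrame,
    tissue: str,
    top_fraction: float = 0.2,
    extra_annotated_ids: set[str] | None = None,
) -> set[str]:
    """Top fraction of genes by relative expression in ``tissue``, unioned
    with an annotated gene list (e.g. development genes from GO).

    Ranking uses expression in the target tissue divided by the mean over
    the whole panel; ties at the cutoff value are all kept.
    """
    if tissue not in expression.columns:
        raise KeyError(f"tissue {tissue!r} not in expression matrix")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0,1]")
    means = expression.mean(axis=1)
    rel = expression[tissue].where(means == 0, expression[tissue] / means)
    rel = rel.mask(means == 0, 0.0)
    k = max(1, int(round(top_fraction * len(rel))))
    cutoff = rel.sort_values(ascending=False).iloc[k - 1]
    chosen = set(rel.index[rel >= cutoff])
    if extra_annotated_ids:
        chosen |= set(extra_annotated_ids)
    return chosen


def relative_expression(gene: GeneLocus, tissue_index: int) -> float:
    """Target-tissue expression over the panel mean (NaN when undefined)."""
    return gene.relative_expression(tissue_index)


def _gap(enh: Interval, tss: int) -> tuple[int, int]:
    """Open interval strictly between an enhancer and a TSS."""
    if tss >= enh.end:
        return enh.end, tss
    if tss < enh.start:
        return tss + 1, enh.start
    return tss, tss  # TSS inside the enhancer: empty gap


def _edge_distance(enh: Interval, tss: int) -> int:
    if enh.start <= tss < enh.end:
        return 0
    return tss - enh.end + 1 if tss >= enh.end else enh.start - tss


def _intervening(
    enh: Interval,
    target: GeneLocus,
    genes: list[GeneLocus],
    tissue_gene_ids: set[str],
    evidence_scope: str,
) -> list[tuple[str, str]]:
    lo, hi = _gap(enh, target.tss_position)
    if hi <= lo:
        return []
    ev: list[tuple[str, str]] = []
    for g in genes:
        if g.gene_id == target.gene_id or g.chromosome != enh.chrom:
            continue
        if evidence_scope == "non_tissue" and g.gene_id in tissue_gene_ids:
            continue
        gl = g.locus_interval
        if gl.start >= lo and gl.end <= hi:
            ev.append((g.gene_id, "gene"))
            continue
        for ex in g.exon_intervals:
            if ex.start < hi and lo < ex.end:
                ev.append((g.gene_id, "exon"))
                break
    return ev


def assign_enhancers(
    enhancers,
    tissue_gene_ids: set[str],
    genome: GenomeModel,
    max_link_distance: int = DEFAULT_MAX_LINK_DISTANCE,
    distance_mode: str = "edge",
    evidence_scope: str = "non_tissue",
) -> list[EnhancerLink]:
    """Link each enhancer to its nearest tissue gene on each side.

    ``distance_mode``: "edge" measures TSS to the nearest enhancer edge,
    "midpoint" to the enhancer midpoint. ``evidence_scope``: "non_tissue"
    counts only non-tissue genes/exons as intervening (the tele rule for a
    tissue-restricted gene set), "non_target" counts any non-target gene.
    Enhancers with no tissue gene within range yield no links. An enhancer
    lying inside its target's locus with no intervening non-target exon is
    proximal. Equidistant candidates on a side resolve to the lower gene_id.
    """
    if evidence_scope not in ("non_tissue", "non_target"):
        raise ValueError(f"bad evidence_scope {evidence_scope!r}")
    genes = genome.genes
    tissue_genes = [g for g in genes if g.gene_id in tissue_gene_ids]
    links: list[EnhancerLink] = []
    for enh in enhancers:
        iv = enh.interval
        best: dict[str, GeneLocus | None] = {"upstream": None, "downstream": None}
        best_d: dict[str, int] = {}
        for g in tissue_genes:
            if g.chromosome != iv.chrom:
                continue
            if distance_mode == "edge":
                d = _edge_distance(iv, g.tss_position)
            else:
                d = abs(g.tss_position - iv.midpoint)
            if d > max_link_distance:
                continue
            side = "upstream" if g.tss_position < iv.start else "downstream"
            if iv.start <= g.tss_position < iv.end:
                side = "downstream"
            cur = best[side]
            if (
                cur is None
                or d < best_d[side]
                or (d == best_d[side] and g.gene_id < cur.gene_id)
            ):
                best[side], best_d[side] = g, d
        for side, g in best.items():
            if g is None:
                continue
            ev = _intervening(iv, g, genes, tissue_gene_ids, evidence_scope)
            links.append(
                EnhancerLink(
                    enhancer_id=enh.enhancer_id,
                    gene_id=g.gene_id,
                    distance_bp=best_d[side],
                    side=side,
                    link_class="tele" if ev else "proximal",
                    intervening_evidence=ev,
                )
            )
    return links


def classify_enhancers(links) -> tuple[set[str], set[str]]:
    """Enhancer-level labels: proximal if any link is proximal, else tele."""
    by_enh: dict[str, list[str]] = {}
    for l in links:
        by_enh.setdefault(l.enhancer_id, []).append(l.link_class)
    proximal = {e for e, cls in by_enh.items() if "proximal" in cls}
    tele = set(by_enh) - proximal
    return proximal, tele


def partition_genes(links, all_gene_ids: set[str] | None = None) -> GenePartition:
    """GeneP / GeneT / unlinked / bystander partition from the link set."""
    if not links:
        raise ValueError("no links to partition")
    proximal_targets = {l.gene_id for l in links if l.link_class == "proximal"}
    linked = {l.gene_id for l in links}
    geneT = linked - proximal_targets
    bystanders = set()
    for l in links:
        if l.link_class == "tele":
            bystanders |= {gid for gid, _ in l.intervening_evidence if gid != l.gene_id}
    unlinked = (all_gene_ids or set()) - linked
    return GenePartition(
        geneP_ids=proximal_targets,
        geneT_ids=geneT,
        unlinked_gene_ids=unlinked,
        bystander_gene_ids=bystanders,
    )


def noncoding_span_stats(partition: GenePartition, genome: GenomeModel) -> pd.DataFrame:
    """Intronic and flanking-intergenic span per gene, compared GeneT vs GeneP.

    Intergenic span is the distance from the locus to the adjacent gene
    locus on each side, truncated (and flagged) at chromosome bounds.
    Returns a tidy frame plus group means/medians and a Wilcoxon rank-sum
    comparison in ``df.attrs["summary"]``.
    """
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in genome.genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    rows = []
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.locus_interval.start)
        for i, g in enumerate(gs):
            grp = (
                "GeneT"
                if g.gene_id in partition.geneT_ids
                else "GeneP"
                if g.gene_id in partition.geneP_ids
                else "other"
            )
            left = gs[i - 1].locus_interval.end if i > 0 else 0
            right = (
                gs[i + 1].locus_interval.start
                if i + 1 < len(gs)
                else genome.chromosomes[chrom]
            )
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "group": grp,
                    "intronic_bp": g.intronic_bp,
                    "intergenic_bp": max(0, g.locus_interval.start - left)
                    + max(0, right - g.locus_interval.end),
                    "edge_truncated": i == 0 or i + 1 == len(gs),
                }
            )
    df = pd.DataFrame(rows)
    summary: dict[str, float] = {}
    t = df[df.group == "GeneT"]
    p = df[df.group == "GeneP"]
    for col in ("intronic_bp", "intergenic_bp"):
        summary[f"geneT_mean_{col}"] = float(t[col].mean()) if len(t) else np.nan
        summary[f"geneP_mean_{col}"] = float(p[col].mean()) if len(p) else np.nan
        summary[f"geneT_median_{col}"] = float(t[col].median()) if len(t) else np.nan
        summary[f"geneP_median_{col}"] = float(p[col].median()) if len(p) else np.nan
        if len(t) and len(p):
            summary[f"fold_{col}"] = summary[f"geneP_mean_{col}"] / max(
                summary[f"geneT_mean_{col}"], 1e-12
            )
            summary[f"ranksum_p_{col}"] = float(
                stats.mannwhitneyu(t[col], p[col], alternative="two-sided").pvalue
            )
    df.attrs["summary"] = summary
    return df


def links_to_frame(links) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "enhancer_id": [l.enhancer_id for l in links],
            "gene_id": [l.gene_id for l in links],
            "distance": [l.distance_bp for l in links],
            "side": [l.side for l in links],
            "class": [l.link_class for l in links],
            "evidence": [
                ";".join(f"{g}:{t}" for g, t in l.intervening_evidence) or "."
                for l in links
            ],
        }
    )
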