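"""Enhancer-gene linking rules, tele/proximal classes and gene partition."""

import numpy as np
import pandas as pd
import pytest

from telenhancer.assignment import (
    assign_enhancers,
    classify_enhancers,
    noncoding_span_stats,
    partition_genes,
    select_tissue_genes,
)
from telenhancer.core import EnhancerSeq, GeneLocus, GenomeModel, Interval


def _gene(gid, tss, length=20_000, strand="+", chrom="chr1", exons=None):
    if strand == "+":
        lo = Interval(chrom, tss, tss + length, name=gid)
    else:
        lo = Interval(chrom, tss - length, tss, name=gid)
    if exons is None:
        exons = [Interval(chrom, lo.start, lo.start + 1000)]
    return GeneLocus(gid, chrom, strand, tss, lo, exons)


def _enh(eid, start, end, chrom="chr1"):
    return EnhancerSeq(eid, chrom, Interval(chrom, start, end, name=eid))


class TestSelectTissueGenes:
    def _expr(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(1, 2, size=(10, 3))
        data[:2, 0] = 10.0  # two clear heart genes
        return pd.DataFrame(data, index=[f"g{i}" for i in range(10)],
                            columns=["heart", "brain", "lung"])

    def test_top_fraction_selects_highest_relative_expression(self):
        assert select_tissue_genes(self._expr(), "heart", 0.2) == {"g0", "g1"}

    def test_union_with_annotated_has_no_duplicates(self):
        got = select_tissue_genes(self._expr(), "heart", 0.2, {"g1", "g9"})
        assert got == {"g0", "g1", "g9"}

    def test_ties_at_cutoff_all_kept(self):
        df = pd.DataFrame(
            {"heart": [4.0, 4.0, 4.0, 1.0], "brain": [1, 1, 1, 1]},
            index=list("abcd"),
        )
        assert select_tissue_genes(df, "heart", 0.25) == {"a", "b", "c"}

    def test_missing_tissue_errors(self):
        with pytest.raises(KeyError):
            select_tissue_genes(self._expr(), "kidney", 0.2)


class TestRelativeExpression:
    def test_ratio_against_panel_mean(self):
        g = _gene("g", 0)
        g.expression = np.array([10.0, 5.0, 0.0])  # mean 5
        assert g.relative_expression(0) == pytest.approx(2.0)

    def test_uniform_expression_is_one(self):
        g = _gene("g", 0)
        g.expression = np.array([3.0, 3.0, 3.0])
        assert g.relative_expression(1) == pytest.approx(1.0)

    def test_all_zero_is_nan(self):
        g = _gene("g", 0)
        g.expression = np.zeros(3)
        assert np.isnan(g.relative_expression(0))


class TestAssignEnhancers:
    def _genome(self, genes):
        return GenomeModel({"chr1": 1_000_000}, genes=genes)

    def test_proximal_and_tele_links_by_construction(self):
        """Enhancer between two tissue genes; a non-tissue exon before the
        farther gene makes that link tele, the near link stays proximal."""
        gA = _gene("gA", 100_000)
        gB = _gene("gB", 400_000)
        bystander = _gene("gX", 300_000, length=1_000,
                          exons=[Interval("chr1", 300_000, 301_000)])
        genome = self._genome([gA, gB, bystander])
        links = assign_enhancers([_enh("e1", 250_000, 251_000)], {"gA", "gB"}, genome)
        by_gene = {l.gene_id: l for l in links}
        assert set(by_gene) == {"gA", "gB"}
        assert by_gene["gA"].link_class == "proximal"
        assert by_gene["gB"].link_class == "tele"
        assert "gX" in {g for g, _ in by_gene["gB"].intervening_evidence}

    def test_enhancer_in_intron_of_target_is_proximal(self):
        g = _gene("gA", 100_000, length=50_000,
                  exons=[Interval("chr1", 100_000, 101_000),
                         Interval("chr1", 149_000, 150_000)])
        genome = self._genome([g])
        (link,) = assign_enhancers([_enh("e1", 120_000, 121_000)], {"gA"}, genome)
        assert link.link_class == "proximal"
        assert link.distance_bp == 0 or link.distance_bp <= 21_000

    def test_distance_rule_drops_far_enhancers(self):
        genome = self._genome([_gene("gA", 700_000)])
        assert assign_enhancers([_enh("e1", 50_000, 51_000)], {"gA"}, genome) == []

    def test_at_most_one_link_per_side_and_within_range(self, sim_dataset):
        from telenhancer.assignment import EnhancerLink

        ds = sim_dataset
        links = assign_enhancers(ds.enhancers, set(ds.truth.tissue_gene_ids), ds.genome)
        per_enh = {}
        for l in links:
            assert l.distance_bp <= 500_000
            assert (l.link_class == "tele") == bool(l.intervening_evidence)
            per_enh.setdefault(l.enhancer_id, []).append(l.side)
        for sides in per_enh.values():
            assert len(sides) <= 2 and len(set(sides)) == len(sides)

    def test_equidistant_tie_resolves_to_lower_gene_id(self):
        g1 = _gene("gA", 200_000)
        g2 = _gene("gB", 200_000, chrom="chr1", strand="+")
        g2.locus_interval = Interval("chr1", 200_000, 220_000, name="gB")
        genome = GenomeModel({"chr1": 1_000_000}, genes=[g1, g2])
        links = assign_enhancers([_enh("e1", 150_000, 151_000)], {"gA", "gB"}, genome)
        assert [l.gene_id for l in links] == ["gA"]


class TestClassifyAndPartition:
    def test_proximal_dominates_mixed_links(self):
        from telenhancer.assignment import EnhancerLink

        links = [
            EnhancerLink("e1", "g1", 10, "upstream", "proximal", []),
            EnhancerLink("e1", "g2", 20, "downstream", "tele", [("gx", "exon")]),
            EnhancerLink("e2", "g2", 30, "upstream", "tele", [("gy", "gene")]),
        ]
        prox, tele = classify_enhancers(links)
        assert prox == {"e1"} and tele == {"e2"}
        part = partition_genes(links, {"g1", "g2", "g3"})
        assert part.geneP_ids == {"g1"}
        assert part.geneT_ids == {"g2"}
        assert part.unlinked_gene_ids == {"g3"}
        assert part.bystander_gene_ids == {"gx", "gy"}

    def test_empty_links_error(self):
        with pytest.raises(ValueError):
            partition_genes([])

    def test_planted_layout_recovered_exactly(self, sim_dataset):
        ds = sim_dataset
        links = assign_enhancers(ds.enhancers, set(ds.truth.tissue_gene_ids), ds.genome)
        prox, tele = classify_enhancers(links)
        truth = ds.truth.enhancer_class
        assert prox == {e for e, c in truth.items() if c == "proximal"}
        assert tele == {e for e, c in truth.items() if c == "tele"}
        part = partition_genes(links)
        assert part.geneT_ids == {g for g, d in ds.truth.gene_destiny.items() if d == "GeneT"}
        assert part.geneP_ids == {g for g, d in ds.truth.gene_destiny.items() if d == "GeneP"}


class TestNoncodingSpanStats:
    def test_intronic_bp_arithmetic(self):
        single = _gene("gS", 10_000, length=10_000,
                       exons=[Interval("chr1", 10_000, 20_000)])
        multi = _gene("gM", 40_000, length=10_000,
                      exons=[Interval("chr1", 40_000, 41_000),
                             Interval("chr1", 49_000, 50_000)])
        assert single.intronic_bp == 0
        assert multi.intronic_bp == 8_000

    def test_planted_threefold_intron_contrast_recovered(self, sim_dataset):
        ds = sim_dataset
        links = __import__("telenhancer.assignment", fromlist=["assign_enhancers"]).assign_enhancers(
            ds.enhancers, set(ds.truth.tissue_gene_ids), ds.genome
        )
        part = partition_genes(links)
        df = noncoding_span_stats(part, ds.genome)
        fold = df.attrs["summary"]["fold_intronic_bp"]
        assert fold == pytest.approx(3.0, rel=0.2)
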