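"""DHS-block containment and breakpoint-density null models."""

import numpy as np
import pytest

from telenhancer.assignment import EnhancerLink
from telenhancer.core import GeneLocus, GenomeModel, Interval
from telenhancer.simulate import simulate_dhs_null
from telenhancer.validation import (
    BreakpointDensityResult,
    DhsBlock,
    breakpoint_density_test,
    build_dhs_blocks,
    dhs_containment_test,
)


def _gene(gid, tss, chrom="chr1"):
    return GeneLocus(gid, chrom, "+", tss, Interval(chrom, tss, tss + 1_000, name=gid))


class TestBuildDhsBlocks:
    def test_block_spans_distal_sites_and_tss(self):
        genes = [_gene("g1", 100_000)]
        pairs = [
            (Interval("chr1", 50_000, 50_400), "g1"),
            (Interval("chr1", 180_000, 180_400), "g1"),
        ]
        (b,) = build_dhs_blocks(pairs, genes)
        assert b.block_interval == Interval("chr1", 50_000, 180_400)
        assert b.block_interval.contains_point(100_000)

    def test_single_downstream_dhs_still_contains_tss(self):
        genes = [_gene("g1", 100_000)]
        (b,) = build_dhs_blocks([(Interval("chr1", 150_000, 150_400), "g1")], genes)
        assert b.block_interval.start == 100_000
        assert b.block_interval.end == 150_400

    def test_unconnected_gene_omitted(self):
        genes = [_gene("g1", 100_000), _gene("g2", 500_000)]
        blocks = build_dhs_blocks([(Interval("chr1", 90_000, 90_400), "g1")], genes)
        assert [b.gene_id for b in blocks] == ["g1"]


class TestDhsContainment:
    def test_observed_fraction_counts_midpoints(self):
        genes = {f"g{i}": _gene(f"g{i}", 100_000 + i * 1_000_000) for i in range(4)}
        blocks = [
            DhsBlock(g.gene_id, Interval("chr1", g.tss_position - 50_000, g.tss_position + 50_000))
            for g in genes.values()
        ]
        enh, links = {}, []
        for i, g in enumerate(genes.values()):
            inside = i % 2 == 0
            off = 20_000 if inside else 80_000
            eid = f"e{i}"
            enh[eid] = Interval("chr1", g.tss_position + off - 500, g.tss_position + off + 500, name=eid)
            links.append(EnhancerLink(eid, g.gene_id, off, "downstream", "proximal", []))
        obs, exp, p = dhs_containment_test(
            links, blocks, enh, genes, np.random.default_rng(0), n_reps=20
        )
        assert obs == pytest.approx(0.5)
        assert 0.0 <= exp <= 1.0

    def test_zero_observed_and_zero_expected_p_is_one(self):
        genes = {"g0": _gene("g0", 100_000)}
        blocks = [DhsBlock("g0", Interval("chr1", 99_000, 101_000))]
        enh = {"e0": Interval("chr1", 500_000, 501_000, name="e0")}
        links = [EnhancerLink("e0", "g0", 400_000, "downstream", "proximal", [])]
        obs, exp, p = dhs_containment_test(links, blocks, enh, genes, np.random.default_rng(0))
        assert obs == 0.0 and exp == 0.0 and p == 1.0

    def test_deterministic_given_seed(self):
        rng_data = np.random.default_rng(4)
        links, blocks, enh, genes = simulate_dhs_null(rng_data, n_links=50, n_genes=80)
        r1 = dhs_containment_test(links, blocks, enh, genes, np.random.default_rng(9))
        r2 = dhs_containment_test(links, blocks, enh, genes, np.random.default_rng(9))
        assert r1 == r2
        assert 0.0 <= r1[1] <= 1.0

    def test_null_observed_matches_expected_within_noise(self):
        """Links placed independently of blocks: observed fraction should
        sit within binomial noise of the null expectation."""
        rng = np.random.default_rng(12)
        zs = []
        for _ in range(30):
            links, blocks, enh, genes = simulate_dhs_null(rng, n_links=150, n_genes=200)
            obs, exp, _ = dhs_containment_test(links, blocks, enh, genes, rng)
            se = np.sqrt(max(exp * (1 - exp), 1e-9) / 150)
            zs.append((obs - exp) / se)
        assert abs(np.mean(zs)) < 0.6  # SE of the mean ~0.18


class TestBreakpointDensity:
    def _setup(self):
        genome = GenomeModel(
            {"chr1": 2_000_000},
            genes=[
                GeneLocus("g1", "chr1", "+", 500_000,
                          Interval("chr1", 500_000, 520_000, name="g1"),
                          [Interval("chr1", 500_000, 502_000)]),
            ],
        )
        enh = {"e1": Interval("chr1", 448_000, 450_000, name="e1")}
        links = [EnhancerLink("e1", "g1", 50_000, "downstream", "proximal", [])]
        return genome, enh, links

    def test_observed_density_arithmetic(self):
        genome, enh, links = self._setup()
        # 2 breakpoints in the 50-kb noncoding gap
        bps = [Interval("chr1", 460_000, 460_002), Interval("chr1", 470_000, 470_002)]
        res = breakpoint_density_test(
            links, bps, genome, enh, {"g1": genome.genes[0]}
        )
        assert res["proximal"].observed_density == pytest.approx(2 / 50.0)

    def test_expected_uses_flank_with_coding_excluded(self):
        genome, enh, links = self._setup()
        bps = [Interval("chr1", 460_000 + i * 5_000, 460_002 + i * 5_000) for i in range(2)]
        res = breakpoint_density_test(
            links, bps, genome, enh, {"g1": genome.genes[0]}, flank_bp=500_000
        )
        r = res["proximal"]
        # extension [0, 1_000_000] minus the 2-kb exon, observed gap 50 kb
        assert r.expected_density == pytest.approx(2 / ((1_000_000 - 2_000) / 1000))
        assert 0 <= r.p_value <= 1

    def test_zero_length_gap_skipped(self):
        genome, enh, links = self._setup()
        enh_inside = {"e1": Interval("chr1", 499_000, 500_500, name="e1")}
        links = [EnhancerLink("e1", "g1", 0, "downstream", "proximal", [])]
        res = breakpoint_density_test(links, [], genome, enh_inside, {"g1": genome.genes[0]})
        assert res == {}

    def test_uniform_breakpoints_ratio_near_one(self):
        rng = np.random.default_rng(5)
        genome, enh, links = self._setup()
        rate = 2e-4
        positions = np.flatnonzero(rng.random(2_000_000) < rate)
        bps = [Interval("chr1", int(p), int(p) + 1) for p in positions]
        res = breakpoint_density_test(links, bps, genome, enh, {"g1": genome.genes[0]})
        r = res["proximal"]
        ratio = r.observed_density / r.expected_density
        se = 1 / np.sqrt(rate * 50_000)  # Poisson noise on the observed count
        assert abs(ratio - 1) < 3 * se
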