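"""Genome data model and sequence-feature utilities.

All coordinates are 0-based half-open (BED convention). Conversion from
other dialects happens at parser boundaries only (:mod:`telenhancer.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree


class GenomeError(ValueError):
    """Raised for coordinate or model invariant violations."""


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open, optionally named."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise GenomeError(
                f"interval end <= start: {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneLocus:
    """A gene: transcription unit, exon structure, TSS and expression.

    ``tss_position`` sits at ``locus_interval.start`` for ``+`` strand genes
    and at ``locus_interval.end`` for ``-`` strand genes. Expression is a
    vector over a tissue panel in arbitrary units.
    """

    gene_id: str
    chromosome: str
    strand: str
    tss_position: int
    locus_interval: Interval
    exon_intervals: list[Interval] = field(default_factory=list)
    is_tissue_gene: bool = False
    expression: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        lo = self.locus_interval
        expected_tss = lo.start if self.strand == "+" else lo.end
        if self.tss_position != expected_tss:
            raise GenomeError(
                f"gene {self.gene_id}: TSS {self.tss_position} not at the "
                f"{self.strand}-strand boundary of {lo.start}-{lo.end}"
            )
        for ex in self.exon_intervals:
            if ex.start < lo.start or ex.end > lo.end or ex.chrom != lo.chrom:
                raise GenomeError(
                    f"gene {self.gene_id}: exon {ex} outside locus {lo}"
                )

    @property
    def intronic_bp(self) -> int:
        return len(self.locus_interval) - sum(len(e) for e in self.exon_intervals)

    def relative_expression(self, tissue_index: int) -> float:
        """Expression in one tissue over the mean across the panel.

        Returns NaN for an all-zero vector (undefined specificity).
        """
        if self.expression is None:
            raise GenomeError(f"gene {self.gene_id}: no expression vector")
        mean = float(np.mean(self.expression))
        if mean == 0.0:
            return float("nan")
        return float(self.expression[tissue_index]) / mean


@dataclass
class EnhancerSeq:
    """An enhancer (or control) element with optional sequence."""

    enhancer_id: str
    chromosome: str
    interval: Interval
    sequence: str | None = None
    source_label: str = "p300"


@dataclass(frozen=True)
class SeqFeatures:
    length: int
    gc_fraction: float
    cpg_density: float
    repeat_fraction: float

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "repeat_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenomeError(f"{name}={v} outside [0,1]")


@dataclass
class GenomeModel:
    """Chromosomes, genes and annotation layers used across the pipeline."""

    chromosomes: dict[str, int]
    genes: list[GeneLocus] = field(default_factory=list)
    pseudogene_intervals: list[Interval] = field(default_factory=list)
    repeat_intervals: list[Interval] = field(default_factory=list)
    sequence: dict[str, str] | None = None
    tissue_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise GenomeError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            self._check_interval(g.locus_interval)
        for iv in list(self.pseudogene_intervals) + list(self.repeat_intervals):
            self._check_interval(iv)

    def _check_interval(self, iv: Interval) -> None:
        if iv.chrom not in self.chromosomes:
            raise GenomeError(f"unknown chromosome {iv.chrom!r}")
        if iv.start < 0 or iv.end > self.chromosomes[iv.chrom]:
            raise GenomeError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} outside chromosome "
                f"bounds [0,{self.chromosomes[iv.chrom]})"
            )

    def gene(self, gene_id: str) -> GeneLocus:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def exon_tree(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {c: IntervalTree() for c in self.chromosomes}
        for g in self.genes:
            for ex in g.exon_intervals:
                trees[ex.chrom].addi(ex.start, ex.end, g.gene_id)
        return trees

    def fetch(self, iv: Interval) -> str:
        if self.sequence is None:
            raise GenomeError("genome has no sequence attached")
        self._check_interval(iv)
        return self.sequence[iv.chrom][iv.start : iv.end]

    def noncoding_intervals(self) -> list[Interval]:
        """Chromosome space outside any exon, per chromosome, sorted."""
        out: list[Interval] = []
        for chrom, length in sorted(self.chromosomes.items()):
            exons = sorted(
                (e.start, e.end)
                for g in self.genes
                if g.chromosome == chrom
                for e in g.exon_intervals
            )
            cursor = 0
            for s, e in exons:
                if s > cursor:
                    out.append(Interval(chrom, cursor, s))
                cursor = max(cursor, e)
            if cursor < length:
                out.append(Interval(chrom, cursor, length))
        return out


_GC = frozenset("GCgc")
_VALID = frozenset("ACGTNacgtn")


def compute_seq_features(
    seq: str, repeat_mask: Sequence[tuple[int, int]] | None = None
) -> SeqFeatures:
    """Length, GC fraction, CpG density and repeat fraction of a sequence.

    GC fraction uses the non-N length as denominator; CpG density counts CG
    dinucleotides per bp on the given strand; repeat fraction is the masked
    bp (``repeat_mask`` holds sequence-relative half-open spans) over the
    sequence length. Strand only affects CpG counting asymmetrically via
    N placement; GC and length are strand-agnostic.
    """
    if not seq:
        raise GenomeError("empty sequence")
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        raise GenomeError(f"non-nucleotide characters in sequence: {bad}")
    n = len(seq)
    upper = seq.upper()
    non_n = n - upper.count("N")
    if non_n == 0:
        raise GenomeError("all-N sequence: features undefined")
    gc = sum(1 for b in upper if b in "GC") / non_n
    cpg = upper.count("CG") / n
    masked = 0
    if repeat_mask:
        for s, e in repeat_mask:
            masked += max(0, min(e, n) - max(s, 0))
    return SeqFeatures(
        length=n,
        gc_fraction=gc,
        cpg_density=cpg,
        repeat_fraction=min(1.0, masked / n),
    )


def _repeat_overlap(genome: GenomeModel, iv: Interval) -> list[tuple[int, int]]:
    spans = []
    for r in genome.repeat_intervals:
        if r.overlaps(iv):
            spans.append((max(r.start, iv.start) - iv.start, min(r.end, iv.end) - iv.start))
    return spans


def element_features(genome: GenomeModel, iv: Interval) -> SeqFeatures:
    """Sequence features of a genomic interval, repeat mask from the model."""
    return compute_seq_features(genome.fetch(iv), _repeat_overlap(genome, iv))


def select_matched_controls(
    targets: Iterable[EnhancerSeq],
    genome: GenomeModel,
    n_per_target: int,
    rng: np.random.Generator,
    gc_tolerance: float = 0.05,
    repeat_tolerance: float = 0.05,
    max_attempts: int = 1000,
    relax_step: float = 0.02,
    max_relax: int = 5,
) -> list[EnhancerSeq]:
    """Draw random noncoding sequences matched to each target element.

    For each target, ``n_per_target`` noncoding stretches of identical length
    are sampled whose GC fraction and repeat fraction fall within the given
    absolute tolerances of the target's. Controls overlap neither targets nor
    each other. If no match is found within ``max_attempts`` draws the
    tolerances are widened by ``relax_step`` (up to ``max_relax`` times)
    before the target is given up on with an error.
    """
    targets = list(targets)
    if n_per_target < 0:
        raise ValueError("n_per_target must be >= 0")
    if n_per_target == 0:
        return []
    noncoding = genome.noncoding_intervals()
    taken: list[Interval] = [t.interval for t in targets]
    controls: list[EnhancerSeq] = []
    for t in targets:
        want = len(t.interval)
        pool = [iv for iv in noncoding if len(iv) >= want]
        if not pool:
            raise GenomeError(
                f"no noncoding interval of length >= {want} for {t.enhancer_id}"
            )
        weights = np.array([len(iv) - want + 1 for iv in pool], dtype=float)
        weights /= weights.sum()
        tfeat = element_features(genome, t.interval)
        found = 0
        for relax in range(max_relax + 1):
            gc_tol = gc_tolerance + relax * relax_step
            rep_tol = repeat_tolerance + relax * relax_step
            for _ in range(max_attempts):
                if found >= n_per_target:
                    break
                host = pool[int(rng.choice(len(pool), p=weights))]
                start = int(rng.integers(host.start, host.end - want + 1))
                cand = Interval(host.chrom, start, start + want)
                if any(cand.overlaps(x) for x in taken):
                    continue
                try:
                    cfeat = element_features(genome, cand)
                except GenomeError:
                    continue
                if (
                    abs(cfeat.gc_fraction - tfeat.gc_fraction) <= gc_tol
                    and abs(cfeat.repeat_fraction - tfeat.repeat_fraction) <= rep_tol
                ):
                    found += 1
                    cid = f"{t.enhancer_id}_ctrl{found}"
                    cand = replace(cand, name=cid)
                    taken.append(cand)
                    controls.append(
                        EnhancerSeq(
                            enhancer_id=cid,
                            chromosome=cand.chrom,
                            interval=cand,
                            sequence=genome.fetch(cand),
                            source_label="control",
                        )
                    )
            if found >= n_per_target:
                break
        if found < n_per_target:
            raise GenomeError(
                f"could not match {n_per_target} controls for {t.enhancer_id} "
                f"(got {found}) after relaxation"
            )
    return controls
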