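"""Synthetic toy-genome generator with known planted parameters.

Emits every input class the pipeline consumes — genome FASTA, gene models,
enhancer/control/HACNS/pseudogene intervals, a tissue expression matrix,
DHS-promoter pairs, synteny breakpoints, three-way alignments, a SNP table
with derived allele frequencies, PWMs, GO annotations and a conservation
track — on a cassette-structured toy genome where every enhancer's class
and target are known by construction.

Layout: each tissue gene sits in its own ~1 Mb cassette. Tele enhancers are
planted upstream of the target's TSS with a non-tissue *bystander* gene in
between; proximal enhancers sit in the clean intergenic interval
downstream of the target locus. Cassettes are spaced so no other tissue
gene falls within the 500 kb linking window, making the planted
tele/proximal labels exactly recoverable by the deterministic assignment
rules.

Planted rates default to the study conditions: per-branch substitution
probabilities scaled from per-kilobase divergences of the enhancer,
control, HACNS and pseudogene (neutral) classes; SNP densities per class;
low-DAF excess mass over a Beta(0.3, 1.5) neutral spectrum; class-specific
and shared motifs at fixed planting rates; GeneT loci three-fold shorter
than GeneP loci.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as tio
from .core import EnhancerSeq, GeneLocus, GenomeModel, Interval, select_matched_controls
from .evolution import TriAlignment
from .motifs import Pwm

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PlantedMotif:
    motif_id: str
    consensus: str
    rates: dict[str, float]  # planting probability per element class


def _default_motifs() -> list[PlantedMotif]:
    return [
        PlantedMotif("M_SHARED", "TGACGTCATG", {"tele": 0.6, "proximal": 0.6, "control": 0.05}),
        PlantedMotif("M_TELE", "CATTGGCGAC", {"tele": 0.5, "proximal": 0.1, "control": 0.05}),
        PlantedMotif("M_PROX", "GGATCTCGTA", {"tele": 0.1, "proximal": 0.5, "control": 0.05}),
    ]


def _default_branch_rates() -> dict[str, tuple[float, float, float]]:
    # (p_human, p_chimp, p_macaque) per element class, scaled from the
    # per-kb class divergences relative to the neutral reference.
    return {
        "proximal": (0.00557, 0.00721, 0.04806),
        "tele": (0.00539, 0.00715, 0.04769),
        "control": (0.00632, 0.00749, 0.04994),
        "hacns": (0.01697, 0.00357, 0.02383),
    }


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 8_000_000
    cassette_bp: int = 1_000_000
    n_genes: int = 80
    tissue_gene_fraction: float = 0.2
    n_tissues: int = 6
    tissue: str = "heart"
    geneT_fraction: float = 0.64
    geneT_locus_scale: float = 1.0 / 3.0
    geneP_locus_bp: int = 30_000
    exon_fraction: float = 0.2
    n_enhancers: int = 200
    tele_fraction: float = 0.5
    enhancer_bp: int = 1_000
    n_controls_per_enhancer: int = 2
    branch_rates: dict = field(default_factory=_default_branch_rates)
    neutral_branch_rates: tuple[float, float, float] = (0.009, 0.009, 0.060)
    snp_rate: dict = field(
        default_factory=lambda: {
            "proximal": 0.00561,
            "tele": 0.00548,
            "control": 0.00594,
            "hacns": 0.00368,
            "neutral": 0.00965,
        }
    )
    daf_beta: tuple[float, float] = (0.3, 1.5)
    daf_cutoff: float = 0.05
    daf_low_excess: dict = field(
        default_factory=lambda: {
            "proximal": 0.017,
            "tele": 0.024,
            "control": 0.0,
            "hacns": 0.0,
            "neutral": 0.0,
        }
    )
    planted_motifs: list = field(default_factory=_default_motifs)
    n_decoy_motifs: int = 20
    motif_length: int = 10
    breakpoint_rate_linked: float = 2e-6
    breakpoint_rate_background: float = 1e-5
    dhs_span_prob: float = 0.82
    cons_frac_above: dict = field(
        default_factory=lambda: {"tele": 0.15, "proximal": 0.13}
    )
    cons_threshold: float = 0.2
    score_track_stride: int = 5
    n_pseudogenes_per_cassette: int = 1
    pseudogene_bp: int = 3_000
    n_hacns: int = 40
    hacns_bp: int = 600
    mito_rates: dict = field(
        default_factory=lambda: {"GeneT": 0.051, "GeneP": 0.029, "other": 0.029}
    )


@dataclass
class SimTruth:
    enhancer_class: dict[str, str]
    enhancer_target: dict[str, str]
    gene_destiny: dict[str, str]
    tissue_gene_ids: list[str]
    branch_rates: dict
    neutral_branch_rates: tuple
    snp_rate: dict
    daf_low_excess: dict
    planted_motif_ids: list[str]
    n_tele: int
    n_proximal: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SimDataset:
    genome: GenomeModel
    enhancers: list[EnhancerSeq]
    controls: list[EnhancerSeq]
    paths: dict[str, Path]
    truth: SimTruth


class LayoutError(ValueError):
    """Requested geometry does not fit the toy genome."""


# cassette-relative anchor offsets (bp)
_TELE_ZONE = (150_000, 270_000)
_BYSTANDER = (300_000, 312_000)
_TISSUE_TSS = 400_000
_PROX_GAP = 10_000
_PROX_ZONE_END = 560_000
_FILLER_SLOTS = (640_000, 690_000, 740_000, 790_000, 840_000)
_PSEUDO_AT = 900_000
_ENH_SPACING = 2_000


def alignment_column_sampler(
    ancestral_base: str, branch_rates: tuple[float, float, float], rng: np.random.Generator
) -> tuple[str, str, str]:
    """Sample one (human, chimp, macaque) column from an ancestral base.

    Star phylogeny: each lineage substitutes independently with its branch
    probability, uniformly among the three alternative bases, matching the
    outlier-attribution logic of the divergence estimator.
    """
    bases = "ACGT"
    anc = bases.index(ancestral_base.upper())
    out = []
    for p in branch_rates:
        if p >= 0.75:
            raise ValueError("branch rate must be < 0.75")
        if rng.random() < p:
            out.append(bases[(anc + 1 + int(rng.integers(3))) % 4])
        else:
            out.append(bases[anc])
    return tuple(out)


def sample_alignment(
    element_id: str,
    interval: Interval,
    ancestral: str,
    branch_rates: tuple[float, float, float],
    rng: np.random.Generator,
) -> TriAlignment:
    """Vectorised star-phylogeny alignment over a whole element."""
    codes = np.frombuffer(ancestral.upper().encode(), dtype=np.uint8).copy()
    idx = np.zeros(codes.size, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        idx[codes == b] = i
    rows = []
    for p in branch_rates:
        if p >= 0.75:
            raise ValueError("branch rate must be < 0.75")
        sub = rng.random(idx.size) < p
        shifted = (idx + 1 + rng.integers(0, 3, size=idx.size)) % 4
        out = np.where(sub, shifted, idx)
        rows.append(_BASES[out].tobytes().decode())
    return TriAlignment(element_id, interval, rows[0], rows[1], rows[2])


def _make_exons(chrom: str, start: int, end: int, fraction: float, n_exons: int = 4):
    glen = end - start
    exon_bp = max(1, int(glen * fraction / n_exons))
    step = glen // n_exons
    exons = []
    for k in range(n_exons):
        s = start + k * step
        exons.append(Interval(chrom, s, min(s + exon_bp, end)))
    return exons


def _sample_daf(n: int, cls: str, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    from scipy.stats import beta as beta_dist

    a, b = cfg.daf_beta
    p_low_neutral = float(beta_dist.cdf(cfg.daf_cutoff, a, b))
    excess = cfg.daf_low_excess.get(cls, 0.0)
    w = excess / max(1e-12, 1.0 - p_low_neutral) if excess > 0 else 0.0
    daf = rng.beta(a, b, size=n)
    forced = rng.random(n) < w
    daf[forced] = rng.uniform(0.0, cfg.daf_cutoff, size=int(forced.sum()))
    return np.clip(daf, 1e-6, 1.0)


def pwm_from_consensus(motif_id: str, consensus: str, tf_name: str | None = None,
                       match_count: float = 91.0, mismatch_count: float = 3.0) -> Pwm:
    mat = np.full((len(consensus), 4), mismatch_count)
    for i, b in enumerate(consensus.upper()):
        mat[i, "ACGT".index(b)] = match_count
    return Pwm(motif_id=motif_id, tf_name=tf_name or motif_id, matrix=mat)


def simulate_dataset(cfg: SimConfig, outdir: str | Path) -> SimDataset:
    """Generate the full synthetic input bundle under ``outdir``.

    Emission order is canonical (sorted by coordinate) and all sampling
    flows through one seeded generator, so output is byte-identical across
    runs with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    n_tissue = int(round(cfg.n_genes * cfg.tissue_gene_fraction))
    if n_tissue < 1:
        raise LayoutError("need at least one tissue gene")
    per_chrom = cfg.chromosome_length // cfg.cassette_bp
    if per_chrom < 1 or n_tissue > per_chrom * cfg.n_chromosomes:
        raise LayoutError(
            f"{n_tissue} cassettes of {cfg.cassette_bp} bp do not fit "
            f"{cfg.n_chromosomes} x {cfg.chromosome_length} bp"
        )
    n_filler = cfg.n_genes - 2 * n_tissue
    if n_filler < 0:
        raise LayoutError("n_genes must cover tissue genes plus bystanders")
    fill_per_cassette, rem = divmod(n_filler, n_tissue)
    if fill_per_cassette + (rem > 0) > len(_FILLER_SLOTS):
        raise LayoutError("too many filler genes per cassette")

    n_tele = int(round(cfg.n_enhancers * cfg.tele_fraction))
    n_prox = cfg.n_enhancers - n_tele
    n_geneT = int(round(cfg.geneT_fraction * n_tissue))
    if n_tele == 0:
        n_geneT = 0
    elif n_geneT == 0:
        n_geneT = 1
    if n_prox > 0 and n_geneT == n_tissue:
        n_geneT = n_tissue - 1
    n_geneP = n_tissue - n_geneT
    tele_slots = (_TELE_ZONE[1] - _TELE_ZONE[0]) // _ENH_SPACING
    if n_geneT and -(-n_tele // n_geneT) > tele_slots:
        raise LayoutError("too many tele enhancers per cassette")

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    chromosomes = {c: cfg.chromosome_length for c in chrom_names}
    seq = {
        c: bytearray(_BASES[rng.integers(0, 4, size=cfg.chromosome_length)].tobytes())
        for c in chrom_names
    }

    destiny_perm = rng.permutation(n_tissue)
    geneT_cassettes = set(destiny_perm[:n_geneT].tolist())

    genes: list[GeneLocus] = []
    tissue_gene_ids: list[str] = []
    gene_destiny: dict[str, str] = {}
    cassette_info = []  # (cassette_idx, chrom, S, gene_id, is_geneT)
    filler_counts = [fill_per_cassette + (i < rem) for i in range(n_tissue)]
    for ci in range(n_tissue):
        chrom = chrom_names[ci // per_chrom]
        S = (ci % per_chrom) * cfg.cassette_bp
        is_T = ci in geneT_cassettes
        glen = int(cfg.geneP_locus_bp * (cfg.geneT_locus_scale if is_T else 1.0))
        gid = f"T{ci:03d}"
        lo = Interval(chrom, S + _TISSUE_TSS, S + _TISSUE_TSS + glen, name=gid)
        genes.append(
            GeneLocus(gid, chrom, "+", lo.start, lo,
                      _make_exons(chrom, lo.start, lo.end, cfg.exon_fraction))
        )
        tissue_gene_ids.append(gid)
        bid = f"B{ci:03d}"
        blo = Interval(chrom, S + _BYSTANDER[0], S + _BYSTANDER[1], name=bid)
        genes.append(
            GeneLocus(bid, chrom, "+", blo.start, blo,
                      _make_exons(chrom, blo.start, blo.end, cfg.exon_fraction, n_exons=2))
        )
        for fi in range(filler_counts[ci]):
            fid = f"F{ci:03d}_{fi}"
            fl = int(rng.integers(8_000, 36_000))
            fs = S + _FILLER_SLOTS[fi]
            flo = Interval(chrom, fs, fs + fl, name=fid)
            genes.append(
                GeneLocus(fid, chrom, "+", flo.start, flo,
                          _make_exons(chrom, flo.start, flo.end, cfg.exon_fraction))
            )
        cassette_info.append((ci, chrom, S, gid, is_T))

    # --- enhancers with planted classes -----------------------------------
    enhancer_class: dict[str, str] = {}
    enhancer_target: dict[str, str] = {}
    enhancers: list[EnhancerSeq] = []
    T_cassettes = [c for c in cassette_info if c[4]]
    P_cassettes = [c for c in cassette_info if not c[4]]
    counters = {ci: {"tele": 0, "prox": 0} for ci, *_ in cassette_info}

    def _place(kind: str, host, k: int) -> None:
        ci, chrom, S, gid, _ = host
        if kind == "tele":
            start = S + _TELE_ZONE[0] + counters[ci]["tele"] * _ENH_SPACING
            counters[ci]["tele"] += 1
        else:
            glen = len(next(g for g in genes if g.gene_id == gid).locus_interval)
            start = S + _TISSUE_TSS + glen + _PROX_GAP + counters[ci]["prox"] * _ENH_SPACING
            if start + cfg.enhancer_bp > S + _PROX_ZONE_END:
                raise LayoutError("too many proximal enhancers per cassette")
            counters[ci]["prox"] += 1
        eid = f"e{k:04d}"
        iv = Interval(chrom, start, start + cfg.enhancer_bp, name=eid)
        enhancers.append(EnhancerSeq(eid, chrom, iv, source_label="p300"))
        enhancer_class[eid] = "tele" if kind == "tele" else "proximal"
        enhancer_target[eid] = gid

    k = 0
    for j in range(n_tele):
        _place("tele", T_cassettes[j % len(T_cassettes)], k)
        k += 1
    for j in range(n_prox):
        _place("prox", P_cassettes[j % len(P_cassettes)], k)
        k += 1
    for ci, chrom, S, gid, is_T in cassette_info:
        got = counters[ci]["tele"] + counters[ci]["prox"]
        if got:
            gene_destiny[gid] = "GeneT" if counters[ci]["prox"] == 0 else "GeneP"
    enhancers.sort(key=lambda e: (e.chromosome, e.interval.start))

    # pseudogenes (neutral reference) and HACNS intervals
    pseudogenes = []
    for ci, chrom, S, *_ in cassette_info:
        for pi in range(cfg.n_pseudogenes_per_cassette):
            s = S + _PSEUDO_AT + pi * (cfg.pseudogene_bp + 1_000)
            pseudogenes.append(Interval(chrom, s, s + cfg.pseudogene_bp, name=f"ps{ci:03d}_{pi}"))
    hacns = []
    for j in range(cfg.n_hacns):
        ci, chrom, S, *_ = cassette_info[j % len(cassette_info)]
        s = S + 950_000 + (j // len(cassette_info)) * (cfg.hacns_bp + 400)
        if s + cfg.hacns_bp <= S + cfg.cassette_bp:
            hacns.append(Interval(chrom, s, s + cfg.hacns_bp, name=f"h{j:03d}"))

    # --- plant motifs into enhancer sequences -----------------------------
    decoys = []
    for j in range(cfg.n_decoy_motifs):
        cons = "".join("ACGT"[i] for i in rng.integers(0, 4, size=cfg.motif_length))
        decoys.append(PlantedMotif(f"M_DECOY{j:02d}", cons, {}))
    all_motifs = list(cfg.planted_motifs) + decoys

    def _embed(iv: Interval, consensus: str) -> None:
        off = int(rng.integers(0, len(iv) - len(consensus) + 1))
        seq[iv.chrom][iv.start + off : iv.start + off + len(consensus)] = consensus.encode()

    for enh in enhancers:
        cls = enhancer_class[enh.enhancer_id]
        for pm in cfg.planted_motifs:
            if rng.random() < pm.rates.get(cls, 0.0):
                _embed(enh.interval, pm.consensus)

    genome = GenomeModel(
        chromosomes=chromosomes,
        genes=genes,
        pseudogene_intervals=pseudogenes,
        sequence={c: s.decode() for c, s in seq.items()},
        tissue_names=[cfg.tissue] + [f"tissue{i}" for i in range(1, cfg.n_tissues)],
    )
    for e in enhancers:
        e.sequence = genome.fetch(e.interval)

    controls = select_matched_controls(
        enhancers, genome, cfg.n_controls_per_enhancer, rng
    )
    for c in controls:
        for pm in cfg.planted_motifs:
            if rng.random() < pm.rates.get("control", 0.0):
                _embed(c.interval, pm.consensus)
    genome.sequence = {c: s.decode() for c, s in seq.items()}
    for e in enhancers + controls:
        e.sequence = genome.fetch(e.interval)

    # --- expression matrix -------------------------------------------------
    import pandas as pd

    tissues = genome.tissue_names
    expr = rng.uniform(1.5, 2.5, size=(len(genes), len(tissues)))
    gene_ids = [g.gene_id for g in genes]
    for i, g in enumerate(genes):
        if g.gene_id in tissue_gene_ids:
            lo, hi = (7.5, 9.5) if gene_destiny.get(g.gene_id) == "GeneT" else (9.5, 11.5)
            expr[i, 0] = rng.uniform(lo, hi)
    expr_df = pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"), columns=tissues)
    for g, row in zip(genes, expr):
        g.expression = row

    # --- DHS-promoter pairs -------------------------------------------------
    enh_by_gene: dict[str, list[Interval]] = {}
    for e in enhancers:
        enh_by_gene.setdefault(enhancer_target[e.enhancer_id], []).append(e.interval)
    dhs_pairs: list[tuple[Interval, str]] = []
    for g in genes:
        if g.gene_id.startswith("B"):
            continue
        tss = g.tss_position
        dhs_pairs.append((Interval(g.chromosome, max(0, tss - 2_500), max(1, tss - 2_000)), g.gene_id))
        linked = enh_by_gene.get(g.gene_id)
        if linked:
            left = min(iv.start for iv in linked)
            right = max(iv.end for iv in linked)
            if rng.random() < cfg.dhs_span_prob:
                lo_d = min(left, tss) - int(rng.integers(2_000, 8_000))
                hi_d = max(right, tss + 1) + int(rng.integers(2_000, 8_000))
            else:  # block too short: stops well before the enhancers
                lo_d = tss - int(rng.integers(2_000, 10_000))
                hi_d = tss + int(rng.integers(2_000, 10_000))
            dhs_pairs.append((Interval(g.chromosome, max(0, lo_d), max(0, lo_d) + 400), g.gene_id))
            dhs_pairs.append((Interval(g.chromosome, hi_d - 400, hi_d), g.gene_id))
        else:
            d = int(rng.integers(20_000, 300_000))
            side = 1 if rng.random() < 0.5 else -1
            pos = min(max(0, tss + side * d), cfg.chromosome_length - 400)
            dhs_pairs.append((Interval(g.chromosome, pos, pos + 400), g.gene_id))
    dhs_pairs.sort(key=lambda p: (p[0].chrom, p[0].start, p[1]))

    # --- synteny breakpoints ------------------------------------------------
    linked_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for e in enhancers:
        g = genome.gene(enhancer_target[e.enhancer_id])
        lo = min(e.interval.start, g.tss_position)
        hi = max(e.interval.end, g.tss_position + 1)
        linked_spans[e.chromosome].append((lo, hi))
    breakpoints: list[Interval] = []
    bp_i = 0
    for chrom in chrom_names:
        spans = sorted(linked_spans[chrom])
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cursor = 0
        segments = []
        for s, e in merged:
            if s > cursor:
                segments.append((cursor, s, cfg.breakpoint_rate_background))
            segments.append((s, e, cfg.breakpoint_rate_linked))
            cursor = e
        if cursor < cfg.chromosome_length:
            segments.append((cursor, cfg.chromosome_length, cfg.breakpoint_rate_background))
        for s, e, rate in segments:
            n = rng.poisson(rate * (e - s))
            for pos in sorted(rng.integers(s, e, size=n).tolist()):
                breakpoints.append(Interval(chrom, pos, min(pos + 2, cfg.chromosome_length), name=f"bp{bp_i}"))
                bp_i += 1

    # --- three-way alignments ----------------------------------------------
    def _class_of(iv: Interval) -> str:
        name = iv.name or ""
        if name.startswith("ps"):
            return "neutral"
        if name.startswith("h"):
            return "hacns"
        if "_ctrl" in name:
            return "control"
        return enhancer_class[name]

    elements: list[Interval] = (
        [e.interval for e in enhancers]
        + [c.interval for c in controls]
        + hacns
        + pseudogenes
    )
    alignments = []
    for iv in elements:
        cls = _class_of(iv)
        rates = (
            cfg.neutral_branch_rates if cls == "neutral" else tuple(cfg.branch_rates[cls])
        )
        alignments.append(
            sample_alignment(iv.name, iv, genome.fetch(iv), rates, rng)
        )

    # --- SNPs ----------------------------------------------------------------
    snps: list[tuple[str, int, float]] = []
    for iv in elements:
        cls = _class_of(iv)
        rate = cfg.snp_rate[cls]
        n = rng.binomial(len(iv), rate)
        if n == 0:
            continue
        pos = rng.choice(len(iv), size=n, replace=False) + iv.start
        dafs = _sample_daf(n, cls, cfg, rng)
        snps.extend((iv.chrom, int(p), float(d)) for p, d in zip(pos, dafs))
    snps.sort()

    # --- conservation track --------------------------------------------------
    track: list[tuple[str, int, float]] = []
    for e in enhancers:
        cls = enhancer_class[e.enhancer_id]
        f_hi = cfg.cons_frac_above.get(cls, 0.1)
        if rng.random() < f_hi:
            mean = rng.uniform(cfg.cons_threshold + 0.05, 0.8)
        else:
            mean = rng.uniform(0.0, cfg.cons_threshold - 0.02)
        for p in range(e.interval.start, e.interval.end, cfg.score_track_stride):
            track.append((e.chromosome, p, float(np.clip(mean + 0.01 * rng.standard_normal(), 0, 1))))
    track.sort()

    # --- GO annotations ------------------------------------------------------
    go_pairs: list[tuple[str, str]] = []
    for g in genes:
        destiny = gene_destiny.get(g.gene_id, "other")
        if rng.random() < cfg.mito_rates.get(destiny, cfg.mito_rates["other"]):
            go_pairs.append((g.gene_id, "GO:MITO"))
        if g.gene_id in tissue_gene_ids and rng.random() < 0.5:
            go_pairs.append((g.gene_id, "GO:DEV"))
        for t in range(3):
            if rng.random() < 0.15:
                go_pairs.append((g.gene_id, f"GO:RAND{t}"))
    go_pairs.sort()

    # --- PWM set -------------------------------------------------------------
    pwms = [pwm_from_consensus(pm.motif_id, pm.consensus) for pm in all_motifs]

    # --- emit ---------------------------------------------------------------
    paths = {
        "genome_fasta": outdir / "genome.fa",
        "genes": outdir / "genes.tsv",
        "enhancers": outdir / "enhancers.bed",
        "controls": outdir / "controls.bed",
        "hacns": outdir / "hacns.bed",
        "pseudogenes": outdir / "pseudogenes.bed",
        "expression": outdir / "expression.tsv",
        "dhs_pairs": outdir / "dhs_pairs.tsv",
        "breakpoints": outdir / "breakpoints.bed",
        "alignments": outdir / "alignments.axt",
        "snps": outdir / "snps.tsv",
        "pwms": outdir / "pwms.txt",
        "go": outdir / "go.tsv",
        "conservation": outdir / "conservation.tsv",
        "truth": outdir / "truth.json",
    }
    _write_fasta(paths["genome_fasta"], genome)
    tio.write_gene_model(paths["genes"], sorted(genes, key=lambda g: (g.chromosome, g.locus_interval.start)))
    tio.write_bed(paths["enhancers"], [e.interval for e in enhancers])
    tio.write_bed(paths["controls"], sorted((c.interval for c in controls)))
    tio.write_bed(paths["hacns"], sorted(hacns))
    tio.write_bed(paths["pseudogenes"], sorted(pseudogenes))
    tio.write_expression_tsv(paths["expression"], expr_df)
    with open(paths["dhs_pairs"], "w") as fh:
        for iv, gid in dhs_pairs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gid}\n")
    tio.write_bed(paths["breakpoints"], breakpoints)
    tio.write_axt_like(paths["alignments"], alignments)
    tio.write_snp_table(paths["snps"], snps)
    tio.write_pwm_transfac(paths["pwms"], pwms)
    tio.write_go_tsv(paths["go"], go_pairs)
    tio.write_score_track(paths["conservation"], track)

    truth = SimTruth(
        enhancer_class=enhancer_class,
        enhancer_target=enhancer_target,
        gene_destiny=gene_destiny,
        tissue_gene_ids=sorted(tissue_gene_ids),
        branch_rates={k: list(v) for k, v in cfg.branch_rates.items()},
        neutral_branch_rates=tuple(cfg.neutral_branch_rates),
        snp_rate=dict(cfg.snp_rate),
        daf_low_excess=dict(cfg.daf_low_excess),
        planted_motif_ids=[pm.motif_id for pm in cfg.planted_motifs],
        n_tele=n_tele,
        n_proximal=n_prox,
    )
    paths["truth"].write_text(truth.to_json())
    return SimDataset(genome=genome, enhancers=enhancers, controls=controls, paths=paths, truth=truth)


def _write_fasta(path: Path, genome: GenomeModel) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(genome.sequence[c]), id=c, description="")
        for c in sorted(genome.chromosomes)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# focused generators for calibration / recovery studies
# ---------------------------------------------------------------------------


def simulate_motif_dataset(
    rng: np.random.Generator,
    n_pos: int = 200,
    n_ctrl: int = 200,
    seq_len: int = 300,
    n_decoys: int = 50,
    planted_rate_pos: float = 0.8,
    planted_rate_ctrl: float = 0.1,
    motif_length: int = 10,
):
    """Random sequences with one discriminative planted motif plus decoys.

    Returns (sequences, labels, pwms, planted_id); the planted consensus is
    embedded in ``planted_rate_pos`` of positives and ``planted_rate_ctrl``
    of controls at a random offset.
    """
    cons = "".join("ACGT"[i] for i in rng.integers(0, 4, size=motif_length))
    seqs: dict[str, str] = {}
    labels: dict[str, int] = {}
    for i in range(n_pos + n_ctrl):
        sid = f"s{i:04d}"
        label = 1 if i < n_pos else -1
        s = list("ACGT"[j] for j in rng.integers(0, 4, size=seq_len))
        rate = planted_rate_pos if label == 1 else planted_rate_ctrl
        if rng.random() < rate:
            off = int(rng.integers(0, seq_len - motif_length + 1))
            s[off : off + motif_length] = list(cons)
        seqs[sid] = "".join(s)
        labels[sid] = label
    pwms = [pwm_from_consensus("M_PLANTED", cons)]
    for j in range(n_decoys):
        dcons = "".join("ACGT"[i] for i in rng.integers(0, 4, size=motif_length))
        pwms.append(pwm_from_consensus(f"M_DECOY{j:02d}", dcons))
    return seqs, labels, pwms, "M_PLANTED"


def simulate_dhs_null(
    rng: np.random.Generator,
    n_links: int = 200,
    n_genes: int = 300,
    chrom_bp: int = 200_000_000,
    link_distance: int | None = 100_000,
    block_length: int | None = 400_000,
):
    """Links placed independently of DHS blocks (containment null).

    Each link pairs a random gene with an enhancer at an offset drawn
    irrespective of that gene's block (random side; magnitude fixed at
    ``link_distance``, or uniform in [10 kb, 500 kb] when None). With
    ``block_length`` set, every block has that total length with the TSS
    at a uniform position inside; with None, the two block arms are drawn
    independently in [10 kb, 500 kb]. The fixed-magnitude, fixed-length
    defaults make the per-link containment probabilities exchangeable and
    decouple the length-matched null draws from the tested genes' own
    geometry — the regime in which the pooled binomial test is calibrated.
    Returns (links, blocks, enhancers_by_id, genes_by_id) ready for
    ``dhs_containment_test``.
    """
    from .assignment import EnhancerLink
    from .validation import DhsBlock

    genes_by_id = {}
    blocks = []
    for i in range(n_genes):
        gid = f"g{i:04d}"
        tss = int(rng.integers(2_000_000, chrom_bp - 2_000_000))
        if block_length is not None:
            left = int(rng.integers(10_000, block_length - 10_000))
            right = block_length - left
        else:
            left = int(rng.integers(10_000, 500_000))
            right = int(rng.integers(10_000, 500_000))
        lo = Interval("chr1", tss, tss + 1_000, name=gid)
        genes_by_id[gid] = GeneLocus(gid, "chr1", "+", tss, lo)
        blocks.append(DhsBlock(gid, Interval("chr1", tss - left, tss + right, name=gid)))
    gene_ids = sorted(genes_by_id)
    links = []
    enhancers_by_id = {}
    for j in range(n_links):
        gid = gene_ids[int(rng.integers(len(gene_ids)))]
        tss = genes_by_id[gid].tss_position
        mag = link_distance if link_distance is not None else int(rng.integers(10_000, 500_000))
        offset = mag * (1 if rng.random() < 0.5 else -1)
        eid = f"e{j:04d}"
        center = tss + offset
        enhancers_by_id[eid] = Interval("chr1", center - 500, center + 500, name=eid)
        links.append(
            EnhancerLink(eid, gid, abs(offset), "upstream" if offset < 0 else "downstream", "proximal", [])
        )
    return links, blocks, enhancers_by_id, genes_by_id
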