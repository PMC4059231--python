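"""Readers and writers for the flat-file formats the pipeline consumes.

Everything is plain text. Interval I/O speaks BED3/BED4 (0-based
half-open); gene models are a BED12-like TSV; alignments are an axt-like
three-row block format; the remaining inputs are simple TSVs. Malformed
lines are reported with their line number.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .core import GenomeError, GeneLocus, Interval

log = logging.getLogger(__name__)

FORMATS = (
    "bed",
    "gene_model",
    "paired_dhs",
    "snp_table",
    "pwm_transfac",
    "axt_like",
    "expression_tsv",
    "go_tsv",
    "score_track",
)


class ParseError(ValueError):
    pass


def _lines(path: str | Path):
    text = Path(path).read_text()
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield i, line


def _split(line: str) -> list[str]:
    return line.replace("\t", " ").split()


def read_intervals(path: str | Path, format_tag: str, genome=None) -> list[Any]:
    """Parse one of the supported input files.

    ``format_tag`` selects the dialect (see :data:`FORMATS`). When a
    ``genome`` (:class:`~telenhancer.core.GenomeModel`) is supplied,
    chromosome names and bounds are validated against it and an unknown
    chromosome is a hard error.
    """
    if format_tag not in FORMATS:
        raise ValueError(f"unknown format_tag {format_tag!r}; expected one of {FORMATS}")
    reader = globals()[f"_read_{format_tag}"]
    records = reader(path)
    empty = records.empty if isinstance(records, pd.DataFrame) else not records
    if empty:
        warnings.warn(f"{path}: empty {format_tag} file", stacklevel=2)
        log.warning("%s: empty %s file", path, format_tag)
    if genome is not None:
        for rec in records:
            iv = rec if isinstance(rec, Interval) else getattr(rec, "interval", None)
            if isinstance(rec, tuple) and rec and isinstance(rec[0], Interval):
                iv = rec[0]
            if iv is not None:
                genome._check_interval(iv)
    return records


def _read_bed(path) -> list[Interval]:
    out = []
    for ln, line in _lines(path):
        f = _split(line)
        if len(f) < 3:
            raise ParseError(f"{path}:{ln}: BED line needs >=3 fields: {line!r}")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: non-integer coordinate") from exc
        try:
            out.append(Interval(f[0], start, end, name=f[3] if len(f) > 3 else None))
        except GenomeError as exc:
            raise ParseError(f"{path}:{ln}: {exc}") from exc
    return out


def write_bed(path: str | Path, intervals: list[Interval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = f"\t{iv.name}" if iv.name is not None else ""
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{name}\n")


def _read_gene_model(path) -> list[GeneLocus]:
    """gene_id chrom strand tss locus_start locus_end exon_blocks.

    ``exon_blocks`` is comma-separated ``start-end`` pairs in absolute
    coordinates, or ``.`` for none.
    """
    out = []
    for ln, line in _lines(path):
        f = _split(line)
        if len(f) != 7:
            raise ParseError(f"{path}:{ln}: gene model needs 7 fields, got {len(f)}")
        gene_id, chrom, strand, tss, lstart, lend, blocks = f
        try:
            exons = []
            if blocks != ".":
                for b in blocks.split(","):
                    s, e = b.split("-")
                    exons.append(Interval(chrom, int(s), int(e)))
            out.append(
                GeneLocus(
                    gene_id=gene_id,
                    chromosome=chrom,
                    strand=strand,
                    tss_position=int(tss),
                    locus_interval=Interval(chrom, int(lstart), int(lend), name=gene_id),
                    exon_intervals=exons,
                )
            )
        except (ValueError, GenomeError) as exc:
            raise ParseError(f"{path}:{ln}: {exc}") from exc
    return out


def write_gene_model(path: str | Path, genes: list[GeneLocus]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            blocks = (
                ",".join(f"{e.start}-{e.end}" for e in g.exon_intervals)
                if g.exon_intervals
                else "."
            )
            lo = g.locus_interval
            fh.write(
                f"{g.gene_id}\t{g.chromosome}\t{g.strand}\t{g.tss_position}\t"
                f"{lo.start}\t{lo.end}\t{blocks}\n"
            )


def _read_paired_dhs(path) -> list[tuple[Interval, str]]:
    """chrom start end gene_id — one DHS-to-promoter connection per line."""
    out = []
    for ln, line in _lines(path):
        f = _split(line)
        if len(f) < 4:
            raise ParseError(f"{path}:{ln}: paired DHS needs 4 fields")
        try:
            out.append((Interval(f[0], int(f[1]), int(f[2])), f[3]))
        except (ValueError, GenomeError) as exc:
            raise ParseError(f"{path}:{ln}: {exc}") from exc
    return out


def _read_snp_table(path) -> list[tuple[str, int, float]]:
    """chrom pos daf — positions 0-based, DAF in [0,1]."""
    out = []
    for ln, line in _lines(path):
        f = _split(line)
        if len(f) < 3:
            raise ParseError(f"{path}:{ln}: SNP table needs 3 fields")
        try:
            chrom, pos, daf = f[0], int(f[1]), float(f[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: {exc}") from exc
        if not 0.0 <= daf <= 1.0:
            raise ParseError(f"{path}:{ln}: DAF {daf} outside [0,1]")
        out.append((chrom, pos, daf))
    return out


def write_snp_table(path: str | Path, snps) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tdaf\n")
        for chrom, pos, daf in snps:
            fh.write(f"{chrom}\t{pos}\t{daf:.6g}\n")


def read_snps_vcf(path: str | Path, daf_info_key: str = "DAF") -> list[tuple[str, int, float]]:
    """VCF adapter: CHROM/POS plus a DAF INFO key; positions shifted to 0-based."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if daf_info_key not in rec.info:
                continue
            val = rec.info[daf_info_key]
            if isinstance(val, tuple):
                val = val[0]
            out.append((rec.chrom, rec.pos - 1, float(val)))
    return out


def _read_pwm_transfac(path) -> list:
    """TRANSFAC-style matrices: ID line, NA (name) line, numbered rows with
    A C G T counts, terminated by ``//``. A minimal JASPAR-like dialect
    (``>motif_id name`` then four ``A|C|G|T [ n n ... ]`` rows) is accepted
    in the same file."""
    from .motifs import Pwm

    out = []
    text = Path(path).read_text()
    lines = [l.rstrip() for l in text.splitlines()]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if line.startswith(">"):
            f = line[1:].split()
            motif_id = f[0]
            name = f[1] if len(f) > 1 else motif_id
            rows = {}
            for j in range(1, 5):
                parts = lines[i + j].replace("[", " ").replace("]", " ").split()
                rows[parts[0].upper()] = [float(x) for x in parts[1:]]
            mat = np.array([rows[b] for b in "ACGT"]).T
            out.append(Pwm(motif_id=motif_id, tf_name=name, matrix=mat))
            i += 5
        elif line.startswith("ID"):
            motif_id = line.split()[1]
            name = motif_id
            rows = []
            i += 1
            while i < len(lines) and not lines[i].startswith("//"):
                l = lines[i].strip()
                if l.startswith("NA"):
                    name = l.split(None, 1)[1]
                elif l[:2].isdigit() or l.startswith("PO") or l.startswith("P0"):
                    if not (l.startswith("PO") or l.startswith("P0")):
                        vals = l.split()
                        rows.append([float(x) for x in vals[1:5]])
                i += 1
            i += 1
            if not rows:
                raise ParseError(f"{path}: matrix {motif_id} has no rows")
            out.append(Pwm(motif_id=motif_id, tf_name=name, matrix=np.array(rows)))
        else:
            raise ParseError(f"{path}: unrecognised PWM line {line!r}")
    return out


def write_pwm_transfac(path: str | Path, pwms) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f"ID {p.motif_id}\nNA {p.tf_name}\nP0 A C G T\n")
            for i, row in enumerate(p.matrix, start=1):
                fh.write(f"{i:02d} " + " ".join(f"{v:g}" for v in row) + "\n")
            fh.write("//\n")


def _read_axt_like(path) -> list:
    """Blocks of ``>element_id chrom start end`` followed by three aligned
    rows (human, chimp, macaque)."""
    from .evolution import TriAlignment

    out = []
    lines = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ParseError(f"{path}: expected alignment header, got {lines[i]!r}")
        f = lines[i][1:].split()
        if len(f) < 4:
            raise ParseError(f"{path}: alignment header needs id chrom start end")
        elem, chrom, start, end = f[0], f[1], int(f[2]), int(f[3])
        h, c, m = lines[i + 1], lines[i + 2], lines[i + 3]
        if not len(h) == len(c) == len(m):
            raise ParseError(f"{path}: ragged alignment block for {elem}")
        out.append(
            TriAlignment(
                element_id=elem,
                interval=Interval(chrom, start, end, name=elem),
                human=h.upper(),
                chimp=c.upper(),
                macaque=m.upper(),
            )
        )
        i += 4
    return out


def write_axt_like(path: str | Path, alignments) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            iv = a.interval
            fh.write(f">{a.element_id} {iv.chrom} {iv.start} {iv.end}\n")
            fh.write(f"{a.human}\n{a.chimp}\n{a.macaque}\n")


def _read_expression_tsv(path) -> pd.DataFrame:
    """genes x tissues matrix; first column gene_id, header row of tissues."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        return df
    if df.isna().any().any() or (df.values < 0).any():
        raise ParseError(f"{path}: expression must be nonnegative and complete")
    return df


def write_expression_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t")


def _read_go_tsv(path) -> list[tuple[str, str]]:
    """gene_id term_id pairs (term-name map distributed separately)."""
    out = []
    for ln, line in _lines(path):
        f = _split(line)
        if len(f) < 2:
            raise ParseError(f"{path}:{ln}: GO annotation needs 2 fields")
        out.append((f[0], f[1]))
    return out


def write_go_tsv(path: str | Path, pairs) -> None:
    with open(path, "w") as fh:
        for gene_id, term_id in pairs:
            fh.write(f"{gene_id}\t{term_id}\n")


def _read_score_track(path) -> list[tuple[str, int, float]]:
    """chrom pos score — per-base conservation values, sparse."""
    out = []
    for ln, line in _lines(path):
        f = _split(line)
        if len(f) < 3:
            raise ParseError(f"{path}:{ln}: score track needs 3 fields")
        try:
            out.append((f[0], int(f[1]), float(f[2])))
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: {exc}") from exc
    return out


def write_score_track(path: str | Path, rows) -> None:
    with open(path, "w") as fh:
        for chrom, pos, score in rows:
            fh.write(f"{chrom}\t{pos}\t{score:.4g}\n")
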