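"""End-to-end orchestration: simulate -> assign -> validate -> evolution ->
variation -> motifs -> enrichment -> summary.

Every stage consumes files produced by the generator (or supplied real
inputs) plus prior-stage outputs, writes its results as TSV into the run
directory, and logs counts in and out of every filter. The summary table
has one row per element class with human-specific and nonhuman-specific
divergence per kb, NI, the MK p-value and SNPs per kb.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assignment as asn
from . import enrichment as enr
from . import evolution as evo
from . import io as tio
from . import motifs as mot
from . import validation as val
from . import variation as var
from .core import EnhancerSeq, GenomeModel
from .simulate import SimConfig, simulate_dataset

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "telenhancer_run"
    seed: int = 0
    tissue: str = "heart"
    top_fraction: float = 0.2
    max_link_distance: int = 500_000
    promoter_exclusion_bp: int = 3_000
    phastcons_threshold: float = 0.2
    daf_cutoff: float = 0.05
    mk_alpha: float = 1e-4
    svm_c_grid: tuple = (0.01, 0.1, 1.0, 10.0)
    max_motif_seqs_per_class: int = 80
    dev_term: str = "GO:DEV"
    mito_term: str = "GO:MITO"
    simulate: dict | None = field(default_factory=dict)
    inputs: dict | None = None
    cache: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if isinstance(cfg.svm_c_grid, list):
            cfg.svm_c_grid = tuple(cfg.svm_c_grid)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _element_class(name: str, enhancer_classes: dict[str, str]) -> str | None:
    if name in enhancer_classes:
        return enhancer_classes[name]
    if "_ctrl" in name:
        return "control"
    if name.startswith("ps"):
        return "neutral"
    if name.startswith("h"):
        return "hacns"
    return None


def _load_inputs(cfg: RunConfig, outdir: Path) -> dict[str, Path]:
    if cfg.inputs:
        return {k: Path(v) for k, v in cfg.inputs.items()}
    sim_dir = outdir / "inputs"
    marker = sim_dir / ".sim_hash"
    sim_kwargs = dict(cfg.simulate or {})
    sim_kwargs.setdefault("seed", cfg.seed)
    sim_cfg = SimConfig(**sim_kwargs)
    h = hashlib.sha256(
        json.dumps(asdict(sim_cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    if cfg.cache and marker.exists() and marker.read_text() == h:
        log.info("simulate: cache hit (%s)", h)
        return {p.stem if p.suffix != ".fa" else "genome_fasta": p for p in sim_dir.iterdir() if not p.name.startswith(".")}
    ds = simulate_dataset(sim_cfg, sim_dir)
    marker.write_text(h)
    return {k: v for k, v in ds.paths.items()}


def _read_genome(paths: dict[str, Path]) -> GenomeModel:
    from Bio import SeqIO

    sequence = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(paths["genome_fasta"]), "fasta")
    }
    chromosomes = {c: len(s) for c, s in sequence.items()}
    genes = tio.read_intervals(paths["genes"], "gene_model")
    pseudogenes = tio.read_intervals(paths["pseudogenes"], "bed")
    expr = tio.read_intervals(paths["expression"], "expression_tsv")
    genome = GenomeModel(
        chromosomes=chromosomes,
        genes=genes,
        pseudogene_intervals=pseudogenes,
        sequence=sequence,
        tissue_names=list(expr.columns),
    )
    for g in genome.genes:
        if g.gene_id in expr.index:
            g.expression = expr.loc[g.gene_id].to_numpy()
    genome_expr = expr
    genome.__dict__["expression_df"] = genome_expr
    return genome


def exclude_promoter_proximal(enhancers, genes, window_bp: int):
    """Drop elements whose interval comes within ``window_bp`` of any TSS
    (promoter contamination filter for histone-mark enhancer maps)."""
    kept = []
    for e in enhancers:
        iv = e.interval
        near = any(
            g.chromosome == iv.chrom
            and iv.start - window_bp < g.tss_position < iv.end + window_bp
            for g in genes
        )
        if not near:
            kept.append(e)
    return kept


def run(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict and writes
    per-stage TSVs plus ``summary_table.tsv`` under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg.config_hash()}
    stage = "inputs"
    try:
        paths = _load_inputs(cfg, outdir)
        genome = _read_genome(paths)
        expr = genome.__dict__["expression_df"]

        # ---------------- assignment ----------------
        stage = "assign"
        go_pairs = tio.read_intervals(paths["go"], "go_tsv")
        dev_genes = {g for g, t in go_pairs if t == cfg.dev_term}
        tissue_genes = asn.select_tissue_genes(
            expr, cfg.tissue, cfg.top_fraction, extra_annotated_ids=dev_genes
        )
        enh_ivs = tio.read_intervals(paths["enhancers"], "bed", genome=genome)
        enhancers = [
            EnhancerSeq(iv.name, iv.chrom, iv, sequence=genome.fetch(iv))
            for iv in enh_ivs
        ]
        links = asn.assign_enhancers(
            enhancers, tissue_genes, genome, max_link_distance=cfg.max_link_distance
        )
        prox_ids, tele_ids = asn.classify_enhancers(links)
        log.info(
            "assign: %d enhancers in, %d linked (%d proximal, %d tele), %d dropped",
            len(enhancers), len(prox_ids) + len(tele_ids), len(prox_ids),
            len(tele_ids), len(enhancers) - len(prox_ids) - len(tele_ids),
        )
        partition = asn.partition_genes(links, {g.gene_id for g in genome.genes})
        span_stats = asn.noncoding_span_stats(partition, genome)
        asn.links_to_frame(links).to_csv(outdir / "links.tsv", sep="\t", index=False)
        span_stats.to_csv(outdir / "gene_spans.tsv", sep="\t", index=False)
        enhancer_classes = {e: "proximal" for e in prox_ids}
        enhancer_classes.update({e: "tele" for e in tele_ids})
        pd.DataFrame(
            sorted(enhancer_classes.items()), columns=["enhancer_id", "class"]
        ).to_csv(outdir / "enhancer_classes.tsv", sep="\t", index=False)
        report["assignment"] = {
            "n_enhancers": len(enhancers),
            "n_proximal": len(prox_ids),
            "n_tele": len(tele_ids),
            "n_geneP": len(partition.geneP_ids),
            "n_geneT": len(partition.geneT_ids),
            "n_bystanders": len(partition.bystander_gene_ids),
            "span_summary": span_stats.attrs["summary"],
        }

        # ---------------- validation ----------------
        stage = "validate"
        rng = np.random.default_rng([cfg.seed, 1])
        dhs_pairs = tio.read_intervals(paths["dhs_pairs"], "paired_dhs")
        blocks = val.build_dhs_blocks(dhs_pairs, genome.genes)
        enh_by_id = {e.enhancer_id: e.interval for e in enhancers}
        genes_by_id = {g.gene_id: g for g in genome.genes}
        obs, exp, p = val.dhs_containment_test(links, blocks, enh_by_id, genes_by_id, rng)
        breakpoints = tio.read_intervals(paths["breakpoints"], "bed")
        bp_res = val.breakpoint_density_test(
            links, breakpoints, genome, enh_by_id, genes_by_id,
            link_classes=enhancer_classes,
        )
        rows = [
            {"test": "dhs_containment", "class": "all", "observed": obs,
             "expected": exp, "p": p, "n": len(links)},
        ]
        for cls, r in sorted(bp_res.items()):
            rows.append(
                {"test": "breakpoint_density", "class": cls,
                 "observed": r.observed_density, "expected": r.expected_density,
                 "p": r.p_value, "n": r.n_links}
            )
        pd.DataFrame(rows).to_csv(outdir / "validation.tsv", sep="\t", index=False)
        report["validation"] = {r["test"] + "/" + r["class"]: r for r in rows}

        # ---------------- evolution ----------------
        stage = "evolution"
        alignments = tio.read_intervals(paths["alignments"], "axt_like")
        profiles: dict[str, list[evo.DivergenceProfile]] = {}
        skipped_la0 = 0
        for aln in alignments:
            cls = _element_class(aln.element_id, enhancer_classes)
            if cls is None:
                continue
            try:
                prof = evo.attribute_divergence(aln)
            except ValueError:
                skipped_la0 += 1
                continue
            profiles.setdefault(cls, []).append(prof)
        log.info("evolution: %d alignments, %d skipped for La=0", len(alignments), skipped_la0)
        pooled = {cls: evo.pool_profiles(ps, cls) for cls, ps in profiles.items()}
        neutral = pooled.get("neutral")
        evo_rows = []
        selection_fracs = {}
        for cls, pool in sorted(pooled.items()):
            row = {
                "class": cls,
                "La": pool.La,
                "Dh_per_kb": 1000 * pool.Dh,
                "Dnh_per_kb": 1000 * (pool.Dc + pool.Dm),
            }
            if neutral is not None and cls != "neutral":
                row["NI"] = evo.neutrality_index(
                    pool.Dh, pool.Dc + pool.Dm, neutral.Dh, neutral.Dc + neutral.Dm
                )
                mk = evo.mk_test(
                    [[pool.L_h, pool.L_nonhuman], [neutral.L_h, neutral.L_nonhuman]]
                )
                row["mk_p"] = mk.p_one_sided
                row["mk_direction"] = mk.direction
                labels = evo.classify_selection(profiles[cls], neutral, cfg.mk_alpha)
                selection_fracs[cls] = evo.selection_fractions(labels)
            evo_rows.append(row)
        evo_df = pd.DataFrame(evo_rows)
        evo_df.to_csv(outdir / "evolution.tsv", sep="\t", index=False)
        track = tio.read_intervals(paths["conservation"], "score_track")
        enh_elements = [e.interval for e in enhancers if e.enhancer_id in enhancer_classes]
        _, cons_stats = evo.conservation_summary(
            enh_elements, track, cfg.phastcons_threshold, classes=enhancer_classes
        )
        report["evolution"] = {
            "classes": evo_df.to_dict("records"),
            "selection_fractions": selection_fracs,
            "conservation": cons_stats,
        }

        # ---------------- variation ----------------
        stage = "variation"
        snps = tio.read_intervals(paths["snps"], "snp_table")
        elements_by_class: dict[str, list] = {}
        alignable: dict[str, int] = {}
        for aln in alignments:
            cls = _element_class(aln.element_id, enhancer_classes)
            if cls is None:
                continue
            elements_by_class.setdefault(cls, []).append(aln.interval)
            prof = next((p for p in profiles.get(cls, []) if p.element_id == aln.element_id), None)
            alignable[cls] = alignable.get(cls, 0) + (prof.La if prof else 0)
        density, density_p = var.snp_density(elements_by_class, snps, alignable)
        hist, low_daf, daf_p = var.daf_spectrum(
            elements_by_class, snps, daf_cutoff=cfg.daf_cutoff, reference_class=None
        )
        excess = {}
        if "neutral" in low_daf:
            for cls in low_daf:
                if cls == "neutral" or cls not in density:
                    continue
                n_cls = density[cls].n_snps
                k_cls = int(round(low_daf[cls] * n_cls))
                if n_cls:
                    excess[cls] = var.excess_low_daf(k_cls, n_cls, low_daf["neutral"])
        var_rows = [
            {"class": cls, "snps_per_kb": d.snps_per_kb, "n_snps": d.n_snps,
             "low_daf_fraction": low_daf.get(cls, float("nan"))}
            for cls, d in sorted(density.items())
        ]
        pd.DataFrame(var_rows).to_csv(outdir / "variation.tsv", sep="\t", index=False)
        report["variation"] = {
            "density": {c: vars(d) for c, d in density.items()},
            "density_p": {f"{a}|{b}": p for (a, b), p in density_p.items()},
            "low_daf": low_daf,
            "low_daf_p": {f"{a}|{b}": p for (a, b), p in daf_p.items()},
            "excess_low_daf_points": {c: e for c, (e, _) in excess.items()},
        }

        # ---------------- motifs ----------------
        stage = "motifs"
        rng_m = np.random.default_rng([cfg.seed, 2])
        pwms = tio.read_intervals(paths["pwms"], "pwm_transfac")
        ctrl_ivs = tio.read_intervals(paths["controls"], "bed")
        controls = [
            EnhancerSeq(iv.name or f"ctrl{i}", iv.chrom, iv, sequence=genome.fetch(iv))
            for i, iv in enumerate(ctrl_ivs)
        ]
        signatures = {}
        enrich = {}
        cap = cfg.max_motif_seqs_per_class
        for cls in ("tele", "proximal"):
            pos = [e for e in enhancers if enhancer_classes.get(e.enhancer_id) == cls]
            if len(pos) < 2 or len(controls) < 2:
                continue
            pos = pos[:cap]
            neg = controls[: 2 * cap]
            seqs = {e.enhancer_id: e.sequence for e in pos}
            seqs.update({c.enhancer_id: c.sequence for c in neg})
            labels = {e.enhancer_id: 1 for e in pos}
            labels.update({c.enhancer_id: -1 for c in neg})
            feats = mot.build_feature_matrix(seqs, labels, pwms)
            signatures[cls] = mot.fit_linear_svm(
                feats, c_grid=cfg.svm_c_grid, seed=cfg.seed
            )
            enrich[cls] = mot.motif_enrichment(feats)
        motif_rows = []
        for cls, sig in signatures.items():
            folds = {e.motif_id: e for e in enrich[cls]}
            for rank, (mid, w) in enumerate(sig.ranked_motifs(), start=1):
                e = folds[mid]
                motif_rows.append(
                    {"class": cls, "motif_id": mid, "weight": w, "rank": rank,
                     "enrichment_fold": e.fold, "p": e.p_value}
                )
        pd.DataFrame(motif_rows).to_csv(outdir / "motifs.tsv", sep="\t", index=False)
        report["motifs"] = {
            cls: {"C": sig.C, "training_accuracy": sig.training_accuracy,
                  "top_motifs": [m for m, _ in sig.ranked_motifs()[:5]]}
            for cls, sig in signatures.items()
        }
        if len(signatures) == 2:
            shared, only_t, only_p, frac = mot.compare_signatures(
                signatures["tele"], signatures["proximal"]
            )
            report["motifs"]["shared_positive_fraction"] = frac
            report["motifs"]["tele_specific"] = sorted(only_t)
            report["motifs"]["proximal_specific"] = sorted(only_p)

        # ---------------- enrichment ----------------
        stage = "enrichment"
        rng_e = np.random.default_rng([cfg.seed, 3])
        annotations = enr.annotations_from_pairs(go_pairs)
        universe = {g.gene_id for g in genome.genes} & {g for g, _ in go_pairs}
        spans = enr.gene_locus_spans(genome)
        go_results = {}
        for label, group in (("GeneT", partition.geneT_ids), ("GeneP", partition.geneP_ids)):
            grp = group & universe
            if grp:
                res = enr.hypergeom_enrichment(grp, annotations, universe)
                go_results[label] = [vars(r) for r in res[:10]]
        mito_genes = {g for g, t in go_pairs if t == cfg.mito_term}
        contrast = enr.group_function_contrast(
            partition.geneT_ids, partition.geneP_ids,
            {"mitochondrial": mito_genes}, spans, rng_e,
        )
        rel = {
            g.gene_id: g.relative_expression(genome.tissue_names.index(cfg.tissue))
            for g in genome.genes if g.expression is not None
        }
        expr_contrast = enr.expression_contrast(
            partition.geneT_ids, partition.geneP_ids, rel
        )
        pd.DataFrame(
            [r for rs in go_results.values() for r in rs]
        ).to_csv(outdir / "go_enrichment.tsv", sep="\t", index=False)
        report["enrichment"] = {
            "go_top": go_results,
            "function_contrast": contrast,
            "expression_contrast": expr_contrast,
        }

        # ---------------- summary ----------------
        stage = "summary"
        table = summarize_table1(pooled, density)
        table.to_csv(outdir / "summary_table.tsv", sep="\t", index=False)
        report["summary_table"] = table.to_dict("records")
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str, sort_keys=True))
    return report


def summarize_table1(
    pooled: dict[str, "evo.DivergenceProfile"],
    density: dict[str, "var.DiversityProfile"] | None = None,
) -> pd.DataFrame:
    """Class table: human-/nonhuman-specific divergence per kb, NI, MK p,
    SNPs per kb — one row per element class plus the neutral reference."""
    neutral = pooled.get("neutral")
    rows = []
    order = ["proximal", "tele", "neutral", "control", "hacns"]
    for cls in sorted(pooled, key=lambda c: order.index(c) if c in order else 99):
        pool = pooled[cls]
        row = {
            "class": cls,
            "human_specific_per_kb": round(1000 * pool.Dh, 2),
            "nonhuman_specific_per_kb": round(1000 * (pool.Dc + pool.Dm), 2),
        }
        if cls == "neutral":
            row["NI"] = 1.0
            row["mk_p"] = float("nan")
        elif neutral is not None:
            row["NI"] = round(
                evo.neutrality_index(
                    pool.Dh, pool.Dc + pool.Dm, neutral.Dh, neutral.Dc + neutral.Dm
                ),
                2,
            )
            mk = evo.mk_test(
                [[pool.L_h, pool.L_nonhuman], [neutral.L_h, neutral.L_nonhuman]]
            )
            row["mk_p"] = mk.p_one_sided
        else:
            log.warning("summary: no neutral reference, NI column omitted")
        if density and cls in density:
            row["snps_per_kb"] = round(density[cls].snps_per_kb, 2)
        rows.append(row)
    return pd.DataFrame(rows)
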