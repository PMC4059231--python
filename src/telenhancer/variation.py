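"""Polymorphism contrasts: SNP density and the derived-allele-frequency
spectrum of enhancer classes.

Nucleotide diversity is summarised as SNPs per kilobase of alignable
sequence (element length when no alignability mask is supplied). Purifying
selection shifts the DAF spectrum toward rare variants, so classes are
compared on their fraction of SNPs with DAF below a cutoff (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Interval

DEFAULT_DAF_CUTOFF = 0.05
DEFAULT_BINS = 20


@dataclass
class DiversityProfile:
    label: str
    snps_per_kb: float
    n_snps: int
    alignable_bp: int
    low_daf_fraction: float = float("nan")


def _snps_in(elements: list[Interval], snps) -> list[float]:
    """DAFs of SNPs falling inside any element (half-open membership)."""
    by_chrom: dict[str, list[Interval]] = {}
    for el in elements:
        by_chrom.setdefault(el.chrom, []).append(el)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)
    dafs = []
    for chrom, pos, daf in snps:
        ivs = by_chrom.get(chrom)
        if not ivs:
            continue
        starts = [iv.start for iv in ivs]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and ivs[i].contains_point(pos):
            dafs.append(daf)
    return dafs


def snp_density(
    elements_by_class: dict[str, list[Interval]],
    snps,
    alignable_bp_by_class: dict[str, int] | None = None,
) -> tuple[dict[str, DiversityProfile], dict[tuple[str, str], float]]:
    """Pooled SNPs per alignable kb per class, plus pairwise binomial tests.

    The pairwise test compares one class's SNP count, at the pooled rate
    implied by the other class, over its own alignable bp (two-sided).
    Classes with zero alignable bp are excluded.
    """
    profiles: dict[str, DiversityProfile] = {}
    for cls, elements in elements_by_class.items():
        bp = (
            alignable_bp_by_class.get(cls)
            if alignable_bp_by_class
            else sum(len(e) for e in elements)
        )
        if not bp:
            continue
        dafs = _snps_in(elements, snps)
        profiles[cls] = DiversityProfile(
            label=cls,
            snps_per_kb=1000.0 * len(dafs) / bp,
            n_snps=len(dafs),
            alignable_bp=bp,
        )
    pvals: dict[tuple[str, str], float] = {}
    names = sorted(profiles)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pa, pb = profiles[a], profiles[b]
            rate_b = pb.n_snps / pb.alignable_bp
            if 0 < rate_b < 1:
                pvals[(a, b)] = float(
                    stats.binomtest(pa.n_snps, pa.alignable_bp, rate_b).pvalue
                )
    return profiles, pvals


def daf_spectrum(
    elements_by_class: dict[str, list[Interval]],
    snps,
    bins: int = DEFAULT_BINS,
    daf_cutoff: float = DEFAULT_DAF_CUTOFF,
    reference_class: str | None = None,
):
    """Normalised DAF histogram and low-DAF fraction per class.

    Returns (histograms, low_daf, pairwise_p): histograms maps class to a
    (density, bin_edges) pair summing to 1; low_daf maps class to the
    fraction of its SNPs with DAF < ``daf_cutoff``; pairwise_p holds
    one-sided binomial tests of each class's low-DAF count at every other
    class's low-DAF rate (alternative: greater, the purifying-selection
    direction), keyed (class, reference). Classes with zero SNPs are
    excluded.
    """
    edges = np.linspace(0.0, 1.0, bins + 1)
    dafs_by_class = {
        cls: np.asarray(_snps_in(elements, snps))
        for cls, elements in elements_by_class.items()
    }
    dafs_by_class = {c: d for c, d in dafs_by_class.items() if d.size}
    histograms = {}
    low_daf = {}
    for cls, d in dafs_by_class.items():
        counts, _ = np.histogram(d, bins=edges)
        histograms[cls] = (counts / counts.sum(), edges)
        low_daf[cls] = float(np.mean(d < daf_cutoff))
    pairwise_p: dict[tuple[str, str], float] = {}
    for cls, d in dafs_by_class.items():
        for ref, dref in dafs_by_class.items():
            if ref == cls:
                continue
            if reference_class is not None and ref != reference_class:
                continue
            p_ref = float(np.mean(dref < daf_cutoff))
            if 0 < p_ref < 1:
                k = int(np.sum(d < daf_cutoff))
                pairwise_p[(cls, ref)] = float(
                    stats.binomtest(k, d.size, p_ref, alternative="greater").pvalue
                )
    return histograms, low_daf, pairwise_p


def excess_low_daf(
    class_count: int,
    class_n: int,
    reference_fraction: float,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Low-DAF excess of a class over a reference, in percentage points,
    with the binomial p of the class count at the reference rate."""
    if class_n < 1:
        raise ValueError("class has no SNPs")
    if not 0 <= reference_fraction <= 1:
        raise ValueError("reference fraction outside [0,1]")
    excess = 100.0 * (class_count / class_n - reference_fraction)
    if 0 < reference_fraction < 1:
        p = float(
            stats.binomtest(class_count, class_n, reference_fraction, alternative=alternative).pvalue
        )
    else:
        p = 1.0
    return excess, p
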