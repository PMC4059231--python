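"""Lineage-specific divergence, Neutrality Index and the MK test.

Given human-chimp-macaque three-way alignments, a substitution is
attributed to the branch of the single species that disagrees with the
other two (unweighted parsimony on a three-taxon star). Per-site
differences are corrected for multiple hits with the one-parameter
Jukes-Cantor formula. Selection on the human lineage is summarised by the
Neutrality Index

    NI = (Dh / Nh) / ((Dc + Dm) / (Nc + Nm)),

the human-vs-nonhuman divergence ratio of a region normalised by the same
ratio in a neutral reference (pooled pseudogene alignments); NI < 1
indicates purifying and NI > 1 positive selection on the human branch.
Significance comes from a McDonald-Kreitman-style Fisher exact test on the
raw outlier counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import Interval

_GAPLESS = frozenset("ACGT")


@dataclass
class TriAlignment:
    """Three aligned rows for one element; columns with a gap or N in any
    species are excluded from the alignable length La."""

    element_id: str
    interval: Interval
    human: str
    chimp: str
    macaque: str

    def __post_init__(self) -> None:
        if not len(self.human) == len(self.chimp) == len(self.macaque):
            raise ValueError(f"{self.element_id}: ragged alignment")

    def columns(self):
        for h, c, m in zip(self.human, self.chimp, self.macaque):
            if h in _GAPLESS and c in _GAPLESS and m in _GAPLESS:
                yield h, c, m


@dataclass
class DivergenceProfile:
    element_id: str
    La: int
    L_h: int = 0
    L_c: int = 0
    L_m: int = 0

    @property
    def dh(self) -> float:
        return self.L_h / self.La

    @property
    def dc(self) -> float:
        return self.L_c / self.La

    @property
    def dm(self) -> float:
        return self.L_m / self.La

    @property
    def Dh(self) -> float:
        return jukes_cantor(self.dh)

    @property
    def Dc(self) -> float:
        return jukes_cantor(self.dc)

    @property
    def Dm(self) -> float:
        return jukes_cantor(self.dm)

    @property
    def D_nonhuman(self) -> float:
        return self.Dc + self.Dm

    @property
    def L_nonhuman(self) -> int:
        return self.L_c + self.L_m


def attribute_divergence(aln: TriAlignment) -> DivergenceProfile:
    """Count outlier columns per species over the alignable length.

    A column contributes to L_h when chimp equals macaque and human is the
    outlier (symmetrically for L_c, L_m). Columns where all three agree, or
    all three differ (no parsimony-unambiguous branch), contribute nothing.
    """
    La = 0
    L = {"h": 0, "c": 0, "m": 0}
    for h, c, m in aln.columns():
        La += 1
        if h == c == m:
            continue
        if c == m and h != c:
            L["h"] += 1
        elif h == m and c != h:
            L["c"] += 1
        elif h == c and m != h:
            L["m"] += 1
        # all-different column: dropped
    if La == 0:
        raise ValueError(f"{aln.element_id}: no three-way-alignable columns")
    return DivergenceProfile(aln.element_id, La, L["h"], L["c"], L["m"])


def pool_profiles(profiles, element_id: str = "pooled") -> DivergenceProfile:
    """Sum counts over elements (class-level divergence)."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("nothing to pool")
    return DivergenceProfile(
        element_id,
        La=sum(p.La for p in profiles),
        L_h=sum(p.L_h for p in profiles),
        L_c=sum(p.L_c for p in profiles),
        L_m=sum(p.L_m for p in profiles),
    )


def jukes_cantor(d: float) -> float:
    """One-parameter multiple-hit correction D = -(3/4) ln(1 - (4/3) d)."""
    if not 0.0 <= d < 0.75:
        raise ValueError(f"per-site difference {d} outside [0, 0.75): JC saturated")
    if d == 0.0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * d / 3.0)


def neutrality_index(
    Dh: float, D_nonhuman: float, Nh: float, N_nonhuman: float
) -> float:
    """(Dh/Nh) / (D_nonhuman/N_nonhuman); all inputs must be positive."""
    for name, v in (("Dh", Dh), ("D_nonhuman", D_nonhuman), ("Nh", Nh), ("N_nonhuman", N_nonhuman)):
        if v <= 0:
            raise ValueError(f"neutrality index undefined: {name}={v} <= 0")
    return (Dh / Nh) / (D_nonhuman / N_nonhuman)


@dataclass
class MkResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    direction: str  # "negative" | "positive"
    p_one_sided: float
    p_two_sided: float
    degenerate: bool = False


def mk_test(counts) -> MkResult:
    """Fisher's exact test on raw substitution counts.

    ``counts`` is a 2x2 of nonnegative integers:
    ``[[element human-specific, element nonhuman-specific],
    [neutral human-specific, neutral nonhuman-specific]]``.
    Direction is *negative* (purifying on the human branch) when the
    element's human-specific proportion is below the neutral reference's,
    *positive* otherwise. A zero margin gives p = 1 with a degeneracy flag.
    """
    (a, b), (c, d) = counts
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError(f"MK counts must be nonnegative integers, got {counts}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return MkResult(((a, b), (c, d)), "negative", 1.0, 1.0, degenerate=True)
    elem_frac = a / (a + b)
    neut_frac = c / (c + d)
    direction = "negative" if elem_frac < neut_frac else "positive"
    alternative = "less" if direction == "negative" else "greater"
    p1 = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1]
    p2 = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    return MkResult(((a, b), (c, d)), direction, float(p1), float(p2))


def classify_selection(
    profiles: list[DivergenceProfile],
    neutral: DivergenceProfile,
    alpha: float = 1e-4,
) -> dict[str, str]:
    """Per-element selection label against the pooled neutral reference.

    An element is *positive*/*negative* when its one-sided MK p-value in
    the observed direction beats ``alpha``; otherwise *neutral*.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    labels: dict[str, str] = {}
    for p in profiles:
        res = mk_test([[p.L_h, p.L_nonhuman], [neutral.L_h, neutral.L_nonhuman]])
        labels[p.element_id] = res.direction if res.p_one_sided < alpha else "neutral"
    return labels


def selection_fractions(labels: dict[str, str]) -> dict[str, float]:
    n = len(labels)
    return {
        lab: sum(1 for v in labels.values() if v == lab) / n
        for lab in ("positive", "negative", "neutral")
    }


@dataclass
class ConservationSummary:
    element_id: str
    mean_score: float
    covered_bp: int


def conservation_summary(
    elements: list[Interval],
    score_track,
    threshold: float = 0.2,
    classes: dict[str, str] | None = None,
):
    """Per-element mean conservation and class-level high-conservation
    fractions.

    ``score_track`` is an iterable of (chrom, pos, score). Bases missing
    from the track are excluded from the mean (not imputed as zero);
    elements entirely outside the track are excluded and counted. Returns
    (summaries, class_stats) where class_stats maps class label to
    ``{"fraction_above", "n", "p_vs_other"}`` — the binomial comparison is
    of each class's above-threshold count at the other class's rate.
    """
    by_chrom: dict[str, dict[int, float]] = {}
    for chrom, pos, score in score_track:
        by_chrom.setdefault(chrom, {})[pos] = score
    summaries: list[ConservationSummary] = []
    excluded = 0
    for el in elements:
        track = by_chrom.get(el.chrom, {})
        vals = [track[p] for p in range(el.start, el.end) if p in track]
        if not vals:
            excluded += 1
            continue
        summaries.append(
            ConservationSummary(el.name or f"{el.chrom}:{el.start}", float(np.mean(vals)), len(vals))
        )
    class_stats: dict[str, dict[str, float]] = {}
    if classes:
        counts: dict[str, tuple[int, int]] = {}
        for s in summaries:
            cls = classes.get(s.element_id)
            if cls is None:
                continue
            above, n = counts.get(cls, (0, 0))
            counts[cls] = (above + (s.mean_score > threshold), n + 1)
        for cls, (above, n) in counts.items():
            others = [c for c in counts if c != cls]
            stat = {"fraction_above": above / n, "n": n, "excluded": excluded}
            if len(others) == 1:
                o_above, o_n = counts[others[0]]
                if 0 < o_above < o_n:
                    stat["p_vs_other"] = float(
                        stats.binomtest(above, n, o_above / o_n).pvalue
                    )
            class_stats[cls] = stat
    return summaries, class_stats
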