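"""Divergence attribution, Jukes-Cantor, NI and the MK test, each checked
against closed forms or brute-force hypergeometric enumeration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telenhancer.core import Interval
from telenhancer.evolution import (
    TriAlignment,
    attribute_divergence,
    classify_selection,
    conservation_summary,
    jukes_cantor,
    mk_test,
    neutrality_index,
    pool_profiles,
    DivergenceProfile,
)


def _aln(h, c, m, eid="e"):
    return TriAlignment(eid, Interval("chr1", 0, len(h), name=eid), h, c, m)


# ---------------------------------------------------------------- oracles


def _hypergeom_pmf(k, N, K, n):
    if k < max(0, n + K - N) or k > min(K, n):
        return 0.0
    return math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)


def fisher_oracle(a, b, c, d):
    """One-sided (less/greater) and two-sided Fisher p by enumeration."""
    N, K, n = a + b + c + d, a + b, a + c
    pmf = [_hypergeom_pmf(k, N, K, n) for k in range(n + 1)]
    less = sum(pmf[: a + 1])
    greater = sum(pmf[a:])
    p_obs = pmf[a]
    two = sum(p for p in pmf if p <= p_obs * (1 + 1e-9))
    return less, greater, min(1.0, two)


# ---------------------------------------------------------------- tests


class TestAttributeDivergence:
    def test_direct_outlier_counting(self):
        h = "A" * 190 + "C" * 10
        c = "A" * 200
        m = "A" * 200
        prof = attribute_divergence(_aln(h, c, m))
        assert prof.La == 200 and prof.L_h == 10
        assert prof.dh == pytest.approx(0.05)
        assert prof.L_c == prof.L_m == 0

    def test_identical_rows_give_zero(self):
        prof = attribute_divergence(_aln("ACGT" * 10, "ACGT" * 10, "ACGT" * 10))
        assert (prof.dh, prof.dc, prof.dm) == (0, 0, 0)

    def test_all_different_column_contributes_nothing(self):
        prof = attribute_divergence(_aln("AA", "AC", "AG"))
        assert prof.La == 2
        assert prof.L_h == prof.L_c == prof.L_m == 0

    def test_gap_columns_excluded_from_la(self):
        prof = attribute_divergence(_aln("AC-T", "A-GT", "ACGT"))
        assert prof.La == 2  # two fully ungapped columns

    def test_no_alignable_columns_errors(self):
        with pytest.raises(ValueError, match="alignable"):
            attribute_divergence(_aln("--", "AC", "AC"))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.sampled_from("ACGT"), min_size=5, max_size=60).map("".join),
           st.integers(0, 2**31 - 1))
    def test_swapping_chimp_macaque_swaps_their_counts(self, h, seed):
        r = np.random.default_rng(seed)
        c = "".join(r.choice(list("ACGT"), size=len(h)))
        m = "".join(r.choice(list("ACGT"), size=len(h)))
        p1 = attribute_divergence(_aln(h, c, m))
        p2 = attribute_divergence(_aln(h, m, c))
        assert (p1.L_h, p1.L_c, p1.L_m) == (p2.L_h, p2.L_m, p2.L_c)


class TestJukesCantor:
    def test_closed_form_values(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.05) == pytest.approx(0.051744653, abs=1e-8)
        assert jukes_cantor(0.1) == pytest.approx(0.107325632, abs=1e-8)

    def test_monotone_and_bounded_below_by_d(self):
        grid = np.linspace(0.0, 0.74, 200)
        D = np.array([jukes_cantor(d) for d in grid])
        assert (np.diff(D) > 0).all()
        assert (D >= grid).all()

    def test_saturation_error(self):
        with pytest.raises(ValueError, match="saturated"):
            jukes_cantor(0.75)
        with pytest.raises(ValueError):
            jukes_cantor(-0.01)


class TestNeutralityIndex:
    @pytest.mark.parametrize(
        "Dh,Dnh,expected",
        [
            (5.66, 60.01, 0.77),  # proximal enhancers
            (5.47, 59.53, 0.75),  # tele-enhancers
            (6.42, 62.34, 0.84),  # matched controls
            (17.24, 29.75, 4.75),  # human-accelerated CNSs
        ],
    )
    def test_published_worked_examples(self, Dh, Dnh, expected):
        assert round(neutrality_index(Dh, Dnh, 9.14, 74.9), 2) == expected

    def test_neutral_reference_against_itself_is_one(self):
        assert neutrality_index(9.14, 74.9, 9.14, 74.9) == pytest.approx(1.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            neutrality_index(0.0, 1.0, 1.0, 1.0)


class TestMkTest:
    def test_one_sided_matches_hypergeometric_tail(self):
        res = mk_test([[5, 95], [20, 80]])
        less, greater, two = fisher_oracle(5, 95, 20, 80)
        assert res.direction == "negative"
        assert res.p_one_sided == pytest.approx(less, rel=1e-9)
        assert res.p_two_sided == pytest.approx(two, rel=1e-6)

    def test_identical_proportions_two_sided_one(self):
        res = mk_test([[10, 90], [10, 90]])
        assert res.p_two_sided == pytest.approx(1.0)

    def test_zero_margin_degenerate(self):
        res = mk_test([[0, 0], [10, 90]])
        assert res.degenerate and res.p_one_sided == 1.0

    def test_rejects_non_integer_counts(self):
        with pytest.raises(ValueError):
            mk_test([[1.5, 2], [3, 4]])

    def test_brute_force_equivalence_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 16, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            res = mk_test([[a, b], [c, d]])
            less, greater, two = fisher_oracle(int(a), int(b), int(c), int(d))
            expected_one = less if res.direction == "negative" else greater
            assert res.p_one_sided == pytest.approx(expected_one, rel=1e-8)
            assert res.p_two_sided == pytest.approx(two, rel=1e-6)


class TestClassifySelection:
    def test_threshold_rule(self):
        neutral = DivergenceProfile("neutral", 100_000, 900, 3_000, 3_100)
        strong = DivergenceProfile("pos", 10_000, 400, 290, 300)
        weak = DivergenceProfile("mid", 10_000, 95, 300, 310)
        labels = classify_selection([strong, weak], neutral, alpha=1e-4)
        assert labels["pos"] == "positive"
        assert labels["mid"] == "neutral"

    def test_alpha_bounds(self):
        neutral = DivergenceProfile("neutral", 1000, 10, 30, 30)
        with pytest.raises(ValueError):
            classify_selection([], neutral, alpha=0.0)


class TestConservationSummary:
    def _track(self, values, start=0):
        return [("chr1", start + i, v) for i, v in enumerate(values)]

    def test_constant_track_mean(self):
        el = Interval("chr1", 0, 10, name="e1")
        (s,), _ = conservation_summary([el], self._track([0.5] * 10))
        assert s.mean_score == pytest.approx(0.5)

    def test_class_fraction_above_threshold(self):
        els = [Interval("chr1", 0, 4, name="a"), Interval("chr1", 10, 14, name="b")]
        track = self._track([0.1] * 4) + self._track([0.3] * 4, start=10)
        _, stats_ = conservation_summary(
            els, track, threshold=0.2, classes={"a": "x", "b": "x"}
        )
        assert stats_["x"]["fraction_above"] == pytest.approx(0.5)

    def test_missing_bases_excluded_not_imputed(self):
        el = Interval("chr1", 0, 10, name="e1")
        (s,), _ = conservation_summary([el], self._track([1.0] * 5))
        assert s.mean_score == pytest.approx(1.0) and s.covered_bp == 5

    def test_uncovered_element_excluded(self):
        els = [Interval("chr1", 100, 110, name="far")]
        summaries, _ = conservation_summary(els, self._track([0.5] * 5))
        assert summaries == []


def test_pooling_sums_counts():
    p1 = DivergenceProfile("a", 100, 2, 3, 4)
    p2 = DivergenceProfile("b", 50, 1, 0, 2)
    pool = pool_profiles([p1, p2])
    assert (pool.La, pool.L_h, pool.L_c, pool.L_m) == (150, 3, 3, 6)
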