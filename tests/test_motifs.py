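"""PWM scanning (with a brute-force oracle), SVM signatures and
enrichment folds."""

import numpy as np
import pytest

from telenhancer.motifs import (
    MotifFeatureMatrix,
    Pwm,
    build_feature_matrix,
    compare_signatures,
    fit_linear_svm,
    motif_enrichment,
    revcomp,
    scan_pwm,
)
from telenhancer.simulate import pwm_from_consensus


def indicator_pwm(consensus="ACGT"):
    mat = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = 1.0
    return Pwm("IND", "ind", mat)


def brute_force_hits(seq, pwm, fraction, background=None):
    """Position-by-position rescan, scoring each window independently."""
    lom = pwm.log_odds(background)
    cutoff = fraction * lom.max(axis=1).sum()
    hits = []
    for strand, lo in (("+", lom), ("-", lom[::-1, ::-1])):
        for p in range(len(seq) - len(pwm) + 1):
            window = seq[p : p + len(pwm)].upper()
            if any(b not in "ACGT" for b in window):
                continue
            score = sum(lo[i, "ACGT".index(b)] for i, b in enumerate(window))
            if score >= cutoff - 1e-12:
                hits.append((p, strand, pytest.approx(score)))
    return sorted(hits)


class TestScanPwm:
    def test_indicator_motif_exact_hit(self):
        hits = scan_pwm("TTACGTTT", indicator_pwm(), score_threshold_fraction=1.0)
        fwd = [h for h in hits if h[1] == "+"]
        rev = [h for h in hits if h[1] == "-"]
        assert [h[0] for h in fwd] == [2]
        # ACGT is its own reverse complement: the same window matches on "-"
        assert [h[0] for h in rev] == [2]

    def test_no_perfect_match_no_hits(self):
        assert scan_pwm("TTTTTTTT", indicator_pwm(), 1.0) == []

    def test_sequence_shorter_than_motif_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            scan_pwm("AC", indicator_pwm(), 0.8)

    def test_matches_brute_force_on_random_sequences(self, rng):
        pwms = [pwm_from_consensus("M1", "ACGTAC"), pwm_from_consensus("M2", "TTGACA")]
        for _ in range(50):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=200))
            for pwm in pwms:
                got = scan_pwm(seq, pwm, 0.8)
                want = brute_force_hits(seq, pwm, 0.8)
                assert [(p, s) for p, s, _ in got] == [(p, s) for p, s, _ in want]

    def test_reverse_complement_symmetry(self, rng):
        pwm = pwm_from_consensus("M", "ACGGTCA")
        for _ in range(20):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=120))
            fwd = scan_pwm(seq, pwm, 0.8)
            rc = scan_pwm(revcomp(seq), pwm, 0.8)
            m, n = len(pwm), len(seq)
            mirrored = sorted(
                (n - m - p, {"+": "-", "-": "+"}[s]) for p, s, _ in fwd
            )
            assert mirrored == sorted((p, s) for p, s, _ in rc)

    def test_n_windows_never_hit(self):
        assert scan_pwm("NNNNNNNN", indicator_pwm(), 0.5) == []

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            Pwm("bad", "bad", -np.ones((4, 4)))


class TestFeatureMatrix:
    def test_hits_per_kb_normalisation(self):
        seq = "T" * 244 + "ACGTAC" + "T" * 250  # 500 bp, one planted site
        pwm = pwm_from_consensus("M1", "ACGTAC")
        feats = build_feature_matrix({"s1": seq}, {"s1": 1}, [pwm], threshold=0.95,
                                     background=np.full(4, 0.25))
        assert feats.values[0, 0] == pytest.approx(1000 * 1 / 500)

    def test_zero_column_retained_and_order_canonical(self):
        seqs = {"b": "ACGT" * 50, "a": "TTTT" * 50}
        labels = {"a": 1, "b": -1}
        pwms = [pwm_from_consensus("Z2", "GGGGGG"), pwm_from_consensus("A1", "CCCCCC")]
        feats = build_feature_matrix(seqs, labels, pwms)
        assert feats.seq_ids == ["a", "b"]
        assert feats.motif_ids == ["A1", "Z2"]
        assert feats.values.shape == (2, 2)


class TestLinearSvm:
    def _toy(self, rng, n=40):
        x1 = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        x2 = rng.normal(size=n) * 0.1
        values = np.c_[x1, x2]
        labels = np.r_[np.ones(n // 2), -np.ones(n // 2)].astype(int)
        return MotifFeatureMatrix(
            values=np.abs(values), seq_ids=[f"s{i}" for i in range(n)],
            motif_ids=["sig", "noise"], labels=labels,
            lengths_bp=np.full(n, 1000.0),
        )

    def test_separable_toy_weights(self, rng):
        feats = self._toy(rng)
        sig = fit_linear_svm(feats, C=1.0)
        assert sig.weights["sig"] > 0
        assert abs(sig.weights["sig"]) > 5 * abs(sig.weights["noise"])
        assert sig.training_accuracy == 1.0

    def test_label_flip_negates_weights(self, rng):
        feats = self._toy(rng)
        flipped = MotifFeatureMatrix(
            values=feats.values, seq_ids=feats.seq_ids, motif_ids=feats.motif_ids,
            labels=-feats.labels, lengths_bp=feats.lengths_bp,
        )
        a = fit_linear_svm(feats, C=1.0)
        b = fit_linear_svm(flipped, C=1.0)
        assert a.weights["sig"] == pytest.approx(-b.weights["sig"], rel=1e-3)

    def test_single_class_rejected(self, rng):
        feats = self._toy(rng)
        feats.labels[:] = 1
        with pytest.raises(ValueError, match="both classes"):
            fit_linear_svm(feats, C=1.0)

    def test_objective_sanity_and_decision_reproduces_accuracy(self, rng):
        feats = self._toy(rng)
        sig = fit_linear_svm(feats, C=1.0)
        w = np.array([sig.weights[m] for m in feats.motif_ids])
        margins = feats.labels * (feats.values @ w + sig.bias)
        obj = 0.5 * w @ w + 1.0 * np.maximum(0, 1 - margins).sum()
        assert obj <= 1.0 * len(feats.labels) + 1e-6  # objective at w=0 is C*n
        pred = np.sign(feats.values @ w + sig.bias)
        assert (pred == feats.labels).mean() == sig.training_accuracy


class TestEnrichment:
    def _feats(self, enh_hits, ctrl_hits, length=1000.0):
        n = len(enh_hits) + len(ctrl_hits)
        values = np.array(enh_hits + ctrl_hits, dtype=float)[:, None] / (length / 1000)
        return MotifFeatureMatrix(
            values=values, seq_ids=[f"s{i}" for i in range(n)], motif_ids=["M"],
            labels=np.array([1] * len(enh_hits) + [-1] * len(ctrl_hits)),
            lengths_bp=np.full(n, length),
        )

    def test_twofold_enrichment(self):
        (res,) = motif_enrichment(self._feats([10, 10], [5, 5]), pseudocount=0.0)
        assert res.fold == pytest.approx(2.0)

    def test_equal_rates_fold_one(self):
        (res,) = motif_enrichment(self._feats([5, 5], [5, 5]), pseudocount=0.0)
        assert res.fold == pytest.approx(1.0)
        assert res.p_value > 0.5

    def test_no_hits_flagged(self):
        (res,) = motif_enrichment(self._feats([0, 0], [0, 0]))
        assert res.flagged and np.isnan(res.fold)


class TestCompareSignatures:
    def _sig(self, weights):
        from telenhancer.motifs import SvmSignature

        return SvmSignature(weights=weights, bias=0.0, C=1.0, training_accuracy=1.0,
                            motif_ids=sorted(weights))

    def test_identical_signatures_fully_shared(self):
        s = self._sig({"a": 1.0, "b": -0.5})
        shared, oa, ob, frac = compare_signatures(s, s)
        assert shared == {"a"} and frac == 1.0

    def test_disjoint_positive_sets(self):
        a = self._sig({"a": 1.0, "b": -1.0})
        b = self._sig({"a": -1.0, "b": 1.0})
        shared, oa, ob, frac = compare_signatures(a, b)
        assert frac == 0.0 and oa == {"a"} and ob == {"b"}

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            compare_signatures(self._sig({"a": 1.0}), self._sig({"b": 1.0}))
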