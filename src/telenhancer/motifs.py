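"""TF-binding-motif signatures of enhancer classes.

Sequences are scanned with position weight matrices scored as log-odds
against a background base composition; a window is a hit when its score
reaches a fraction of the matrix's maximum attainable score (both strands,
overlapping hits all counted). Per-sequence hit counts (per kb) over the
motif panel form the feature matrix of a soft-margin linear SVM separating
enhancers from matched controls; the signed weight of each motif is its
association with the enhancer class. Per-motif enrichment folds compare
pooled hit rates between enhancers and controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

DEFAULT_THRESHOLD_FRACTION = 0.8
DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class Pwm:
    motif_id: str
    tf_name: str
    matrix: np.ndarray  # positions x 4 (A,C,G,T), counts or probabilities

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be positions x 4")
        if len(self.matrix) < 4:
            raise ValueError(f"{self.motif_id}: matrix shorter than 4 positions")
        if (self.matrix < 0).any():
            raise ValueError(f"{self.motif_id}: negative matrix entries")

    def __len__(self) -> int:
        return len(self.matrix)

    def probabilities(self, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
        m = self.matrix + pseudocount
        sums = m.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise ValueError(f"{self.motif_id}: zero column after pseudocount")
        return m / sums

    def log_odds(
        self,
        background: np.ndarray | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> np.ndarray:
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        bg = bg / bg.sum()
        return np.log2(self.probabilities(pseudocount) / bg)


def background_composition(sequences) -> np.ndarray:
    """Base composition of a pool of sequences (used as scanning background)."""
    counts = np.zeros(4)
    for seq in sequences:
        s = seq.upper()
        for b, i in _BASE_INDEX.items():
            counts[i] += s.count(b)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _window_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Score of every offset; windows containing non-ACGT bases get -inf."""
    m = len(lom)
    n = len(codes)
    if n < m:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, m)
    valid = (win >= 0).all(axis=1)
    scores = np.full(n - m + 1, -np.inf)
    if valid.any():
        w = win[valid]
        scores[valid] = lom[np.arange(m)[None, :], w].sum(axis=1)
    return scores


def scan_pwm(
    seq: str,
    pwm: Pwm,
    score_threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    background: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[tuple[int, str, float]]:
    """All (offset, strand, score) hits of a PWM on both strands.

    Offsets are 0-based positions of the window start on the forward
    strand; a ``-`` hit at offset p means the reverse complement of
    ``seq[p:p+len(pwm)]`` matches. A hit requires
    score >= ``score_threshold_fraction`` x the maximum attainable score.
    """
    if not 0 < score_threshold_fraction <= 1:
        raise ValueError("score_threshold_fraction must be in (0,1]")
    m = len(pwm)
    if len(seq) < m:
        raise ValueError(f"sequence shorter than motif {pwm.motif_id}")
    lom = pwm.log_odds(background, pseudocount)
    max_score = lom.max(axis=1).sum()
    cutoff = score_threshold_fraction * max_score
    codes = _encode(seq)
    hits: list[tuple[int, str, float]] = []
    fwd = _window_scores(codes, lom)
    for p in np.flatnonzero(fwd >= cutoff):
        hits.append((int(p), "+", float(fwd[p])))
    # reverse strand: score the reverse-complemented matrix on the forward seq
    lom_rc = lom[::-1, ::-1]
    rev = _window_scores(codes, lom_rc)
    for p in np.flatnonzero(rev >= cutoff):
        hits.append((int(p), "-", float(rev[p])))
    return sorted(hits)


@dataclass
class MotifFeatureMatrix:
    values: np.ndarray  # sequences x motifs, hits per kb
    seq_ids: list[str]
    motif_ids: list[str]
    labels: np.ndarray  # +1 enhancer, -1 control
    lengths_bp: np.ndarray

    def __post_init__(self) -> None:
        assert (self.values >= 0).all()
        assert set(np.unique(self.labels)) <= {-1, 1}


def build_feature_matrix(
    sequences: dict[str, str],
    labels: dict[str, int],
    pwms: list[Pwm],
    threshold: float = DEFAULT_THRESHOLD_FRACTION,
    background: np.ndarray | None = None,
    binary: bool = False,
) -> MotifFeatureMatrix:
    """Per-sequence, per-motif hit counts normalised to hits per kb.

    Rows and columns are canonically sorted (sequence id, motif id) so the
    matrix is invariant to input ordering. ``binary`` switches to 0/1
    presence features. The background defaults to the base composition of
    the control (label -1) sequences.
    """
    seq_ids = sorted(sequences)
    if len({labels[s] for s in seq_ids}) < 1:
        raise ValueError("need at least one labelled sequence")
    motif_order = sorted(pwms, key=lambda p: p.motif_id)
    if background is None:
        ctrl = [sequences[s] for s in seq_ids if labels[s] == -1]
        background = background_composition(ctrl) if ctrl else None
    values = np.zeros((len(seq_ids), len(motif_order)))
    lengths = np.array([len(sequences[s]) for s in seq_ids], dtype=float)
    for j, pwm in enumerate(motif_order):
        for i, sid in enumerate(seq_ids):
            n_hits = len(scan_pwm(sequences[sid], pwm, threshold, background))
            values[i, j] = (
                float(n_hits > 0) if binary else 1000.0 * n_hits / lengths[i]
            )
    return MotifFeatureMatrix(
        values=values,
        seq_ids=seq_ids,
        motif_ids=[p.motif_id for p in motif_order],
        labels=np.array([labels[s] for s in seq_ids]),
        lengths_bp=lengths,
    )


@dataclass
class SvmSignature:
    weights: dict[str, float]
    bias: float
    C: float
    training_accuracy: float
    motif_ids: list[str] = field(default_factory=list)

    def ranked_motifs(self) -> list[tuple[str, float]]:
        """Motifs by descending weight; ties broken by motif id."""
        return sorted(self.weights.items(), key=lambda kv: (-kv[1], kv[0]))

    def positive_motifs(self) -> set[str]:
        return {m for m, w in self.weights.items() if w > 0}


def fit_linear_svm(
    features: MotifFeatureMatrix,
    C: float | None = None,
    c_grid=DEFAULT_C_GRID,
    cv_folds: int = 5,
    seed: int = 0,
) -> SvmSignature:
    """Soft-margin linear SVM (min 1/2 w'w + C sum eps_i, hinge loss).

    With ``C=None`` the value is picked by stratified cross-validated
    accuracy over ``c_grid``. Raises on single-class input.
    """
    y = features.labels
    if len(set(y.tolist())) < 2:
        raise ValueError("SVM needs both classes present")
    X = features.values
    if C is None:
        folds = min(cv_folds, int(min((y == 1).sum(), (y == -1).sum())))
        best = (-np.inf, None)
        for c in c_grid:
            cv = StratifiedKFold(n_splits=max(2, folds), shuffle=True, random_state=seed)
            acc = cross_val_score(SVC(kernel="linear", C=c), X, y, cv=cv).mean()
            if acc > best[0]:
                best = (acc, c)
        C = best[1]
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    w = clf.coef_.ravel()
    # sklearn orders classes [-1, +1]; coef_ already points toward +1
    acc = float((clf.predict(X) == y).mean())
    return SvmSignature(
        weights=dict(zip(features.motif_ids, w.tolist())),
        bias=float(clf.intercept_[0]),
        C=float(C),
        training_accuracy=acc,
        motif_ids=list(features.motif_ids),
    )


@dataclass
class MotifEnrichment:
    motif_id: str
    fold: float
    enh_hits_per_kb: float
    ctrl_hits_per_kb: float
    p_value: float
    flagged: bool = False


def motif_enrichment(
    features: MotifFeatureMatrix, pseudocount: float = 0.5
) -> list[MotifEnrichment]:
    """Per-motif pooled hit-rate fold (enhancers / controls) with a
    binomial p on the pooled counts.

    The binomial compares the enhancer share of pooled hits with the
    enhancer share of scanned kb (two-sided). Motifs with zero hits in
    both groups are flagged with an undefined (NaN) fold.
    """
    pos = features.labels == 1
    neg = features.labels == -1
    enh_kb = features.lengths_bp[pos].sum() / 1000.0
    ctrl_kb = features.lengths_bp[neg].sum() / 1000.0
    if enh_kb == 0 or ctrl_kb == 0:
        raise ValueError("both labels must be present")
    counts = features.values * features.lengths_bp[:, None] / 1000.0
    out = []
    for j, mid in enumerate(features.motif_ids):
        k_enh = counts[pos, j].sum()
        k_ctrl = counts[neg, j].sum()
        total = k_enh + k_ctrl
        if total == 0:
            out.append(MotifEnrichment(mid, float("nan"), 0.0, 0.0, 1.0, flagged=True))
            continue
        fold = ((k_enh + pseudocount) / enh_kb) / ((k_ctrl + pseudocount) / ctrl_kb)
        p_share = enh_kb / (enh_kb + ctrl_kb)
        p = float(stats.binomtest(int(round(k_enh)), int(round(total)), p_share).pvalue)
        out.append(
            MotifEnrichment(mid, float(fold), k_enh / enh_kb, k_ctrl / ctrl_kb, p)
        )
    return out


def compare_signatures(
    sig_a: SvmSignature, sig_b: SvmSignature
) -> tuple[set[str], set[str], set[str], float]:
    """Shared and class-specific positive-weight motif sets.

    Returns (shared, only_a, only_b, shared_fraction) where the fraction is
    |shared| over |union of positives|.
    """
    if set(sig_a.weights) != set(sig_b.weights):
        raise ValueError("signatures cover different motif universes")
    pa, pb = sig_a.positive_motifs(), sig_b.positive_motifs()
    union = pa | pb
    shared = pa & pb
    frac = len(shared) / len(union) if union else float("nan")
    return shared, pa - pb, pb - pa, frac
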