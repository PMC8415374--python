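"""Gapped k-mer linear classifier of chromatin accessibility.

The classifier follows the gkmSVM contract used for in-silico mutagenesis:
features are gapped k-mers (all ``C(l, k)`` choices of ``k`` informative
positions inside an ``l``-bp window, ``l`` = 10 by default), canonicalized
with their reverse complements so that scores are exactly strand-symmetric,
and the trained model exposes a weight for every possible ``l``-mer.  The
score of a sequence is the sum of the weights of its ``l``-bp windows plus
an intercept, which makes the accessibility effect of substitutions
(deltaSVM) a sum of local window differences.

The estimator is scikit-learn compatible (``fit`` / ``predict`` /
``decision_function``) and accepts an array of DNA strings as ``X``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import normalize

from .genomic_io import gc_fraction, repeat_fraction
from .intervals import GenomicInterval, IntervalIndex

__all__ = [
    "encode_sequence",
    "decode_sequence",
    "reverse_complement",
    "GkmFeaturizer",
    "GappedKmerClassifier",
    "ExternalWeightModel",
    "TrainingSet",
    "sample_matched_negatives",
    "cross_validate",
    "cross_stage_matrix",
]

_BASE_TO_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_CODE[ord(_b)] = _i
    _BASE_TO_CODE[ord(_b.lower())] = _i
_CODE_TO_BASE = np.array(list("ACGTN"))

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode_sequence(seq: str) -> np.ndarray:
    """Encode DNA to int8 codes A=0, C=1, G=2, T=3, N/other=4."""
    return _BASE_TO_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(_CODE_TO_BASE[codes])


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GkmFeaturizer:
    """Canonical gapped k-mer featurization of ``l``-bp windows.

    A feature is (mask, letters): one of the ``C(l, k)`` masks of ``k``
    informative positions, together with the bases read at those positions.
    Each window emits every mask once.  Features are canonicalized as the
    minimum of the feature id and the id of its reverse-complement mirror
    in a fixed total order, so ``featurize(s) == featurize(revcomp(s))``.
    """

    def __init__(self, l: int = 10, k: int = 6):
        if l < 2:
            raise ValueError("word length l must be >= 2")
        if not (1 <= k <= l):
            raise ValueError("informative positions k must satisfy 1 <= k <= l")
        self.l = l
        self.k = k
        masks = list(combinations(range(l), k))
        self.n_masks = len(masks)
        self._mask_arr = np.array(masks, dtype=np.intp)  # (n_masks, k)
        self._pow4 = (4 ** np.arange(k)).astype(np.int64)
        mask_index = {m: i for i, m in enumerate(masks)}
        rc_index = np.array(
            [mask_index[tuple(sorted(l - 1 - p for p in m))] for m in masks],
            dtype=np.int64,
        )
        self._n_words = 4**k
        self._mask_offset = (np.arange(self.n_masks, dtype=np.int64) * self._n_words)
        self._rc_mask_offset = rc_index * self._n_words
        self.n_features = self.n_masks * self._n_words

    # -- core window machinery ------------------------------------------------

    def window_view(self, codes: np.ndarray) -> np.ndarray:
        if codes.shape[0] < self.l:
            raise ValueError(f"sequence shorter than word length {self.l}")
        return np.lib.stride_tricks.sliding_window_view(codes, self.l)

    def window_ids_from_matrix(self, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Canonical feature ids for an explicit ``(n_windows, l)`` matrix.

        Returns ``(ids, valid)`` where ``ids`` has shape
        ``(n_windows, n_masks)`` and ``valid`` marks windows free of
        non-ACGT codes (invalid windows are skipped in scoring/counting).
        """
        if W.shape[1] != self.l:
            raise ValueError(f"window matrix must have width {self.l}")
        W64 = np.ascontiguousarray(W, dtype=np.int64)
        valid = (W64 < 4).all(axis=1)
        n = W64.shape[0]
        ids = np.broadcast_to(self._mask_offset, (n, self.n_masks)).copy()
        rc_ids = np.broadcast_to(self._rc_mask_offset, (n, self.n_masks)).copy()
        # accumulate base-4 codes column by column (integer matmul has no
        # fast path, explicit gathers do)
        for j in range(self.k):
            ids += W64[:, self._mask_arr[:, j]] * int(self._pow4[j])
            rc_ids += (3 - W64[:, self._mask_arr[:, self.k - 1 - j]]) * int(
                self._pow4[j]
            )
        np.minimum(ids, rc_ids, out=ids)
        return ids, valid

    def window_ids(
        self, codes: np.ndarray, win_idx: Optional[np.ndarray] = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Canonical feature ids for each ``l``-bp window of a sequence."""
        W = self.window_view(codes)
        if win_idx is not None:
            W = W[win_idx]
        return self.window_ids_from_matrix(W)

    # -- featurization --------------------------------------------------------

    def feature_counts(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        """Canonical feature ids (sorted) and their counts for one sequence."""
        ids, valid = self.window_ids(encode_sequence(seq))
        flat = np.sort(ids[valid].ravel(), kind="stable")
        if len(flat) == 0:
            return flat, flat
        edges = np.flatnonzero(np.diff(flat)) + 1
        starts = np.concatenate(([0], edges))
        counts = np.diff(np.concatenate((starts, [len(flat)])))
        return flat[starts], counts

    def transform(self, sequences: Sequence[str]) -> sp.csr_matrix:
        """Sparse (n_sequences, n_features) canonical gapped k-mer counts."""
        indptr = [0]
        indices: list[np.ndarray] = []
        data: list[np.ndarray] = []
        for seq in sequences:
            ids, counts = self.feature_counts(seq)
            indices.append(ids)
            data.append(counts.astype(np.float64))
            indptr.append(indptr[-1] + len(ids))
        return sp.csr_matrix(
            (
                np.concatenate(data) if data else np.empty(0),
                np.concatenate(indices) if indices else np.empty(0, dtype=np.int64),
                np.array(indptr),
            ),
            shape=(len(sequences), self.n_features),
        )


class GappedKmerClassifier(ClassifierMixin, BaseEstimator):
    """L2-regularized linear classifier over canonical gapped k-mer counts.

    Parameters
    ----------
    l :
        Word (window) length in bp; features are drawn from ``l``-mers.
    k :
        Number of informative positions per word.
    C :
        Inverse regularization strength of the logistic loss.
    tol, max_iter :
        Optimizer controls (liblinear, deterministic).
    random_state :
        Seed recorded for scikit-learn compatibility; training itself is
        deterministic given the data.

    Notes
    -----
    Training uses per-sequence L2-normalized counts (length-robust, as in
    gapped k-mer kernel practice).  :meth:`sequence_score` and
    :meth:`weight` expose the unnormalized sum-of-window-weights score
    used by deltaSVM, which is linear and exactly strand-symmetric.
    """

    def __init__(
        self,
        l: int = 10,
        k: int = 6,
        C: float = 1.0,
        tol: float = 1e-6,
        max_iter: int = 5000,
        random_state: int = 0,
    ):
        self.l = l
        self.k = k
        self.C = C
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- fitting --------------------------------------------------------------

    def fit(self, X, y) -> "GappedKmerClassifier":
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training set must contain both classes")
        self.featurizer_ = GkmFeaturizer(self.l, self.k)
        if sp.issparse(X):
            if X.shape[1] != self.featurizer_.n_features:
                raise ValueError("precomputed matrix has the wrong feature count")
            M = X
        else:
            M = self.featurizer_.transform(list(X))
        Mn = normalize(M, norm="l2", copy=True)
        base = LogisticRegression(
            C=self.C,
            solver="liblinear",
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        base.fit(Mn, y)
        self._dense_table_ = None  # invalidate any cached word table
        self.classes_ = base.classes_
        self.coef_ = np.asarray(base.coef_).ravel().copy()
        self.intercept_ = float(base.intercept_[0])
        self.n_features_in_ = self.featurizer_.n_features
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise RuntimeError("classifier is not fitted")

    # -- classifier surface ----------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        """Decision scores on the trained (L2-normalized) feature scale."""
        self._check_fitted()
        M = X if sp.issparse(X) else self.featurizer_.transform(list(X))
        M = normalize(M, norm="l2")
        return np.asarray(M @ self.coef_) + self.intercept_

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return self.classes_[(d > 0).astype(int)]

    # -- deltaSVM scoring surface ---------------------------------------------

    def window_scores(
        self, codes: np.ndarray, win_idx: Optional[np.ndarray] = None
    ) -> np.ndarray:
        """Per-window sum of canonical feature weights (invalid windows 0)."""
        self._check_fitted()
        ids, valid = self.featurizer_.window_ids(codes, win_idx)
        return self._sum_window_weights(ids, valid)

    def window_scores_from_matrix(self, W: np.ndarray) -> np.ndarray:
        """Scores for an explicit ``(n_windows, l)`` code matrix."""
        self._check_fitted()
        ids, valid = self.featurizer_.window_ids_from_matrix(W)
        return self._sum_window_weights(ids, valid)

    def dense_word_table(self) -> np.ndarray:
        """Cached table of all ``4^l`` word scores, indexed by the base-4
        encoding ``sum(code[p] * 4**p)``.

        Built by broadcasting each mask's canonical feature weights over
        the non-informative positions; agrees with :meth:`weight` to
        float rounding (the summation order differs).  Used by the
        deltaSVM machinery, where it turns window scoring into one array
        lookup.
        """
        self._check_fitted()
        cached = getattr(self, "_dense_table_", None)
        if cached is not None:
            return cached
        l, k = self.l, self.k
        if 4**l > 64_000_000:
            raise ValueError(f"dense table for l={l} would be too large")
        f = self.featurizer_
        T = np.zeros((4,) * l)
        codes = np.arange(4**k, dtype=np.int64)
        digits = [(codes >> (2 * i)) & 3 for i in range(k)]
        rc_codes = sum((3 - digits[k - 1 - j]) << (2 * j) for j in range(k))
        for m_idx in range(f.n_masks):
            ids = f._mask_offset[m_idx] + codes
            rc_ids = f._rc_mask_offset[m_idx] + rc_codes
            v = self.coef_[np.minimum(ids, rc_ids)]
            shape = [1] * l
            for p in f._mask_arr[m_idx]:
                shape[l - 1 - p] = 4
            T += v.reshape(shape)
        self._dense_table_ = T.reshape(-1)
        return self._dense_table_

    def _sum_window_weights(
        self, ids: np.ndarray, valid: np.ndarray, exact: bool = False
    ) -> np.ndarray:
        # with exact=True the summands are sorted first, making the float
        # sum independent of mask order: a window and its reverse
        # complement then score identically, bit for bit (used by the
        # sequence_score / weight contract; the delta machinery uses the
        # fast unsorted path, where 1e-9 agreement suffices)
        vals = self.coef_[ids]
        if exact:
            vals.sort(axis=1)
        out = vals.sum(axis=1)
        out[~valid] = 0.0
        return out

    def sequence_score(self, seq: str) -> float:
        """Sum of window weights over the sequence, plus the intercept.

        This is the score whose between-homolog difference is deltaSVM:
        the intercept cancels and the difference decomposes into windows
        overlapping substituted positions.
        """
        if len(seq) < self.l:
            raise ValueError(f"sequence shorter than word length {self.l}")
        self._check_fitted()
        ids, valid = self.featurizer_.window_ids(encode_sequence(seq))
        scores = self._sum_window_weights(ids, valid, exact=True)
        scores.sort()  # order-independent summation for exact strand symmetry
        return float(scores.sum()) + self.intercept_

    def sequence_scores(self, X: Sequence[str]) -> np.ndarray:
        return np.array([self.sequence_score(s) for s in X])

    def weight(self, word: str) -> float:
        """Model weight of one ``l``-mer (sum of its canonical features)."""
        self._check_fitted()
        if len(word) != self.l:
            raise ValueError(f"weight() requires a word of length {self.l}")
        ids, valid = self.featurizer_.window_ids(encode_sequence(word))
        return float(self._sum_window_weights(ids, valid, exact=True)[0])

    # -- serialization ---------------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        self._check_fitted()
        with open(path, "w") as fh:
            fh.write("#enhevo-gkm-model\tv1\n")
            for key in ("l", "k", "C", "tol", "max_iter", "random_state"):
                fh.write(f"#{key}\t{getattr(self, key)!r}\n")
            fh.write(f"#intercept\t{float(self.intercept_)!r}\n")
            nz = np.nonzero(self.coef_)[0]
            for i in nz:
                fh.write(f"{i}\t{float(self.coef_[i])!r}\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "GappedKmerClassifier":
        params: dict[str, str] = {}
        entries: list[tuple[int, float]] = []
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#enhevo-gkm-model"):
                raise ValueError("not an enhevo gkm model file")
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].partition("\t")
                    params[key] = val
                elif line:
                    i, _, w = line.partition("\t")
                    entries.append((int(i), float(w)))
        model = cls(
            l=int(params["l"]),
            k=int(params["k"]),
            C=float(params["C"]),
            tol=float(params["tol"]),
            max_iter=int(params["max_iter"]),
            random_state=int(params["random_state"]),
        )
        model.featurizer_ = GkmFeaturizer(model.l, model.k)
        model.coef_ = np.zeros(model.featurizer_.n_features)
        for i, w in entries:
            model.coef_[i] = w
        model.intercept_ = float(params["intercept"])
        model.classes_ = np.array([0, 1])
        model.n_features_in_ = model.featurizer_.n_features
        return model


class ExternalWeightModel:
    """Scoring model backed by an externally produced all-``l``-mers table.

    Accepts the ``word TAB weight`` format emitted by scoring every
    possible ``l``-mer with a trained gapped k-mer model, and exposes the
    same deltaSVM scoring surface as :class:`GappedKmerClassifier`
    (``window_scores`` / ``sequence_score`` / ``weight``), so parity runs
    against external weights plug into the selection test unchanged.
    """

    def __init__(self, l: int, table: np.ndarray, intercept: float = 0.0):
        if table.shape != (4**l,):
            raise ValueError(f"expected a table of 4^{l} weights")
        self.l = l
        self._table = table
        self.intercept_ = intercept
        self._pow4 = (4 ** np.arange(l)).astype(np.int64)

    @classmethod
    def from_file(cls, path: Union[str, Path], l: int = 10) -> "ExternalWeightModel":
        table = np.zeros(4**l)
        seen = np.zeros(4**l, dtype=bool)
        pow4 = 4 ** np.arange(l)
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                word, _, w = line.partition("\t")
                if len(word) != l:
                    raise ValueError(f"word {word!r} does not have length {l}")
                idx = int(encode_sequence(word).astype(np.int64) @ pow4)
                table[idx] = float(w)
                seen[idx] = True
        if not seen.any():
            raise ValueError("empty weight table")
        return cls(l, table)

    def window_scores(
        self, codes: np.ndarray, win_idx: Optional[np.ndarray] = None
    ) -> np.ndarray:
        W = np.lib.stride_tricks.sliding_window_view(codes, self.l)
        if win_idx is not None:
            W = W[win_idx]
        valid = (W < 4).all(axis=1)
        idx = W.astype(np.int64) @ self._pow4
        out = np.where(valid, self._table[np.where(valid, idx, 0)], 0.0)
        return out

    def window_scores_from_matrix(self, W: np.ndarray) -> np.ndarray:
        valid = (W < 4).all(axis=1)
        idx = W.astype(np.int64) @ self._pow4
        return np.where(valid, self._table[np.where(valid, idx, 0)], 0.0)

    def dense_word_table(self) -> np.ndarray:
        return self._table

    def sequence_score(self, seq: str) -> float:
        if len(seq) < self.l:
            raise ValueError(f"sequence shorter than word length {self.l}")
        return float(self.window_scores(encode_sequence(seq)).sum()) + self.intercept_

    def weight(self, word: str) -> float:
        if len(word) != self.l:
            raise ValueError(f"weight() requires a word of length {self.l}")
        return float(self.window_scores(encode_sequence(word))[0])


# ---------------------------------------------------------------------------
# Matched negative sampling (genNullSeqs-style)

@dataclass
class TrainingSet:
    """Balanced positive/negative sequences with a per-pair matching report."""

    positives: list[str]
    negatives: list[str]
    report: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ValueError("positives and negatives must be balanced")
        for p, n in zip(self.positives, self.negatives):
            if len(p) != len(n):
                raise ValueError("per-pair lengths must match")


def sample_matched_negatives(
    positives: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    gc_tol: float = 0.02,
    repeat_tol: float = 0.1,
    seed: int = 0,
    max_tries: int = 10_000,
    max_widenings: int = 5,
) -> TrainingSet:
    """Sample one genome-background negative per positive.

    For each positive interval a window of identical length is drawn
    uniformly from the genome, rejecting draws that contain N, overlap any
    positive, or miss the positive's GC content (``gc_tol``) or repeat
    fraction (``repeat_tol``).  After ``max_tries`` rejections both
    tolerances are doubled (with a warning), up to ``max_widenings`` times.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    index = IntervalIndex(positives)

    pos_seqs: list[str] = []
    neg_seqs: list[str] = []
    rows = []
    for iv in positives:
        pseq = genome[iv.chrom][iv.start : iv.end]
        pgc, prep = gc_fraction(pseq), repeat_fraction(pseq)
        m = len(pseq)
        cur_gc_tol, cur_rep_tol = gc_tol, repeat_tol
        found = None
        for widening in range(max_widenings + 1):
            for _ in range(max_tries):
                ci = rng.choice(len(chroms), p=probs)
                chrom = chroms[ci]
                if len(genome[chrom]) < m:
                    continue
                start = int(rng.integers(0, len(genome[chrom]) - m + 1))
                cand = GenomicInterval(chrom, start, start + m)
                if index.overlapping(cand):
                    continue
                seq = genome[chrom][start : start + m]
                if "N" in seq.upper():
                    continue
                if abs(gc_fraction(seq) - pgc) > cur_gc_tol:
                    continue
                if abs(repeat_fraction(seq) - prep) > cur_rep_tol:
                    continue
                found = seq
                break
            if found is not None:
                break
            cur_gc_tol *= 2
            cur_rep_tol *= 2
            warnings.warn(
                f"negative sampling for {iv.id or iv.chrom}:{iv.start} widened "
                f"tolerances to gc={cur_gc_tol:.3g}, repeat={cur_rep_tol:.3g}"
            )
        if found is None:
            raise RuntimeError(
                f"could not sample a matched negative for {iv.id or iv.chrom}"
            )
        pos_seqs.append(pseq)
        neg_seqs.append(found)
        rows.append(
            {
                "enhancer_id": iv.id,
                "length": m,
                "gc_positive": pgc,
                "gc_negative": gc_fraction(found),
                "repeat_positive": prep,
                "repeat_negative": repeat_fraction(found),
            }
        )
    return TrainingSet(pos_seqs, neg_seqs, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Cross-validation and cross-stage evaluation

def cross_validate(
    positives: Sequence[str],
    negatives: Sequence[str],
    estimator: Optional[GappedKmerClassifier] = None,
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Stratified k-fold ROC evaluation, pooled over out-of-fold scores.

    Returns a dict with ``auc`` (rank-statistic AUC on pooled out-of-fold
    decision scores), ``fold_aucs``, the pooled ROC curve and raw scores.
    """
    if estimator is None:
        estimator = GappedKmerClassifier()
    X = list(positives) + list(negatives)
    y = np.array([1] * len(positives) + [0] * len(negatives))
    if min(len(positives), len(negatives)) < folds:
        raise ValueError("need at least `folds` sequences per class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    # featurize every sequence once; folds reuse the precomputed matrix
    M = GkmFeaturizer(estimator.l, estimator.k).transform(X)
    oof = np.zeros(len(X))
    fold_aucs = []
    for train_idx, test_idx in skf.split(np.zeros(len(X)), y):
        model = clone(estimator)
        model.fit(M[train_idx], y[train_idx])
        scores = model.decision_function(M[test_idx])
        oof[test_idx] = scores
        fold_aucs.append(roc_auc_score(y[test_idx], scores))
    fpr, tpr, _ = roc_curve(y, oof)
    return {
        "auc": float(roc_auc_score(y, oof)),
        "fold_aucs": [float(a) for a in fold_aucs],
        "fpr": fpr,
        "tpr": tpr,
        "scores": oof,
        "y": y,
    }


def cross_stage_matrix(
    models: Mapping[str, GappedKmerClassifier],
    test_sets: Mapping[str, tuple[Sequence[str], Sequence[str]]],
) -> pd.DataFrame:
    """AUC of every stage's model on every stage's positives vs negatives.

    Entry ``(i, j)`` is the AUC of the model trained on stage ``j`` when
    scoring the positives and negatives of stage ``i``.
    """
    stages = list(test_sets)
    out = pd.DataFrame(index=stages, columns=list(models), dtype=float)
    featurizer = next(iter(models.values())).featurizer_
    for test_stage, (pos, neg) in test_sets.items():
        X = featurizer.transform(list(pos) + list(neg))
        y = np.array([1] * len(pos) + [0] * len(neg))
        for model_stage, model in models.items():
            out.loc[test_stage, model_stage] = roc_auc_score(
                y, model.decision_function(X)
            )
    return out
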