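"""In-silico mutagenesis test for positive selection on enhancer accessibility.

Per enhancer: infer the ancestral sequence of the focal and sister species
by parsimony against an outgroup, call focal-branch substitutions, compute
the accessibility effect of those substitutions (deltaSVM: sum of window
weights of the focal sequence minus the ancestor), and compare it with an
empirical null built by re-introducing the same number of random
substitutions into the ancestor many times.  Mutation-bias controls:
transition/transversion-weighted or spectrum-matched null base sampling,
and exclusion of dinucleotide (adjacent) substitutions.

Empirical p-values use the ``(r + 1) / (N + 1)`` pseudo-count estimator,
which is never 0 and is super-uniform under the null.  Enhancers with
fewer than two applied substitutions are dropped from testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .conservation import fisher_exact
from .genomic_io import AlignedTriple
from .gkm import encode_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "AncestorCall",
    "infer_ancestor",
    "flag_dinucleotides",
    "SubstitutionSpectrum",
    "estimate_spectrum",
    "DeltaScorer",
    "delta_svm",
    "NullSummary",
    "null_distribution",
    "test_enhancers",
    "positive_proportion_by_group",
]

# alternatives of each base, ordered [transition, transversion, transversion]
_ALTS = np.array(
    [
        [2, 1, 3],  # A -> G | C, T
        [3, 0, 2],  # C -> T | A, G
        [0, 1, 3],  # G -> A | C, T
        [1, 0, 2],  # T -> C | A, G
    ],
    dtype=np.int8,
)
_TRANSITION_PARTNER = np.array([2, 3, 0, 1])


# ---------------------------------------------------------------------------
# Ancestor inference

@dataclass
class AncestorCall:
    """Inferred ancestor on focal coordinates plus focal-branch substitutions.

    ``excluded`` marks focal positions whose alignment column could not be
    used for substitution calling (gap/N in any record, or three distinct
    bases); those positions carry the focal base in the ancestor and are
    skipped when the null resamples substitution positions.
    """

    enhancer_id: str
    ancestor: str
    substitutions: list[tuple[int, str, str]]  # (position, ancestral, derived)
    dinucleotide_flags: list[bool]
    excluded: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        last = -1
        for pos, anc, der in self.substitutions:
            if pos <= last:
                raise ValueError("substitution positions must strictly increase")
            if anc == der:
                raise ValueError("ancestral and derived base must differ")
            if self.ancestor[pos] != anc:
                raise ValueError("ancestor string disagrees with substitution list")
            last = pos
        if len(self.dinucleotide_flags) != len(self.substitutions):
            raise ValueError("one dinucleotide flag per substitution required")

    @property
    def n_excluded(self) -> int:
        return int(self.excluded.sum())

    def focal_sequence(self) -> str:
        seq = list(self.ancestor)
        for pos, _anc, der in self.substitutions:
            seq[pos] = der
        return "".join(seq)


def infer_ancestor(triple: AlignedTriple) -> AncestorCall:
    """Parsimony ancestor of focal and sister using the outgroup.

    Per ungapped column: equal focal and sister bases are ancestral; where
    they differ, an outgroup matching the sister implies a focal-branch
    substitution, while an outgroup matching the focal implies the change
    happened on the sister branch.  Columns with three distinct bases, or
    any gap or N, are excluded from substitution calling (the focal base
    is kept so the ancestor stays on focal coordinates); focal-gap columns
    are dropped entirely.
    """
    f = encode_sequence(triple.focal)
    s = encode_sequence(triple.sister)
    o = encode_sequence(triple.outgroup)
    focal_chars = np.frombuffer(triple.focal.encode(), dtype=np.uint8)
    keep = focal_chars != ord("-")
    f, s, o = f[keep], s[keep], o[keep]
    sister_chars = np.frombuffer(triple.sister.encode(), dtype=np.uint8)[keep]
    outgroup_chars = np.frombuffer(triple.outgroup.encode(), dtype=np.uint8)[keep]
    gap_s = sister_chars == ord("-")
    gap_o = outgroup_chars == ord("-")

    clean = (f < 4) & (s < 4) & (o < 4) & ~gap_s & ~gap_o
    anc = f.copy()
    is_sub = np.zeros(len(f), dtype=bool)
    differs = clean & (f != s)
    focal_branch = differs & (o == s)
    sister_branch = differs & (o == f)
    unresolved = differs & ~(focal_branch | sister_branch)
    anc[focal_branch] = s[focal_branch]
    is_sub[focal_branch] = True
    excluded = ~clean | unresolved

    bases = "ACGTN"
    subs = [
        (int(p), bases[anc[p]], bases[f[p]]) for p in np.flatnonzero(is_sub)
    ]
    ancestor = "".join(bases[c] for c in anc)
    call = AncestorCall(
        triple.enhancer_id,
        ancestor,
        subs,
        [False] * len(subs),
        excluded,
    )
    return flag_dinucleotides(call)


def flag_dinucleotides(call: AncestorCall) -> AncestorCall:
    """Flag every substitution that has a neighbor at distance exactly 1."""
    positions = [p for p, _, _ in call.substitutions]
    flags = []
    for i, p in enumerate(positions):
        left = i > 0 and p - positions[i - 1] == 1
        right = i + 1 < len(positions) and positions[i + 1] - p == 1
        flags.append(left or right)
    call.dinucleotide_flags = flags
    return call


# ---------------------------------------------------------------------------
# Substitution spectrum

@dataclass
class SubstitutionSpectrum:
    """Pooled substitution rates split by CpG context.

    ``counts[ctx, i, j]`` is the number of i->j substitutions with the
    ancestral base in context ``ctx`` (0 = non-CpG, 1 = CpG); a position
    is CpG when its ancestral base participates in a CG dinucleotide in
    the ancestor, on either strand.  ``opportunities[ctx, i]`` counts
    ancestral bases, and a rate is count / opportunities (``nan`` when a
    base never occurs).  ``ts_tv_ratio`` is the per-opportunity transition
    rate over the per-opportunity transversion rate.
    """

    counts: np.ndarray  # (2, 4, 4)
    opportunities: np.ndarray  # (2, 4)

    @property
    def rates(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                self.opportunities[:, :, None] > 0,
                self.counts / np.maximum(self.opportunities[:, :, None], 1),
                np.nan,
            )

    @property
    def ts_tv_ratio(self) -> float:
        total = self.counts.sum(axis=0)  # (4, 4) pooled over context
        n_ts = sum(total[i, _TRANSITION_PARTNER[i]] for i in range(4))
        n_tv = total.sum() - n_ts
        if n_tv == 0:
            return np.nan
        # each base has 1 transition and 2 transversion alternatives
        return 2.0 * n_ts / n_tv

    def base_substitution_probs(self) -> np.ndarray:
        """(4, 3) alternative-base probabilities in ``_ALTS`` order."""
        total = self.counts.sum(axis=0)
        probs = np.full((4, 3), 1 / 3)
        for i in range(4):
            row = np.array([total[i, j] for j in _ALTS[i]], dtype=float)
            if row.sum() > 0:
                probs[i] = row / row.sum()
        return probs


def _cpg_mask(anc: np.ndarray) -> np.ndarray:
    mask = np.zeros(len(anc), dtype=bool)
    c_then_g = (anc[:-1] == 1) & (anc[1:] == 2)
    mask[:-1] |= c_then_g
    mask[1:] |= c_then_g
    return mask


def estimate_spectrum(calls: Iterable[AncestorCall]) -> SubstitutionSpectrum:
    """Pool substitution counts and base opportunities over all enhancers."""
    counts = np.zeros((2, 4, 4))
    opportunities = np.zeros((2, 4))
    any_call = False
    base_index = {b: i for i, b in enumerate("ACGT")}
    for call in calls:
        any_call = True
        anc = encode_sequence(call.ancestor)
        cpg = _cpg_mask(anc)
        usable = ~call.excluded & (anc < 4)
        for ctx in (0, 1):
            sel = usable & (cpg == bool(ctx))
            opportunities[ctx] += np.bincount(anc[sel], minlength=5)[:4]
        for pos, a, d in call.substitutions:
            ctx = int(cpg[pos])
            counts[ctx, base_index[a], base_index[d]] += 1
    if not any_call:
        raise ValueError("at least one ancestor call is required")
    return SubstitutionSpectrum(counts, opportunities)


def alternative_base_probs(
    base_sampling: str,
    spectrum: Optional[SubstitutionSpectrum] = None,
    ts_tv_ratio: float = 3.0,
) -> np.ndarray:
    """(4, 3) probabilities over each base's alternatives (in ``_ALTS`` order).

    ``uniform`` draws each alternative with probability 1/3;
    ``ts_tv_weighted`` weights the transition ``ts_tv_ratio`` : 1 : 1;
    ``spectrum`` uses the estimated substitution counts of the ancestral
    base.
    """
    if base_sampling == "uniform":
        return np.full((4, 3), 1 / 3)
    if base_sampling == "ts_tv_weighted":
        r = ts_tv_ratio
        return np.tile(np.array([r, 1.0, 1.0]) / (r + 2.0), (4, 1))
    if base_sampling == "spectrum":
        if spectrum is None:
            raise ValueError("spectrum sampling requires a SubstitutionSpectrum")
        return spectrum.base_substitution_probs()
    raise ValueError(f"unknown base_sampling {base_sampling!r}")


# ---------------------------------------------------------------------------
# deltaSVM and its empirical null

class DeltaScorer:
    """Fast deltaSVM machinery for one enhancer.

    Scoring runs on the model's dense per-word weight table: each
    ancestor window's base-4 index is precomputed, and a substitution at
    position ``p`` shifts the index of a window starting at ``w`` by
    ``(new - old) * 4**(p - w)``, so mutated windows are scored by pure
    digit arithmetic and one table lookup.  Null permutations whose
    substitutions are mutually farther apart than one window length (the
    common case) are additive over a precomputed single-substitution
    delta table; interacting draws get an exact per-cluster correction.
    Both paths agree exactly with full rescoring of the mutated sequence.
    """

    def __init__(self, model, call: AncestorCall, exclude_dinucleotides: bool = False):
        self.model = model
        self.call = call
        self.l = model.l
        self.exclude_dinucleotides = exclude_dinucleotides
        subs = call.substitutions
        if exclude_dinucleotides:
            subs = [
                s for s, flagged in zip(subs, call.dinucleotide_flags) if not flagged
            ]
        self.applied_substitutions = subs
        self.anc_codes = encode_sequence(call.ancestor)
        n = len(self.anc_codes)
        if n < self.l:
            raise ValueError("ancestor shorter than the model word length")
        self.n_windows = n - self.l + 1
        self._w = model.dense_word_table()
        self._pow4 = (4 ** np.arange(self.l)).astype(np.int64)
        clipped = np.minimum(self.anc_codes, 3).astype(np.int64)
        self._anc64 = clipped
        # windows containing N (code 4) are invalid and score 0 on both
        # sides of every delta; N positions are never substituted
        bad = np.concatenate(([0], np.cumsum(self.anc_codes >= 4)))
        self._win_valid = (bad[self.l :] - bad[: -self.l]) == 0
        idx = np.zeros(self.n_windows, dtype=np.int64)
        for p in range(self.l):
            idx += clipped[p : p + self.n_windows] * self._pow4[p]
        self._win_idx = idx
        self.anc_window_scores = np.where(self._win_valid, self._w[idx], 0.0)
        self._delta_table: Optional[np.ndarray] = None
        base_index = {b: i for i, b in enumerate("ACGTN")}
        self._sub_pos = np.array([p for p, _, _ in subs], dtype=np.int64)
        self._sub_alt = np.array([base_index[d] for _, _, d in subs], dtype=np.int64)

    # -- exact path -----------------------------------------------------------

    def delta_exact(self, positions: np.ndarray, alt_codes: np.ndarray) -> float:
        """deltaSVM of an arbitrary substitution set, by index arithmetic
        over the windows covering the substituted positions."""
        if len(positions) == 0:
            return 0.0
        positions = np.asarray(positions, dtype=np.int64)
        alt_codes = np.asarray(alt_codes, dtype=np.int64)
        chunks = [
            np.arange(max(0, p - self.l + 1), min(p, self.n_windows - 1) + 1)
            for p in positions
        ]
        affected = np.unique(np.concatenate(chunks))
        adjust = np.zeros(len(affected), dtype=np.int64)
        for p, c in zip(positions, alt_codes):
            lo = np.searchsorted(affected, max(0, p - self.l + 1))
            hi = np.searchsorted(affected, min(p, self.n_windows - 1), side="right")
            adjust[lo:hi] += (c - self._anc64[p]) * self._pow4[p - affected[lo:hi]]
        valid = self._win_valid[affected]
        new = np.where(valid, self._w[self._win_idx[affected] + adjust], 0.0)
        return float((new - self.anc_window_scores[affected]).sum())

    @property
    def n_applied(self) -> int:
        return len(self.applied_substitutions)

    @property
    def observed_delta(self) -> float:
        return self.delta_exact(self._sub_pos, self._sub_alt)

    # -- single-substitution delta table --------------------------------------

    def delta_table(self) -> np.ndarray:
        """(length, 4) table of single-substitution deltas; 0 at the
        ancestral base, ``nan`` at excluded or N positions."""
        if self._delta_table is not None:
            return self._delta_table
        n = len(self.anc_codes)
        table = np.full((n, 4), np.nan)
        usable = np.flatnonzero(~self.call.excluded & (self.anc_codes < 4))
        if len(usable):
            anc_at = self._anc64[usable]
            deltas = np.zeros((len(usable), 4))
            for off in range(self.l):
                w = usable - off
                m = (w >= 0) & (w < self.n_windows)
                wv = w[m]
                mm = self._win_valid[wv]
                wv = wv[mm]
                sel = np.flatnonzero(m)[mm]
                base = self._w[self._win_idx[wv]]
                step = self._pow4[off]
                for c in range(4):
                    shift = (c - anc_at[sel]) * step
                    deltas[sel, c] += self._w[self._win_idx[wv] + shift] - base
            table[usable] = deltas
            table[usable, anc_at] = 0.0
        self._delta_table = table
        return table

    # -- null sampling ---------------------------------------------------------

    def sample_null(
        self,
        n_permutations: int,
        base_sampling: str = "uniform",
        spectrum: Optional[SubstitutionSpectrum] = None,
        rng: Optional[np.random.Generator] = None,
        ts_tv_ratio: float = 3.0,
    ) -> np.ndarray:
        """Null deltaSVM sample: ``n_applied`` random substitutions per draw.

        Positions are drawn without replacement, uniformly over
        non-excluded ancestor positions; the alternative base is drawn
        uniformly, with transitions weighted ``ts_tv_ratio`` : 1 : 1, or
        from the estimated substitution spectrum row of the ancestral
        base.
        """
        if rng is None:
            rng = np.random.default_rng(0)
        n_sub = self.n_applied
        if n_sub < 1:
            raise ValueError("cannot build a null with zero substitutions")
        allowed = np.flatnonzero(~self.call.excluded & (self.anc_codes < 4))
        if len(allowed) < n_sub:
            raise ValueError("fewer usable positions than substitutions")

        cum = np.cumsum(
            alternative_base_probs(base_sampling, spectrum, ts_tv_ratio), axis=1
        )

        # distinct positions per permutation: n_sub smallest of random keys
        keys = rng.random((n_permutations, len(allowed)))
        if n_sub < len(allowed):
            sel = np.argpartition(keys, n_sub - 1, axis=1)[:, :n_sub]
        else:
            sel = np.tile(np.arange(len(allowed)), (n_permutations, 1))
        pos = allowed[sel]  # (n_permutations, n_sub)
        anc_b = self.anc_codes[pos].astype(np.int64)
        u = rng.random((n_permutations, n_sub))
        choice = (u[:, :, None] > cum[anc_b]).sum(axis=2).clip(max=2)
        alt = _ALTS[anc_b, choice]

        table = self.delta_table()
        deltas = table[pos, alt].sum(axis=1)
        pos_sorted = np.sort(pos, axis=1)
        additive = (
            (np.diff(pos_sorted, axis=1) >= self.l).all(axis=1)
            if n_sub > 1
            else np.ones(n_permutations, dtype=bool)
        )
        rows = np.flatnonzero(~additive)
        for i in rows:
            # exact correction per interacting cluster; isolated positions
            # keep their additive table contribution
            order = np.argsort(pos[i], kind="stable")
            ps, cs = pos[i][order], alt[i][order]
            boundaries = list(np.flatnonzero(np.diff(ps) >= self.l) + 1)
            start = 0
            for end in boundaries + [n_sub]:
                if end - start >= 2:
                    cp, ca = ps[start:end], cs[start:end]
                    deltas[i] += self.delta_exact(cp, ca) - table[cp, ca].sum()
                start = end
        return deltas


def delta_svm(model, call: AncestorCall, exclude_dinucleotides: bool = False) -> tuple[float, int]:
    """Observed deltaSVM and the number of applied substitutions.

    With zero applied substitutions the delta is exactly 0 (callers treat
    the count as a no-substitution flag).
    """
    scorer = DeltaScorer(model, call, exclude_dinucleotides)
    return scorer.observed_delta, scorer.n_applied


@dataclass
class NullSummary:
    """Observed deltaSVM against its empirical null."""

    enhancer_id: str
    observed: float
    n_substitutions: int
    n_permutations: int
    exceed_upper: int  # null >= observed
    exceed_lower: int  # null <= observed
    sample: Optional[np.ndarray] = field(default=None, repr=False)

    def p_value(self, tail: str = "upper") -> float:
        n = self.n_permutations
        p_up = (self.exceed_upper + 1) / (n + 1)
        p_lo = (self.exceed_lower + 1) / (n + 1)
        if tail == "upper":
            return p_up
        if tail == "lower":
            return p_lo
        if tail == "two_sided":
            return min(1.0, 2 * min(p_up, p_lo))
        raise ValueError(f"unknown tail {tail!r}")


def null_distribution(
    model,
    call: AncestorCall,
    n_permutations: int = 10_000,
    base_sampling: str = "uniform",
    spectrum: Optional[SubstitutionSpectrum] = None,
    seed: int = 0,
    exclude_dinucleotides: bool = False,
    keep_sample: bool = True,
    ts_tv_ratio: float = 3.0,
) -> NullSummary:
    """Empirical null of deltaSVM for one enhancer (see :class:`DeltaScorer`)."""
    scorer = DeltaScorer(model, call, exclude_dinucleotides)
    if scorer.n_applied < 1:
        raise ValueError("enhancer has no applied substitutions")
    rng = np.random.default_rng(seed)
    sample = scorer.sample_null(
        n_permutations, base_sampling, spectrum, rng, ts_tv_ratio
    )
    obs = scorer.observed_delta
    return NullSummary(
        call.enhancer_id,
        obs,
        scorer.n_applied,
        n_permutations,
        int((sample >= obs).sum()),
        int((sample <= obs).sum()),
        sample if keep_sample else None,
    )


# ---------------------------------------------------------------------------
# Per-stage testing

def test_enhancers(
    model,
    calls: Sequence[AncestorCall],
    n_permutations: int = 10_000,
    base_sampling: str = "uniform",
    spectrum: Optional[SubstitutionSpectrum] = None,
    min_substitutions: int = 2,
    tail: str = "upper",
    q_threshold: float = 0.05,
    exclude_dinucleotides: bool = False,
    seed: int = 0,
    ts_tv_ratio: float = 3.0,
) -> pd.DataFrame:
    """Selection test over a set of enhancers, with BH q-values.

    Enhancers with fewer than ``min_substitutions`` applied substitutions
    (counted after dinucleotide exclusion, when enabled) are dropped; the
    dropped count is logged and stored in ``result.attrs['n_dropped']``.
    ``positive_call`` is ``q_value < q_threshold``.
    """
    rows = []
    n_dropped = 0
    for call in calls:
        scorer = DeltaScorer(model, call, exclude_dinucleotides)
        if scorer.n_applied < min_substitutions:
            n_dropped += 1
            continue
        rng = substream(seed, f"null:{call.enhancer_id}")
        sample = scorer.sample_null(
            n_permutations, base_sampling, spectrum, rng, ts_tv_ratio
        )
        obs = scorer.observed_delta
        summary = NullSummary(
            call.enhancer_id, obs, scorer.n_applied, n_permutations,
            int((sample >= obs).sum()), int((sample <= obs).sum()),
        )
        rows.append(
            {
                "enhancer_id": call.enhancer_id,
                "n_substitutions": scorer.n_applied,
                "observed_delta": obs,
                "null_exceed_count": (
                    summary.exceed_upper if tail != "lower" else summary.exceed_lower
                ),
                "n_permutations": n_permutations,
                "p_value": summary.p_value(tail),
            }
        )
    logger.info(
        "selection test: %d enhancers tested, %d dropped below %d substitutions",
        len(rows), n_dropped, min_substitutions,
    )
    result = pd.DataFrame(
        rows,
        columns=[
            "enhancer_id", "n_substitutions", "observed_delta",
            "null_exceed_count", "n_permutations", "p_value",
        ],
    )
    if len(result):
        result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result["positive_call"] = result["q_value"] < q_threshold
    else:
        result["q_value"] = pd.Series(dtype=float)
        result["positive_call"] = pd.Series(dtype=bool)
    result.attrs["n_dropped"] = n_dropped
    result.attrs["tail"] = tail
    return result


test_enhancers.__test__ = False  # not a pytest test, despite the name


def positive_proportion_by_group(
    results: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    reference: Optional[str] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Proportion of positive calls per group, with Fisher tests vs a reference.

    ``groups`` maps enhancer_id to a group label; every tested enhancer
    must have a label.  Returns ``(proportions, fisher)``.
    """
    groups = pd.Series(dict(groups))
    missing = set(results["enhancer_id"]) - set(groups.index)
    if missing:
        raise ValueError(f"enhancers without a group label: {sorted(missing)[:5]}")
    df = results.assign(group=groups.loc[results["enhancer_id"]].values)
    prop_rows = []
    for g, sub in df.groupby("group", sort=True):
        n, k = len(sub), int(sub["positive_call"].sum())
        prop_rows.append(
            {"group": g, "n": n, "n_positive": k,
             "proportion": k / n if n else np.nan}
        )
    props = pd.DataFrame(prop_rows)
    fisher_rows = []
    if reference is not None and reference in set(props["group"]):
        ref = props.set_index("group").loc[reference]
        for _, row in props.iterrows():
            if row["group"] == reference:
                continue
            odds, p = fisher_exact(
                [
                    [int(ref["n_positive"]), int(ref["n"] - ref["n_positive"])],
                    [int(row["n_positive"]), int(row["n"] - row["n_positive"])],
                ]
            )
            fisher_rows.append(
                {"group": row["group"], "reference": reference,
                 "odds_ratio": odds, "fisher_p": p}
            )
    return props, pd.DataFrame(fisher_rows)
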