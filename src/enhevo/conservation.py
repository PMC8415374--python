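"""Cross-species, cross-stage enhancer conservation analysis.

Covers: the distal (enhancer) filter against annotated TSSs,
stage-specificity calling across the five time points, temporal
pleiotropy summaries, block-wise orthologous coordinate translation,
conserved-enhancer calling under the strict (>= 1 bp overlap) and relaxed
(< 1 kb distance) definitions, the per-stage Jaccard index, pairwise
Fisher exact comparisons of stage proportions, and the muscle/neuron
tissue-category split.

The overlap predicate everywhere is ">= 1 shared base" on half-open
intervals: touching intervals do not overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genomic_io import BlockMap
from .intervals import STAGES, GenomicInterval, IntervalIndex, gap_distance

__all__ = [
    "classify_distal",
    "StageSpecificCall",
    "call_stage_specific",
    "temporal_pleiotropy",
    "TranslationResult",
    "translate",
    "ConservationCall",
    "call_conserved",
    "conservation_summary",
    "jaccard_index",
    "fisher_exact",
    "compare_stage_proportions",
    "assign_tissue_categories",
]


# ---------------------------------------------------------------------------
# Distal-element (enhancer) definition

def classify_distal(
    peaks: Sequence[GenomicInterval],
    tss_annotation: Sequence[GenomicInterval],
    min_tss_distance: int = 500,
) -> list[GenomicInterval]:
    """Keep peaks strictly farther than ``min_tss_distance`` from every TSS.

    A TSS is treated as a point (1-bp interval); the distance from a peak
    to a TSS is 0 if the TSS lies inside the peak, otherwise the number of
    bases between them.  Peaks at exactly ``min_tss_distance`` are removed
    (strict inequality).  An empty TSS annotation keeps all peaks, with a
    warning.
    """
    if not tss_annotation:
        warnings.warn("empty TSS annotation: keeping all peaks as distal")
        return list(peaks)
    index = IntervalIndex(tss_annotation)
    out = []
    for peak in peaks:
        d = index.nearest_distance(peak)
        if d is None or d > min_tss_distance:
            out.append(peak)
    return out


# ---------------------------------------------------------------------------
# Stage specificity and temporal pleiotropy

@dataclass(frozen=True)
class StageSpecificCall:
    """Usage of one peak across the five stages."""

    enhancer: GenomicInterval
    specific_to: Optional[str]
    n_stages_active: int

    def __post_init__(self) -> None:
        if (self.specific_to is not None) != (self.n_stages_active == 1):
            raise ValueError("specific_to must be set exactly when active in 1 stage")


def _check_five_stages(peak_sets: Mapping[str, Sequence[GenomicInterval]]) -> None:
    missing = set(STAGES) - set(peak_sets)
    if missing:
        raise ValueError(f"peak sets missing stages {sorted(missing)}")


def call_stage_specific(
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
) -> dict[str, list[StageSpecificCall]]:
    """Per stage, classify each peak by how many stages it is used in.

    A peak is specific to its stage iff it overlaps (>= 1 bp) no peak of
    any other stage; ``n_stages_active`` is 1 plus the number of other
    stages with at least one overlapping peak.
    """
    _check_five_stages(peak_sets)
    indexes = {st: IntervalIndex(peak_sets[st]) for st in STAGES}
    out: dict[str, list[StageSpecificCall]] = {}
    for st in STAGES:
        calls = []
        for peak in peak_sets[st]:
            active = 1 + sum(
                1
                for other in STAGES
                if other != st and indexes[other].overlapping(peak)
            )
            calls.append(
                StageSpecificCall(
                    peak, specific_to=st if active == 1 else None,
                    n_stages_active=active,
                )
            )
        out[st] = calls
    return out


def stage_specific_enhancers(
    calls: Mapping[str, Sequence[StageSpecificCall]],
) -> dict[str, list[GenomicInterval]]:
    """Extract the stage-specific enhancers from usage calls."""
    return {
        st: [c.enhancer for c in calls[st] if c.specific_to == st] for st in calls
    }


def temporal_pleiotropy(
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage-usage histograms and adjacent-stage sharing fractions.

    Returns ``(usage, adjacent)``: ``usage`` has one row per stage with
    the fractions of its peaks used in 1..5 stages (rows sum to 1);
    ``adjacent`` covers TP2-TP4 with the fractions of peaks also used in
    both, exactly one, or neither adjacent stage.
    """
    _check_five_stages(peak_sets)
    calls = call_stage_specific(peak_sets)
    usage_rows = []
    for st in STAGES:
        n = len(calls[st])
        counts = np.zeros(5)
        for c in calls[st]:
            counts[c.n_stages_active - 1] += 1
        fracs = counts / n if n else counts
        usage_rows.append(
            {"stage": st, "n_peaks": n,
             **{f"used_in_{i + 1}": fracs[i] for i in range(5)}}
        )
    usage = pd.DataFrame(usage_rows)

    indexes = {st: IntervalIndex(peak_sets[st]) for st in STAGES}
    adj_rows = []
    for st in ("TP2", "TP3", "TP4"):
        prev_st = STAGES[STAGES.index(st) - 1]
        next_st = STAGES[STAGES.index(st) + 1]
        n = len(peak_sets[st])
        both = one = neither = 0
        for peak in peak_sets[st]:
            in_prev = bool(indexes[prev_st].overlapping(peak))
            in_next = bool(indexes[next_st].overlapping(peak))
            if in_prev and in_next:
                both += 1
            elif in_prev or in_next:
                one += 1
            else:
                neither += 1
        adj_rows.append(
            {
                "stage": st,
                "n_peaks": n,
                "both_adjacent": both / n if n else 0.0,
                "one_adjacent": one / n if n else 0.0,
                "neither_adjacent": neither / n if n else 0.0,
            }
        )
    return usage, pd.DataFrame(adj_rows)


# ---------------------------------------------------------------------------
# Orthologous coordinate translation

@dataclass(frozen=True)
class TranslationResult:
    """Projected image of an interval in the other species' coordinates."""

    interval: GenomicInterval
    mapped_bases: int


def translate(
    interval: GenomicInterval,
    block_map: BlockMap,
    require_unique: bool = True,
) -> Optional[TranslationResult]:
    """Project an interval through alignment blocks onto species B.

    Every aligned base of the interval is projected block-wise; the result
    spans from the first to the last mapped base on B and reports how many
    bases mapped.  Returns ``None`` when no base maps, or — under
    ``require_unique`` — when mapped bases land on more than one B
    chromosome or on both strands (not a one-to-one orthologous region).
    """
    pieces: list[tuple[str, int, int, str]] = []  # (chromB, startB, endB, strand)
    mapped = 0
    for blk in block_map.blocks:
        if blk.chrom_a != interval.chrom:
            continue
        lo = max(interval.start, blk.start_a)
        hi = min(interval.end, blk.end_a)
        if lo >= hi:
            continue
        mapped += hi - lo
        if blk.strand == "+":
            b_lo = blk.start_b + (lo - blk.start_a)
            b_hi = blk.start_b + (hi - blk.start_a)
        else:
            b_lo = blk.end_b - (hi - blk.start_a)
            b_hi = blk.end_b - (lo - blk.start_a)
        pieces.append((blk.chrom_b, b_lo, b_hi, blk.strand))
    if mapped == 0:
        return None
    chroms = {p[0] for p in pieces}
    strands = {p[3] for p in pieces}
    if require_unique and (len(chroms) > 1 or len(strands) > 1):
        return None
    chrom_b = pieces[0][0]
    span = GenomicInterval(
        chrom_b,
        min(p[1] for p in pieces),
        max(p[2] for p in pieces),
        strand=pieces[0][3] if len(strands) == 1 else ".",
        id=interval.id,
        stage=interval.stage,
    )
    return TranslationResult(span, mapped)


# ---------------------------------------------------------------------------
# Conserved-enhancer calling

@dataclass(frozen=True)
class ConservationCall:
    """Conservation status of one species-A stage-specific enhancer."""

    enhancer_id: str
    stage: Optional[str]
    partner_id: Optional[str]
    has_ortholog_region: bool
    conserved_overlap: bool
    conserved_1kb: bool

    def __post_init__(self) -> None:
        if self.conserved_overlap and not self.conserved_1kb:
            raise ValueError("overlap conservation implies within-1kb conservation")
        if (self.conserved_overlap or self.conserved_1kb) and not self.has_ortholog_region:
            raise ValueError("conservation requires an orthologous region")


def call_conserved(
    specific_a: Mapping[str, Sequence[GenomicInterval]],
    specific_b: Mapping[str, Sequence[GenomicInterval]],
    block_map: BlockMap,
    max_distance: int = 1000,
) -> dict[str, list[ConservationCall]]:
    """Call conservation of species-A stage-specific enhancers against B.

    For each stage, every A enhancer is translated through the block map;
    it is conserved under the strict definition when its image overlaps
    (>= 1 bp) a same-stage-specific B enhancer, and under the relaxed
    definition when the edge-to-edge distance to the nearest same-stage B
    enhancer is strictly below ``max_distance`` (overlap counts as 0).
    """
    out: dict[str, list[ConservationCall]] = {}
    for st in specific_a:
        b_index = IntervalIndex(specific_b.get(st, []))
        calls = []
        for enh in specific_a[st]:
            tr = translate(enh, block_map)
            if tr is None:
                calls.append(
                    ConservationCall(enh.id, st, None, False, False, False)
                )
                continue
            hits = b_index.overlapping(tr.interval)
            if hits:
                calls.append(
                    ConservationCall(enh.id, st, hits[0].id, True, True, True)
                )
                continue
            d = b_index.nearest_distance(tr.interval)
            within = d is not None and d < max_distance
            partner = None
            if within:
                partner = min(
                    (iv for iv in specific_b.get(st, [])
                     if iv.chrom == tr.interval.chrom),
                    key=lambda iv: gap_distance(tr.interval, iv),
                ).id
            calls.append(
                ConservationCall(enh.id, st, partner, True, False, within)
            )
        out[st] = calls
    return out


def jaccard_index(n_a: int, n_b: int, n_conserved: int) -> Optional[float]:
    """Jaccard index over one-to-one orthologous stage-specific enhancers.

    ``|conserved| / (|A| + |B| - |conserved|)``; ``None`` (undefined) when
    both sides are empty.
    """
    if n_conserved > min(n_a, n_b):
        raise ValueError("conserved count cannot exceed either side")
    union = n_a + n_b - n_conserved
    if union == 0:
        return None
    return n_conserved / union


def conservation_summary(
    specific_a: Mapping[str, Sequence[GenomicInterval]],
    specific_b: Mapping[str, Sequence[GenomicInterval]],
    calls: Mapping[str, Sequence[ConservationCall]],
    mode: str = "overlap",
) -> pd.DataFrame:
    """Per-stage conserved counts, proportions (A / B / pooled) and Jaccard."""
    if mode not in ("overlap", "within_1kb"):
        raise ValueError(f"unknown conservation mode {mode!r}")
    flag = "conserved_overlap" if mode == "overlap" else "conserved_1kb"
    rows = []
    for st in calls:
        n_a = len(specific_a[st])
        n_b = len(specific_b.get(st, []))
        n_orth = sum(c.has_ortholog_region for c in calls[st])
        n_cons = sum(getattr(c, flag) for c in calls[st])
        rows.append(
            {
                "stage": st,
                "mode": mode,
                "n_specific_A": n_a,
                "n_specific_B": n_b,
                "n_with_ortholog": n_orth,
                "n_conserved": n_cons,
                "proportion_A": n_cons / n_a if n_a else np.nan,
                "proportion_B": n_cons / n_b if n_b else np.nan,
                "proportion_pooled": 2 * n_cons / (n_a + n_b) if n_a + n_b else np.nan,
                "jaccard": jaccard_index(n_a, n_b, min(n_cons, n_b)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fisher exact test (exact integer enumeration)

def fisher_exact(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table of counts.

    Returns ``(odds_ratio, p)``.  The p-value sums, over all tables with
    the observed margins, the hypergeometric probabilities no larger than
    the observed one; arithmetic is exact-integer so ties are handled
    without floating-point epsilons.  The sample odds ratio is ``ad/bc``
    (``nan`` on a zero denominator).  A table with a zero margin carries
    no information: p = 1.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    odds = (a * d) / (b * c) if b * c > 0 else np.nan
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return odds, 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = comb(r1, a) * comb(r2, c1 - a)
    num = 0
    for x in range(lo, hi + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        if w <= obs:
            num += w
    return odds, num / comb(n, c1)


def compare_stage_proportions(
    counts: pd.DataFrame,
    reference: str = "TP3",
    k_col: str = "k",
    n_col: str = "n",
) -> pd.DataFrame:
    """Pairwise Fisher exact tests of each stage's proportion vs a reference.

    ``counts`` needs one row per stage with columns ``stage``, ``k_col``
    (successes) and ``n_col`` (totals).  Raw two-sided p-values are
    primary; Benjamini-Hochberg adjusted values are reported alongside.
    """
    counts = counts.set_index("stage")
    if reference not in counts.index:
        raise ValueError(f"reference stage {reference!r} not in counts")
    k_ref = int(counts.loc[reference, k_col])
    n_ref = int(counts.loc[reference, n_col])
    rows = []
    for st in counts.index:
        if st == reference:
            continue
        k, n = int(counts.loc[st, k_col]), int(counts.loc[st, n_col])
        odds, p = fisher_exact([[k_ref, n_ref - k_ref], [k, n - k]])
        rows.append(
            {"stage": st, "reference": reference, k_col: k, n_col: n,
             "odds_ratio": odds, "fisher_p": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fisher_q"] = multipletests(out["fisher_p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Tissue-category assignment

def assign_tissue_categories(
    enhancers: Sequence[GenomicInterval],
    tissue_sets: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Assign enhancers to tissue categories by >= 1 bp overlap.

    An enhancer overlapping exactly one tissue's set gets that label; one
    overlapping several is labelled ``ambiguous`` (and is meant to be
    excluded from category comparisons); the rest are ``remaining``.
    """
    indexes = {t: IntervalIndex(ivs) for t, ivs in tissue_sets.items()}
    rows = []
    for enh in enhancers:
        hits = [t for t, idx in indexes.items() if idx.overlapping(enh)]
        if len(hits) == 1:
            label = hits[0]
        elif len(hits) > 1:
            label = "ambiguous"
        else:
            label = "remaining"
        rows.append({"enhancer_id": enh.id, "category": label})
    return pd.DataFrame(rows)
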