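"""Genomic intervals and elementary interval arithmetic.

All coordinates in the package are 0-based half-open (BED convention).
An interval occupies bases ``start .. end-1``; two intervals overlap iff
they share at least one base, so touching intervals do not overlap.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "STAGES",
    "GenomicInterval",
    "IntervalIndex",
    "overlap_length",
    "gap_distance",
]

#: The five sampled embryonic time points, ordered along development.
STAGES = ("TP1", "TP2", "TP3", "TP4", "TP5")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded, 0-based half-open genomic interval.

    Parameters
    ----------
    chrom :
        Chromosome / contig name.
    start, end :
        0-based half-open coordinates, ``0 <= start < end``.
    strand :
        One of ``{'+', '-', '.'}``.
    id :
        Optional element identifier (e.g. enhancer id).
    stage :
        Optional developmental time point, one of :data:`STAGES`.
    species :
        Optional species label.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""
    stage: Optional[str] = None
    species: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.stage is not None and self.stage not in STAGES:
            raise ValueError(f"unknown stage label {self.stage!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def with_(self, **kwargs) -> "GenomicInterval":
        return replace(self, **kwargs)


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two intervals (0 if different chrom)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    """Edge-to-edge distance in bases; 0 when overlapping or touching.

    Returns ``None`` for intervals on different chromosomes.  The distance
    is the count of bases strictly between the two intervals.
    """
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


class IntervalIndex:
    """Sorted per-chromosome index answering overlap and nearest queries.

    Suitable for the peak-set sizes this pipeline handles (thousands of
    intervals); queries are binary-search based.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        self._starts: dict[str, list[int]] = {}
        self._max_end_prefix: dict[str, list[int]] = {}
        for chrom, ivs in self._by_chrom.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            self._starts[chrom] = [iv.start for iv in ivs]
            # running maximum of ends, so overlap queries can stop early
            run: list[int] = []
            m = 0
            for iv in ivs:
                m = max(m, iv.end)
                run.append(m)
            self._max_end_prefix[chrom] = run

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All indexed intervals sharing >= 1 base with ``query``."""
        ivs = self._by_chrom.get(query.chrom)
        if not ivs:
            return []
        starts = self._starts[query.chrom]
        hi = bisect_left(starts, query.end)  # intervals starting before query.end
        out = []
        for i in range(hi - 1, -1, -1):
            iv = ivs[i]
            if self._max_end_prefix[query.chrom][i] <= query.start:
                break
            if iv.end > query.start:
                out.append(iv)
        out.reverse()
        return out

    def nearest_distance(self, query: GenomicInterval) -> Optional[int]:
        """Distance to the nearest indexed interval on the same chromosome."""
        ivs = self._by_chrom.get(query.chrom)
        if not ivs:
            return None
        if self.overlapping(query):
            return 0
        starts = self._starts[query.chrom]
        best: Optional[int] = None
        pos = bisect_right(starts, query.end)
        # nearest to the right
        if pos < len(ivs):
            d = gap_distance(query, ivs[pos])
            best = d if best is None else min(best, d)
        if pos - 1 >= 0:
            d = gap_distance(query, ivs[pos - 1])
            best = d if best is None else min(best, d)
        # scan left for intervals that start earlier but may end nearer
        for i in range(pos - 2, -1, -1):
            d = gap_distance(query, ivs[i])
            if best is not None and ivs[i].start < query.start - best - 1 and (
                self._max_end_prefix[query.chrom][i] < query.start - best
            ):
                break
            best = d if best is None else min(best, d)
        return best

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())
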