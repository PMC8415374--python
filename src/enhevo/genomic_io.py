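"""Readers and writers for every on-disk format the pipeline touches.

Formats: FASTA (genomes, enhancer sequences, per-enhancer aligned triples),
BED3-BED6 (peaks, TSS), a block-map TSV describing cross-species alignment
blocks, SNP tables (per-enhancer counts or site records), and truth tables.

All coordinates are 0-based half-open internally and on disk.  Every
reader/writer pair is a lossless round trip on its accepted dialect, and
writers emit deterministic ordering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval

__all__ = [
    "read_fasta",
    "write_fasta",
    "repeat_fraction",
    "gc_fraction",
    "read_bed",
    "write_bed",
    "Block",
    "BlockMap",
    "read_block_map",
    "write_block_map",
    "AlignedTriple",
    "read_aligned_triple",
    "write_aligned_triple",
    "read_snp_table",
    "write_snp_table",
    "read_table",
    "write_table",
]

_VALID_CHARS = set("ACGTNacgtn")
_VALID_CHARS_GAPPED = _VALID_CHARS | {"-"}


# ---------------------------------------------------------------------------
# FASTA

def _validate_sequence(name: str, seq: str, allow_gaps: bool) -> None:
    allowed = _VALID_CHARS_GAPPED if allow_gaps else _VALID_CHARS
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(
                f"record {name!r}: invalid character {ch!r} at position {pos}"
            )


def read_fasta(path: Union[str, Path], allow_gaps: bool = False) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` mapping.

    Case is preserved (lowercase marks repeat-masked sequence).  Duplicate
    record names and characters outside ``ACGTNacgtn`` (plus ``-`` when
    ``allow_gaps``) are rejected.
    """
    path = Path(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"record {rec.id!r} is empty")
        if rec.id in out:
            raise ValueError(f"duplicate record name {rec.id!r}")
        _validate_sequence(rec.id, seq, allow_gaps)
        out[rec.id] = seq
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(path: Union[str, Path], records: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def repeat_fraction(seq: str) -> float:
    """Fraction of lowercase (repeat-masked) bases."""
    if not seq:
        raise ValueError("empty sequence")
    return sum(ch.islower() for ch in seq) / len(seq)


def gc_fraction(seq: str) -> float:
    """G+C fraction, case-insensitive; N bases count in the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


# ---------------------------------------------------------------------------
# BED

def read_bed(
    path: Union[str, Path],
    species: str = "",
    stage: Optional[str] = None,
) -> list[GenomicInterval]:
    """Read BED3-BED6 into :class:`GenomicInterval` rows, input order kept."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: fewer than 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate") from exc
            if start >= end or start < 0:
                raise ValueError(
                    f"line {lineno}: invalid interval {chrom}:{start}-{end}"
                )
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            out.append(
                GenomicInterval(
                    chrom, start, end, strand=strand, id=name,
                    stage=stage, species=species,
                )
            )
    return out


def write_bed(path: Union[str, Path], intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Block map (reduced PSL/chain: one aligned block per row)

@dataclass(frozen=True)
class Block:
    """One gapless alignment block between species A and species B."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start_a < self.end_a and 0 <= self.start_b < self.end_b):
            raise ValueError("block coordinates must satisfy 0 <= start < end")
        if (self.end_a - self.start_a) != (self.end_b - self.start_b):
            raise ValueError("paired block intervals must have equal length")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid block strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end_a - self.start_a


@dataclass
class BlockMap:
    """Ordered gapless alignment blocks mapping species A onto species B.

    Blocks must be non-overlapping and sorted in A coordinates within each
    A chromosome.  Unaligned A positions simply have no block.
    """

    blocks: list[Block] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev: dict[str, Block] = {}
        for blk in self.blocks:
            p = prev.get(blk.chrom_a)
            if p is not None:
                if blk.start_a < p.end_a:
                    raise ValueError(
                        "blocks overlap or are out of order in A coordinates: "
                        f"{p} then {blk}"
                    )
            prev[blk.chrom_a] = blk

    def __len__(self) -> int:
        return len(self.blocks)

    def inverted(self) -> "BlockMap":
        """The same alignment read in the B -> A direction ('+' blocks only)."""
        inv = []
        for blk in self.blocks:
            if blk.strand != "+":
                raise NotImplementedError("inversion implemented for '+' blocks")
            inv.append(
                Block(blk.chrom_b, blk.start_b, blk.end_b,
                      blk.chrom_a, blk.start_a, blk.end_a, "+")
            )
        inv.sort(key=lambda b: (b.chrom_a, b.start_a))
        return BlockMap(inv)


_BLOCK_COLUMNS = ("chromA", "startA", "endA", "chromB", "startB", "endB", "strand")


def read_block_map(path: Union[str, Path]) -> BlockMap:
    blocks: list[Block] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "chromA":  # tolerate an un-commented header
                continue
            if len(fields) != 7:
                raise ValueError(f"line {lineno}: expected 7 columns")
            try:
                blocks.append(
                    Block(fields[0], int(fields[1]), int(fields[2]),
                          fields[3], int(fields[4]), int(fields[5]), fields[6])
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return BlockMap(blocks)


def write_block_map(path: Union[str, Path], block_map: BlockMap) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_BLOCK_COLUMNS) + "\n")
        for b in block_map.blocks:
            fh.write(
                f"{b.chrom_a}\t{b.start_a}\t{b.end_a}\t"
                f"{b.chrom_b}\t{b.start_b}\t{b.end_b}\t{b.strand}\n"
            )


# ---------------------------------------------------------------------------
# Aligned triples (focal / sister / outgroup)

@dataclass(frozen=True)
class AlignedTriple:
    """Per-enhancer three-way alignment projected onto focal coordinates.

    Records are ordered focal, sister, outgroup and have equal length;
    ``-`` marks alignment gaps.
    """

    enhancer_id: str
    focal: str
    sister: str
    outgroup: str

    def __post_init__(self) -> None:
        n = len(self.focal)
        if not (len(self.sister) == len(self.outgroup) == n) or n == 0:
            raise ValueError(
                f"triple {self.enhancer_id!r}: records must be non-empty and "
                "of equal length"
            )

    def __len__(self) -> int:
        return len(self.focal)


def read_aligned_triple(path: Union[str, Path], enhancer_id: Optional[str] = None) -> AlignedTriple:
    records = read_fasta(path, allow_gaps=True)
    if len(records) != 3:
        raise ValueError(f"expected 3 aligned records, found {len(records)}")
    focal, sister, outgroup = records.values()
    if enhancer_id is None:
        enhancer_id = next(iter(records)).split("|")[0]
    if not (len(focal) == len(sister) == len(outgroup)):
        raise ValueError("aligned records have unequal lengths")
    return AlignedTriple(enhancer_id, focal, sister, outgroup)


def write_aligned_triple(path: Union[str, Path], triple: AlignedTriple) -> None:
    write_fasta(
        path,
        {
            f"{triple.enhancer_id}|focal": triple.focal,
            f"{triple.enhancer_id}|sister": triple.sister,
            f"{triple.enhancer_id}|outgroup": triple.outgroup,
        },
    )


# ---------------------------------------------------------------------------
# SNP tables and generic TSV tables

def read_snp_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a SNP table at either granularity.

    Per-enhancer counts: columns ``enhancer_id, n_snps``.
    Site records: columns ``chrom, pos, ref, alt`` (counted downstream).
    """
    df = pd.read_csv(path, sep="\t", comment=None)
    cols = list(df.columns)
    if {"enhancer_id", "n_snps"}.issubset(cols):
        if (df["n_snps"] < 0).any():
            raise ValueError("negative SNP counts")
        return df[["enhancer_id", "n_snps"]]
    if {"chrom", "pos", "ref", "alt"}.issubset(cols):
        return df[["chrom", "pos", "ref", "alt"]]
    raise ValueError(
        "SNP table must have columns (enhancer_id, n_snps) or (chrom, pos, ref, alt)"
    )


def write_snp_table(path: Union[str, Path], table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def count_snps_in(sites: pd.DataFrame, enhancers: Sequence[GenomicInterval]) -> pd.DataFrame:
    """Collapse site-level SNP records to per-enhancer counts."""
    rows = []
    for iv in enhancers:
        mask = (
            (sites["chrom"] == iv.chrom)
            & (sites["pos"] >= iv.start)
            & (sites["pos"] < iv.end)
        )
        rows.append({"enhancer_id": iv.id, "n_snps": int(mask.sum())})
    return pd.DataFrame(rows)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(path: Union[str, Path], df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
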