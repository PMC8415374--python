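"""Synthetic two-species, five-stage enhancer worlds with known ground truth.

The generator emulates every input of the analysis: two species' genomes,
per-stage DNase-like peak sets, a cross-species alignment block map with
insertions and unaligned gaps, a TSS annotation, per-enhancer three-way
alignments on a focal/sister/outgroup topology, and per-enhancer
polymorphism counts.  Enhancer accessibility is driven by planted PWM
motifs; the ground-truth accessibility scorer (sum of best PWM log-odds)
is deliberately distinct from the gapped k-mer model so that classifier
performance is a genuine generalization test.

Substitutions on each branch follow a fixed-count conditional process:
the count is drawn from a Poisson with mean branch-length x sites, then
placed at distinct positions with a transition/transversion rate ratio
``kappa``.  Under directional selection on the focal branch, proposed
substitutions are accepted with probability ``min(1, exp(+-s * dScore))``
where ``dScore`` is the change in true accessibility, so accepted changes
push accessibility consistently up (or down).  No indels occur inside
triples; the cross-species block map does contain indels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._rng import substream, substream_seed
from .genomic_io import (
    AlignedTriple,
    Block,
    BlockMap,
    write_aligned_triple,
    write_bed,
    write_block_map,
    write_fasta,
    write_table,
)
from .gkm import decode_sequence, encode_sequence
from .intervals import STAGES, GenomicInterval

__all__ = [
    "MotifSet",
    "make_motifs",
    "make_enhancer",
    "accessibility_score",
    "EvolutionParams",
    "TripleResult",
    "evolve_triple",
    "make_polymorphisms",
    "WorldConfig",
    "SyntheticWorld",
    "make_two_species_world",
]

_TRANSITION_PARTNER = np.array([2, 3, 0, 1])  # A<->G, C<->T


# ---------------------------------------------------------------------------
# Motifs and enhancer sequences

@dataclass(frozen=True)
class MotifSet:
    """Position weight matrices driving ground-truth accessibility."""

    pwms: tuple[np.ndarray, ...]  # each (4, width), columns sum to 1
    seed: int

    def __post_init__(self) -> None:
        for pwm in self.pwms:
            if pwm.shape[0] != 4 or pwm.shape[1] < 6:
                raise ValueError("each PWM must be 4 x width with width >= 6")
            if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-9):
                raise ValueError("PWM columns must sum to 1")
            if ((pwm < 0) | (pwm > 1)).any():
                raise ValueError("PWM probabilities must lie in [0, 1]")

    @property
    def width(self) -> int:
        return self.pwms[0].shape[1]

    def information_content(self) -> list[float]:
        """Mean per-column information content (bits) of each motif."""
        out = []
        for pwm in self.pwms:
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(pwm > 0, pwm * np.log2(pwm), 0.0)
            out.append(float(np.mean(2.0 + term.sum(axis=0))))
        return out


def _major_prob_for_ic(ic: float) -> float:
    """Major-base probability giving per-column IC ``ic`` (one-hot family)."""
    from scipy.optimize import brentq

    def f(x: float) -> float:
        rest = (1 - x) / 3
        val = 2.0 + x * np.log2(x)
        if rest > 0:
            val += (1 - x) * np.log2(rest)
        return val - ic

    hi = 1 - 1e-9
    if ic <= 0:
        return 0.25
    if f(hi) < 0:  # target at (or numerically above) the 2-bit ceiling
        return hi
    return float(brentq(f, 0.25 + 1e-12, hi, xtol=1e-12))


def make_motifs(n_motifs: int, width: int, ic_target: float, seed: int) -> MotifSet:
    """Generate ``n_motifs`` random PWMs with a target mean column IC.

    Each column concentrates probability on one random major base; the
    per-column IC is jittered by +-0.1 bits around ``ic_target`` so the
    mean stays well within 0.2 bits of the target.
    """
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    if width < 6:
        raise ValueError("motif width must be >= 6")
    if ic_target > 2.0:
        raise ValueError("ic_target above 2 bits per column is unattainable")
    if ic_target < 0:
        raise ValueError("ic_target must be nonnegative")
    rng = np.random.default_rng(seed)
    pwms = []
    for _ in range(n_motifs):
        pwm = np.empty((4, width))
        for j in range(width):
            ic_j = float(np.clip(ic_target + rng.uniform(-0.1, 0.1), 0.0, 1.99))
            x = _major_prob_for_ic(ic_j)
            major = int(rng.integers(4))
            col = np.full(4, (1 - x) / 3)
            col[major] = x
            pwm[:, j] = col / col.sum()
        pwms.append(pwm)
    return MotifSet(tuple(pwms), seed)


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.int8)


def make_enhancer(
    motifs: MotifSet,
    length: int,
    gc: float,
    n_sites: int,
    seed: int,
) -> tuple[str, list[tuple[int, int]]]:
    """An enhancer sequence: i.i.d. background with planted motif instances.

    Returns ``(sequence, sites)`` where ``sites`` lists
    ``(start, motif_index)`` for each planted, non-overlapping instance.
    """
    w = motifs.width
    if length < 10 * w:
        raise ValueError("length must be at least 10 x motif width")
    if not (0 < gc < 1):
        raise ValueError("gc must lie strictly between 0 and 1")
    if n_sites * w > length:
        raise ValueError("requested sites do not fit in the sequence")
    rng = np.random.default_rng(seed)
    codes = _random_background(rng, length, gc)
    sites: list[tuple[int, int]] = []
    starts: list[int] = []
    for s in range(n_sites):
        midx = int(rng.integers(len(motifs.pwms)))
        placed = False
        for _ in range(1000):
            start = int(rng.integers(0, length - w + 1))
            if all(abs(start - other) >= w for other in starts):
                placed = True
                break
        if not placed:  # deterministic fallback: leftmost free slot
            for start in range(0, length - w + 1):
                if all(abs(start - other) >= w for other in starts):
                    placed = True
                    break
        if not placed:
            raise RuntimeError("could not place non-overlapping motif sites")
        starts.append(start)
        pwm = motifs.pwms[midx]
        for j in range(w):
            codes[start + j] = rng.choice(4, p=pwm[:, j])
        sites.append((start, midx))
    return decode_sequence(codes), sorted(sites)


def accessibility_score(seq: Union[str, np.ndarray], motifs: MotifSet) -> float:
    """Ground-truth accessibility: summed positive-part PWM log-odds hits.

    Every window whose log-odds (against a uniform background) is positive
    contributes, for every motif, so each planted instance adds to the
    phenotype and damaging any instance lowers it.  This scorer defines
    the phenotype that directional selection acts on and is deliberately
    distinct from the gapped k-mer model used for inference.
    """
    codes = encode_sequence(seq) if isinstance(seq, str) else seq
    total = 0.0
    for pwm in motifs.pwms:
        w = pwm.shape[1]
        if len(codes) < w:
            raise ValueError("sequence shorter than motif width")
        lo = np.log2(np.maximum(pwm, 1e-9) / 0.25)
        W = np.lib.stride_tricks.sliding_window_view(codes, w)
        scores = lo[W, np.arange(w)].sum(axis=1)
        total += float(np.maximum(scores, 0.0).sum())
    return total


# ---------------------------------------------------------------------------
# Branch evolution

@dataclass(frozen=True)
class EvolutionParams:
    """Substitution process on the focal/sister/outgroup topology.

    ``branch_*`` are expected substitutions per site on each segment
    (the outgroup segment spans root-to-outgroup); ``kappa`` is the
    transition/transversion rate ratio; ``selection_mode`` applies
    directional selection of strength ``selection_strength`` to the
    focal branch only.
    """

    branch_focal: float = 0.02
    branch_sister: float = 0.02
    branch_outgroup: float = 0.06
    kappa: float = 3.0
    selection_mode: str = "neutral"
    selection_strength: float = 0.0
    dinucleotide_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("branch_focal", "branch_sister", "branch_outgroup"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.selection_mode not in ("neutral", "up", "down"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")
        if (self.selection_mode == "neutral") != (self.selection_strength == 0):
            raise ValueError(
                "selection_strength must be 0 exactly when selection_mode is neutral"
            )
        if not (0 <= self.dinucleotide_fraction <= 1):
            raise ValueError("dinucleotide_fraction must lie in [0, 1]")


@dataclass
class TripleResult:
    """An evolved triple plus its ground truth."""

    triple: AlignedTriple
    ancestral: str
    focal_substitutions: list[tuple[int, str, str]]


def _draw_alt_base(rng: np.random.Generator, base: int, kappa: float) -> int:
    ts = _TRANSITION_PARTNER[base]
    tvs = [b for b in range(4) if b != base and b != ts]
    p_ts = kappa / (kappa + 2)
    u = rng.random()
    if u < p_ts:
        return int(ts)
    return int(tvs[0] if u < p_ts + (1 - p_ts) / 2 else tvs[1])


def _neutral_branch(
    codes: np.ndarray, n_subs: int, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    out = codes.copy()
    if n_subs == 0:
        return out
    positions = rng.choice(len(codes), size=min(n_subs, len(codes)), replace=False)
    for pos in positions:
        out[pos] = _draw_alt_base(rng, int(out[pos]), kappa)
    return out


def evolve_triple(
    ancestral: str,
    params: EvolutionParams,
    true_scorer: Optional[Callable[[np.ndarray], float]] = None,
    enhancer_id: str = "enh",
) -> TripleResult:
    """Evolve focal, sister and outgroup sequences from a common ancestor.

    Substitution-only (sequence lengths are conserved).  The outgroup
    evolves on its own segment; focal and sister evolve independently from
    the ancestor.  ``true_scorer`` maps an int8 code array to the true
    accessibility and is required when ``selection_mode`` is not neutral.
    """
    if "-" in ancestral:
        raise ValueError("ancestral sequence must not contain gaps")
    codes = encode_sequence(ancestral)
    n = len(codes)
    rng = np.random.default_rng(params.seed)

    n_out = int(rng.poisson(params.branch_outgroup * n))
    n_sis = int(rng.poisson(params.branch_sister * n))
    n_foc = int(rng.poisson(params.branch_focal * n))

    outgroup = _neutral_branch(codes, n_out, params.kappa, rng)
    sister = _neutral_branch(codes, n_sis, params.kappa, rng)

    focal = codes.copy()
    used: set[int] = set()
    subs: list[tuple[int, str, str]] = []
    sign = {"neutral": 0.0, "up": 1.0, "down": -1.0}[params.selection_mode]
    if sign != 0 and true_scorer is None:
        raise ValueError("true_scorer is required under directional selection")
    current_score = true_scorer(focal) if true_scorer is not None and sign != 0 else 0.0

    n_placed = 0
    n_candidates = 24  # proposal pool per accepted substitution under selection
    while n_placed < min(n_foc, n):
        pair = (
            params.dinucleotide_fraction > 0
            and n_foc - n_placed >= 2
            and rng.random() < params.dinucleotide_fraction
        )
        proposals: list[tuple[list[int], list[int]]] = []
        for _attempt in range(50 * n_candidates):
            pos = int(rng.integers(n - 1 if pair else n))
            if pos in used or (pair and pos + 1 in used):
                continue
            targets = [pos, pos + 1] if pair else [pos]
            alts = [_draw_alt_base(rng, int(focal[t]), params.kappa) for t in targets]
            proposals.append((targets, alts))
            if sign == 0 or len(proposals) == n_candidates:
                break
        if not proposals:
            break
        if sign == 0:
            targets, alts = proposals[0]
        else:
            # acceptance proportional to exp(sign * s * dScore) over the pool
            deltas = []
            for targets, alts in proposals:
                trial = focal.copy()
                for t, a in zip(targets, alts):
                    trial[t] = a
                deltas.append(true_scorer(trial) - current_score)
            logw = sign * params.selection_strength * np.asarray(deltas)
            w = np.exp(logw - logw.max())
            idx = int(rng.choice(len(proposals), p=w / w.sum()))
            targets, alts = proposals[idx]
            current_score += deltas[idx]
        for t, a in zip(targets, alts):
            subs.append((t, decode_sequence(np.array([focal[t]])),
                         decode_sequence(np.array([a]))))
            focal[t] = a
            used.add(t)
        n_placed += len(targets)

    triple = AlignedTriple(
        enhancer_id,
        decode_sequence(focal),
        decode_sequence(sister),
        decode_sequence(outgroup),
    )
    return TripleResult(triple, ancestral, sorted(subs))


# ---------------------------------------------------------------------------
# Polymorphisms

def make_polymorphisms(
    lengths: Mapping[str, int],
    selected: Mapping[str, bool],
    theta: float = 0.01,
    sweep_factor: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-enhancer SNP counts with an optional selective-sweep deficit.

    Neutral enhancers draw ``Poisson(theta * length)`` segregating sites;
    enhancers under positive selection draw
    ``Poisson(theta * length * sweep_factor)``, emulating the diversity
    reduction left by a sweep.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if not (0 < sweep_factor <= 1):
        raise ValueError("sweep_factor must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for eid in lengths:
        length = lengths[eid]
        if length <= 0:
            raise ValueError(f"enhancer {eid!r} has non-positive length")
        mean = theta * length * (sweep_factor if selected.get(eid, False) else 1.0)
        rows.append({"enhancer_id": eid, "n_snps": int(rng.poisson(mean))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-world construction

def _per_stage(value, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = set(STAGES) - set(value)
        if missing:
            raise ValueError(f"{name} missing stages {sorted(missing)}")
        return {st: value[st] for st in STAGES}
    return {st: value for st in STAGES}


@dataclass
class WorldConfig:
    """Full simulation configuration; defaults encode the study conditions.

    Per-stage fields accept a scalar or a ``{stage: value}`` mapping.  The
    default conserved fractions peak at TP3 and the default true-selection
    fractions dip at TP3, mirroring the hourglass structure of the system
    being emulated, with nonconserved enhancers under more frequent
    positive selection than conserved ones.
    """

    n_enhancers: Union[int, Mapping[str, int]] = 40
    conserved_fraction: Union[float, Mapping[str, float]] = field(
        default_factory=lambda: {
            "TP1": 0.25, "TP2": 0.30, "TP3": 0.50, "TP4": 0.25, "TP5": 0.30,
        }
    )
    selected_fraction_conserved: Union[float, Mapping[str, float]] = field(
        default_factory=lambda: {
            "TP1": 0.15, "TP2": 0.15, "TP3": 0.0, "TP4": 0.15, "TP5": 0.15,
        }
    )
    selected_fraction_nonconserved: Union[float, Mapping[str, float]] = field(
        default_factory=lambda: {
            "TP1": 0.45, "TP2": 0.45, "TP3": 0.15, "TP4": 0.45, "TP5": 0.45,
        }
    )
    enhancer_length: int = 300
    spacer_pad: int = 550
    gc: float = 0.4
    n_motifs_per_stage: int = 3
    motif_width: int = 8
    motif_ic: float = 1.5
    n_sites: int = 4
    branch_focal: float = 0.03
    branch_sister: float = 0.03
    branch_outgroup: float = 0.09
    kappa: float = 3.0
    selection_strength: float = 5.0
    dinucleotide_fraction: float = 0.0
    theta: float = 0.01
    sweep_factor: float = 0.3
    n_shared_peaks: int = 10
    n_promoter_peaks: int = 5
    n_extra_b_enhancers: int = 0
    b_divergence: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for st, f in _per_stage(self.conserved_fraction, "conserved_fraction").items():
            if not (0 <= f <= 1):
                raise ValueError(f"conserved_fraction[{st}] = {f} outside [0, 1]")
        for name in ("selected_fraction_conserved", "selected_fraction_nonconserved"):
            for st, f in _per_stage(getattr(self, name), name).items():
                if not (0 <= f <= 1):
                    raise ValueError(f"{name}[{st}] = {f} outside [0, 1]")
        if self.enhancer_length < 10 * self.motif_width:
            raise ValueError("enhancer_length must be at least 10 x motif_width")
        if self.spacer_pad < 550:
            raise ValueError(
                "spacer_pad below 550 bp cannot guarantee >1 kb separation "
                "between neighboring enhancer images"
            )


@dataclass
class SyntheticWorld:
    """Ground-truth bundle: all pipeline inputs plus the labels behind them."""

    config: WorldConfig
    genomes: dict[str, dict[str, str]]
    peak_sets: dict[str, dict[str, list[GenomicInterval]]]
    tss: dict[str, list[GenomicInterval]]
    block_map: BlockMap
    triples: dict[str, AlignedTriple]
    true_ancestors: dict[str, str]
    true_substitutions: dict[str, list[tuple[int, str, str]]]
    snp_table: pd.DataFrame
    truth: pd.DataFrame
    motif_sets: dict[str, MotifSet]
    species_a: str = "speciesA"
    species_b: str = "speciesB"

    def write(self, outdir: Union[str, Path]) -> None:
        """Write every component in its on-disk format under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for species, genome in self.genomes.items():
            write_fasta(outdir / f"genome_{species}.fa", genome)
        for species, stages in self.peak_sets.items():
            for st, peaks in stages.items():
                write_bed(outdir / f"peaks_{species}_{st}.bed", peaks)
        for species, tss in self.tss.items():
            write_bed(outdir / f"tss_{species}.bed", tss)
        write_block_map(outdir / "block_map.tsv", self.block_map)
        triple_dir = outdir / "triples"
        triple_dir.mkdir(exist_ok=True)
        for eid, triple in self.triples.items():
            write_aligned_triple(triple_dir / f"{eid}.fa", triple)
        write_table(outdir / "snp_table.tsv", self.snp_table)
        write_table(outdir / "truth.tsv", self.truth)


def make_two_species_world(config: WorldConfig) -> SyntheticWorld:
    """Build a complete synthetic world from ``config``.

    Species A carries the focal enhancers (with triples and SNP counts);
    species B provides the distant comparison genome.  Conserved enhancers
    are embedded in aligned blocks whose images overlap a same-stage B
    peak; nonconserved ones either fall in unaligned gaps (no ortholog) or
    align to regions more than 1 kb from any same-stage B peak.  Spacer
    middles vary between aligned, deleted and inserted segments so that
    coordinate translation is nontrivial.
    """
    config.validate()
    seed = config.seed
    n_enh = {st: int(v) for st, v in _per_stage(config.n_enhancers, "n_enhancers").items()}
    cons_frac = _per_stage(config.conserved_fraction, "conserved_fraction")
    sel_c = _per_stage(config.selected_fraction_conserved, "selected_fraction_conserved")
    sel_n = _per_stage(
        config.selected_fraction_nonconserved, "selected_fraction_nonconserved"
    )

    layout_rng = substream(seed, "layout")
    bseq_rng = substream(seed, "b-sequence")

    motif_sets = {
        st: make_motifs(
            config.n_motifs_per_stage,
            config.motif_width,
            config.motif_ic,
            substream_seed(seed, f"motifs:{st}"),
        )
        for st in STAGES
    }

    chrom_a, chrom_b = "chrA", "chrB"
    parts_a: list[str] = []
    parts_b: list[str] = []
    blocks: list[Block] = []
    pos_a = pos_b = 0

    def emit_aligned(seg: str, divergence: float) -> tuple[int, int]:
        nonlocal pos_a, pos_b
        codes = encode_sequence(seg)
        n_mut = int(bseq_rng.poisson(divergence * len(codes)))
        mutated = _neutral_branch(codes, n_mut, config.kappa, bseq_rng)
        start_a, start_b = pos_a, pos_b
        parts_a.append(seg)
        parts_b.append(decode_sequence(mutated))
        blocks.append(
            Block(chrom_a, start_a, start_a + len(seg),
                  chrom_b, start_b, start_b + len(seg), "+")
        )
        pos_a += len(seg)
        pos_b += len(seg)
        return start_a, start_b

    def emit_a_only(seg: str) -> int:
        nonlocal pos_a
        start_a = pos_a
        parts_a.append(seg)
        pos_a += len(seg)
        return start_a

    def emit_b_only(seg: str) -> int:
        nonlocal pos_b
        start_b = pos_b
        parts_b.append(seg)
        pos_b += len(seg)
        return start_b

    def background(rng: np.random.Generator, length: int) -> str:
        return decode_sequence(_random_background(rng, length, config.gc))

    def emit_spacer() -> None:
        # [pad][variable middle][pad]: pads keep neighboring enhancer
        # images > 1 kb apart in B no matter what the middle does
        emit_aligned(background(layout_rng, config.spacer_pad), config.b_divergence)
        variant = int(layout_rng.integers(4))
        mid = background(layout_rng, int(layout_rng.integers(100, 200)))
        if variant == 0:  # aligned middle
            emit_aligned(mid, config.b_divergence)
        elif variant == 1:  # middle deleted in B
            emit_a_only(mid)
        elif variant == 2:  # middle deleted in B, plus a B insertion
            emit_a_only(mid)
            emit_b_only(background(layout_rng, int(layout_rng.integers(50, 250))))
        else:  # aligned middle split around a B insertion
            half = len(mid) // 2
            emit_aligned(mid[:half], config.b_divergence)
            emit_b_only(background(layout_rng, int(layout_rng.integers(50, 250))))
            emit_aligned(mid[half:], config.b_divergence)
        emit_aligned(background(layout_rng, config.spacer_pad), config.b_divergence)

    peaks_a: dict[str, list[GenomicInterval]] = {st: [] for st in STAGES}
    peaks_b: dict[str, list[GenomicInterval]] = {st: [] for st in STAGES}
    triples: dict[str, AlignedTriple] = {}
    true_ancestors: dict[str, str] = {}
    true_subs: dict[str, list[tuple[int, str, str]]] = {}
    truth_rows = []

    for st in STAGES:
        n = n_enh[st]
        n_cons = round(cons_frac[st] * n)
        n_sel_cons = round(sel_c[st] * n_cons)
        n_sel_non = round(sel_n[st] * (n - n_cons))
        for i in range(n):
            eid = f"{st}_enh{i:04d}"
            conserved = i < n_cons
            if conserved:
                selection = "up" if i < n_sel_cons else "neutral"
            else:
                selection = "up" if (i - n_cons) < n_sel_non else "neutral"
            motifs = motif_sets[st]
            ancestral, _sites = make_enhancer(
                motifs,
                config.enhancer_length,
                config.gc,
                config.n_sites,
                substream_seed(seed, f"enhancer:{eid}"),
            )
            params = EvolutionParams(
                branch_focal=config.branch_focal,
                branch_sister=config.branch_sister,
                branch_outgroup=config.branch_outgroup,
                kappa=config.kappa,
                selection_mode=selection,
                selection_strength=(
                    config.selection_strength if selection != "neutral" else 0.0
                ),
                dinucleotide_fraction=config.dinucleotide_fraction,
                seed=substream_seed(seed, f"evolution:{eid}"),
            )
            scorer = (lambda codes, m=motifs: accessibility_score(codes, m))
            result = evolve_triple(ancestral, params, scorer, enhancer_id=eid)

            emit_spacer()
            focal_seq = result.triple.focal
            has_ortholog = True
            if conserved:
                start_a, start_b = emit_aligned(focal_seq, config.b_divergence)
                peaks_b[st].append(
                    GenomicInterval(
                        chrom_b, start_b, start_b + len(focal_seq),
                        id=f"{eid}_B", stage=st, species="B",
                    )
                )
            elif i % 2 == 0:  # nonconserved, orthologous region exists
                start_a, _ = emit_aligned(focal_seq, config.b_divergence)
            else:  # nonconserved, no orthologous region
                start_a = emit_a_only(focal_seq)
                has_ortholog = False
            peaks_a[st].append(
                GenomicInterval(
                    chrom_a, start_a, start_a + len(focal_seq),
                    id=eid, stage=st, species="A",
                )
            )
            triples[eid] = result.triple
            true_ancestors[eid] = result.ancestral
            true_subs[eid] = result.focal_substitutions
            truth_rows.append(
                {
                    "enhancer_id": eid,
                    "stage": st,
                    "chrom": chrom_a,
                    "start": start_a,
                    "end": start_a + len(focal_seq),
                    "conserved": conserved,
                    "has_ortholog": has_ortholog,
                    "selection_mode": selection,
                    "n_true_substitutions": len(result.focal_substitutions),
                    "length": len(focal_seq),
                }
            )

    # peaks shared across several stages (pleiotropy, removed from the
    # stage-specific sets downstream)
    for j in range(config.n_shared_peaks):
        emit_spacer()
        seg = background(layout_rng, config.enhancer_length)
        start_a = emit_a_only(seg)
        n_stages = int(layout_rng.integers(2, 6))
        chosen = layout_rng.choice(len(STAGES), size=n_stages, replace=False)
        for si in sorted(chosen):
            st = STAGES[si]
            peaks_a[st].append(
                GenomicInterval(
                    chrom_a, start_a, start_a + len(seg),
                    id=f"shared{j:03d}_{st}", stage=st, species="A",
                )
            )

    # promoter-proximal peaks plus their TSS (removed by the distal filter)
    tss_a: list[GenomicInterval] = []
    for j in range(config.n_promoter_peaks):
        emit_spacer()
        seg = background(layout_rng, 200)
        start_a = emit_a_only(seg)
        t = start_a + 100
        tss_a.append(GenomicInterval(chrom_a, t, t + 1, id=f"tssA{j:03d}", species="A"))
        st = STAGES[j % len(STAGES)]
        peaks_a[st].append(
            GenomicInterval(
                chrom_a, start_a, start_a + len(seg),
                id=f"prom{j:03d}", stage=st, species="A",
            )
        )
    emit_spacer()

    # B-only tail: optional extra B peaks and B TSS, far from any image
    tss_b: list[GenomicInterval] = []
    for st in STAGES:
        for j in range(config.n_extra_b_enhancers):
            emit_b_only(background(bseq_rng, 1200))
            seg = background(bseq_rng, config.enhancer_length)
            start_b = emit_b_only(seg)
            peaks_b[st].append(
                GenomicInterval(
                    chrom_b, start_b, start_b + len(seg),
                    id=f"extraB_{st}_{j:03d}", stage=st, species="B",
                )
            )
    emit_b_only(background(bseq_rng, 800))
    t = pos_b
    emit_b_only(background(bseq_rng, 400))
    tss_b.append(GenomicInterval(chrom_b, t, t + 1, id="tssB000", species="B"))

    genome_a = "".join(parts_a)
    genome_b = "".join(parts_b)

    truth = pd.DataFrame(truth_rows)
    snp_table = make_polymorphisms(
        {r["enhancer_id"]: r["length"] for r in truth_rows},
        {r["enhancer_id"]: r["selection_mode"] != "neutral" for r in truth_rows},
        theta=config.theta,
        sweep_factor=config.sweep_factor,
        seed=substream_seed(seed, "polymorphisms"),
    )

    return SyntheticWorld(
        config=config,
        genomes={"speciesA": {chrom_a: genome_a}, "speciesB": {chrom_b: genome_b}},
        peak_sets={"speciesA": peaks_a, "speciesB": peaks_b},
        tss={"speciesA": tss_a, "speciesB": tss_b},
        block_map=BlockMap(blocks),
        triples=triples,
        true_ancestors=true_ancestors,
        true_substitutions=true_subs,
        snp_table=snp_table,
        truth=truth,
        motif_sets=motif_sets,
    )
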