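"""Stage specificity, translation, conserved calling and exact statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from enhevo.conservation import (
    assign_tissue_categories,
    call_conserved,
    call_stage_specific,
    classify_distal,
    compare_stage_proportions,
    conservation_summary,
    fisher_exact,
    jaccard_index,
    stage_specific_enhancers,
    temporal_pleiotropy,
    translate,
)
from enhevo.genomic_io import Block, BlockMap
from enhevo.intervals import STAGES, GenomicInterval
from enhevo.synthetic import WorldConfig, make_two_species_world

I = GenomicInterval


def _stage_sets(intervals_by_stage):
    return {st: intervals_by_stage.get(st, []) for st in STAGES}


class TestClassifyDistal:
    @pytest.mark.parametrize(
        "tss_pos, kept",
        [(1100, False), (1701, True), (1700, False), (499, False), (498, True)],
        ids=["inside", "gap-501", "gap-500-exactly", "left-gap-500", "left-gap-501"],
    )
    def test_strict_distance_boundary(self, tss_pos, kept):
        peak = I("chr2L", 1000, 1200)
        tss = [I("chr2L", tss_pos, tss_pos + 1)]
        result = classify_distal([peak], tss, 500)
        assert (len(result) == 1) == kept

    def test_empty_tss_keeps_all_with_warning(self):
        with pytest.warns(UserWarning, match="empty TSS"):
            result = classify_distal([I("chr", 0, 10)], [], 500)
        assert len(result) == 1


class TestStageSpecific:
    def test_peak_in_one_stage_only_is_specific(self):
        sets = _stage_sets({"TP3": [I("c", 100, 200, id="x")]})
        calls = call_stage_specific(sets)
        assert calls["TP3"][0].specific_to == "TP3"
        assert calls["TP3"][0].n_stages_active == 1

    def test_single_base_overlap_removes_specificity(self):
        sets = _stage_sets(
            {"TP3": [I("c", 100, 200)], "TP2": [I("c", 199, 300)]}
        )
        calls = call_stage_specific(sets)
        assert calls["TP3"][0].specific_to is None
        assert calls["TP3"][0].n_stages_active == 2

    def test_touching_intervals_do_not_overlap(self):
        sets = _stage_sets(
            {"TP3": [I("c", 100, 200)], "TP2": [I("c", 200, 300)]}
        )
        calls = call_stage_specific(sets)
        assert calls["TP3"][0].specific_to == "TP3"

    def test_synthetic_world_specificity_recovered_exactly(self):
        world = make_two_species_world(
            WorldConfig(n_enhancers=10, n_shared_peaks=6, n_promoter_peaks=0, seed=3)
        )
        calls = call_stage_specific(world.peak_sets["speciesA"])
        specific = stage_specific_enhancers(calls)
        truth_ids = {
            st: set(world.truth.loc[world.truth["stage"] == st, "enhancer_id"])
            for st in STAGES
        }
        for st in STAGES:
            assert {iv.id for iv in specific[st]} == truth_ids[st]


class TestTemporalPleiotropy:
    def test_identical_stages_all_used_in_five(self):
        peaks = [I("c", i * 1000, i * 1000 + 100) for i in range(5)]
        usage, adjacent = temporal_pleiotropy({st: list(peaks) for st in STAGES})
        assert (usage["used_in_5"] == 1.0).all()
        assert (adjacent["both_adjacent"] == 1.0).all()

    def test_disjoint_stages_all_used_in_one(self):
        sets = {
            st: [I("c", 10_000 * k, 10_000 * k + 100)]
            for k, st in enumerate(STAGES)
        }
        usage, adjacent = temporal_pleiotropy(sets)
        assert (usage["used_in_1"] == 1.0).all()
        assert (adjacent["neither_adjacent"] == 1.0).all()

    def test_matches_quadratic_oracle_on_random_world(self):
        rng = np.random.default_rng(5)
        sets = {
            st: [
                I("c", s, s + int(rng.integers(50, 200)))
                for s in sorted(rng.choice(20_000, size=30, replace=False))
            ]
            for st in STAGES
        }
        usage, _ = temporal_pleiotropy(sets)

        def overlaps(a, b):
            return max(a.start, b.start) < min(a.end, b.end)

        for st in STAGES:
            counts = np.zeros(5)
            for peak in sets[st]:
                active = 1 + sum(
                    any(overlaps(peak, q) for q in sets[other])
                    for other in STAGES
                    if other != st
                )
                counts[active - 1] += 1
            expected = counts / len(sets[st])
            row = usage.set_index("stage").loc[st]
            got = np.array([row[f"used_in_{i}"] for i in range(1, 6)])
            assert np.allclose(got, expected)


TWO_BLOCK_MAP = BlockMap(
    [
        Block("chrA", 0, 100, "chrB", 100, 200, "+"),
        # 50 bp insertion in B between the blocks
        Block("chrA", 100, 200, "chrB", 250, 350, "+"),
    ]
)


class TestTranslate:
    def test_single_block_offset(self):
        bm = BlockMap([Block("chrA", 0, 1000, "chrB", 100, 1100, "+")])
        tr = translate(I("chrA", 10, 20), bm)
        assert (tr.interval.start, tr.interval.end) == (110, 120)
        assert tr.mapped_bases == 10

    def test_unaligned_interval_returns_none(self):
        bm = BlockMap([Block("chrA", 0, 100, "chrB", 0, 100, "+")])
        assert translate(I("chrA", 500, 600), bm) is None

    def test_straddling_an_insertion_spans_the_gap(self):
        tr = translate(I("chrA", 90, 110), TWO_BLOCK_MAP)
        assert (tr.interval.start, tr.interval.end) == (190, 260)
        assert tr.mapped_bases == 20  # all bases map, but the span is longer

    def test_per_base_projection_oracle(self):
        # project every base by hand through the two-block map
        def project(pos):
            for blk in TWO_BLOCK_MAP.blocks:
                if blk.start_a <= pos < blk.end_a:
                    return blk.start_b + (pos - blk.start_a)
            return None

        rng = np.random.default_rng(0)
        for _ in range(50):
            start = int(rng.integers(0, 250))
            end = start + int(rng.integers(1, 80))
            images = [project(p) for p in range(start, end)]
            mapped = [b for b in images if b is not None]
            tr = translate(I("chrA", start, end), TWO_BLOCK_MAP)
            if not mapped:
                assert tr is None
            else:
                assert tr.mapped_bases == len(mapped)
                assert tr.interval.start == min(mapped)
                assert tr.interval.end == max(mapped) + 1

    def test_multi_chromosome_image_fails_uniqueness(self):
        bm = BlockMap(
            [
                Block("chrA", 0, 50, "chrB", 0, 50, "+"),
                Block("chrA", 50, 100, "chrC", 0, 50, "+"),
            ]
        )
        assert translate(I("chrA", 0, 100), bm) is None
        tr = translate(I("chrA", 0, 100), bm, require_unique=False)
        assert tr is not None and tr.mapped_bases == 100

    def test_minus_strand_block(self):
        bm = BlockMap([Block("chrA", 0, 100, "chrB", 0, 100, "-")])
        tr = translate(I("chrA", 0, 10), bm)
        assert (tr.interval.start, tr.interval.end) == (90, 100)

    def test_round_trip_through_inverted_map_contains_mapped_bases(self):
        tr = translate(I("chrA", 40, 160), TWO_BLOCK_MAP)
        back = translate(tr.interval, TWO_BLOCK_MAP.inverted())
        assert back is not None
        assert back.interval.start <= 40 and back.interval.end >= 160


class TestCallConserved:
    def _maps(self):
        bm = BlockMap([Block("chrA", 0, 10_000, "chrB", 0, 10_000, "+")])
        a = _stage_sets({"TP3": [I("chrA", 1000, 1300, id="a1", stage="TP3")]})
        return bm, a

    def test_exact_image_conserved_in_both_modes(self):
        bm, a = self._maps()
        b = _stage_sets({"TP3": [I("chrB", 1000, 1300, id="b1", stage="TP3")]})
        calls = call_conserved(a, b, bm)["TP3"]
        assert calls[0].conserved_overlap and calls[0].conserved_1kb
        assert calls[0].partner_id == "b1"

    @pytest.mark.parametrize(
        "b_start, overlap, within",
        [(1300, False, True), (2299, False, True), (2300, False, False),
         (1299, True, True)],
        ids=["touching", "gap-999", "gap-1000", "one-bp-overlap"],
    )
    def test_distance_boundaries(self, b_start, overlap, within):
        bm, a = self._maps()
        b = _stage_sets(
            {"TP3": [I("chrB", b_start, b_start + 300, id="b1", stage="TP3")]}
        )
        calls = call_conserved(a, b, bm)["TP3"]
        assert calls[0].conserved_overlap == overlap
        assert calls[0].conserved_1kb == within

    def test_no_ortholog_region(self):
        bm = BlockMap([Block("chrA", 5000, 6000, "chrB", 0, 1000, "+")])
        a = _stage_sets({"TP3": [I("chrA", 1000, 1300, id="a1", stage="TP3")]})
        calls = call_conserved(a, _stage_sets({}), bm)["TP3"]
        assert not calls[0].has_ortholog_region

    def test_overlap_mode_subset_of_within_1kb(self):
        world = make_two_species_world(WorldConfig(n_enhancers=20, seed=9))
        calls_a = call_stage_specific(world.peak_sets["speciesA"])
        calls_b = call_stage_specific(world.peak_sets["speciesB"])
        calls = call_conserved(
            stage_specific_enhancers(calls_a),
            stage_specific_enhancers(calls_b),
            world.block_map,
        )
        for st in STAGES:
            for c in calls[st]:
                assert not (c.conserved_overlap and not c.conserved_1kb)

    def test_configured_conserved_fraction_recovered(self):
        config = WorldConfig(n_enhancers=60, n_shared_peaks=0,
                             n_promoter_peaks=0, seed=21)
        world = make_two_species_world(config)
        specific_a = stage_specific_enhancers(
            call_stage_specific(world.peak_sets["speciesA"])
        )
        specific_b = stage_specific_enhancers(
            call_stage_specific(world.peak_sets["speciesB"])
        )
        calls = call_conserved(specific_a, specific_b, world.block_map)
        summary = conservation_summary(specific_a, specific_b, calls, "overlap")
        for _, row in summary.iterrows():
            frac = config.conserved_fraction[row["stage"]]
            # construction is deterministic: counts match the config exactly
            assert row["n_conserved"] == round(frac * 60)


class TestJaccard:
    def test_worked_example(self):
        assert jaccard_index(6, 8, 4) == pytest.approx(0.4)

    def test_bounds(self):
        assert jaccard_index(5, 5, 5) == 1.0
        assert jaccard_index(5, 8, 0) == 0.0
        assert jaccard_index(0, 0, 0) is None

    def test_symmetry(self):
        assert jaccard_index(6, 8, 4) == jaccard_index(8, 6, 4)


def _enumeration_fisher(table):
    """Independent oracle: exact two-sided p by full enumeration."""
    from fractions import Fraction
    from math import comb

    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    obs = comb(r1, a) * comb(r2, c1 - a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        if w <= obs:
            total += Fraction(w, comb(n, c1))
    return float(total)


class TestFisherExact:
    def test_balanced_table_p_one(self):
        odds, p = fisher_exact([[5, 5], [5, 5]])
        assert p == 1.0 and odds == 1.0

    def test_perfect_association(self):
        _, p = fisher_exact([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / 184756, rel=1e-12)

    def test_matches_enumeration_oracle_on_all_small_tables(self):
        for n in range(1, 41, 3):
            for a in range(0, n + 1, 3):
                for b in range(0, n - a + 1, 4):
                    for c in range(0, n - a - b + 1, 4):
                        d = n - a - b - c
                        table = [[a, b], [c, d]]
                        _, p = fisher_exact(table)
                        assert p == pytest.approx(
                            _enumeration_fisher(table), abs=1e-12
                        )

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            table = rng.integers(0, 60, size=(2, 2))
            _, p = fisher_exact(table.tolist())
            assert p == pytest.approx(
                sps.fisher_exact(table)[1], rel=1e-7, abs=1e-12
            )

    def test_transposition_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t = rng.integers(0, 40, size=(2, 2))
            assert fisher_exact(t.tolist())[1] == pytest.approx(
                fisher_exact(t.T.tolist())[1], abs=1e-12
            )

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact([[0, 0], [3, 5]])[1] == 1.0


class TestCompareStageProportions:
    def test_reference_comparisons(self):
        counts = pd.DataFrame(
            {"stage": list(STAGES), "k": [5, 6, 20, 4, 7], "n": [40] * 5}
        )
        out = compare_stage_proportions(counts, reference="TP3")
        assert set(out["stage"]) == {"TP1", "TP2", "TP4", "TP5"}
        row = out.set_index("stage").loc["TP1"]
        assert row["fisher_p"] == pytest.approx(
            _enumeration_fisher([[20, 20], [5, 35]]), abs=1e-12
        )
        assert "fisher_q" in out.columns


class TestTissueCategories:
    def test_assignment_rules(self):
        muscle = [I("c", 100, 200)]
        neuron = [I("c", 400, 500)]
        enhancers = [
            I("c", 150, 250, id="in_muscle"),
            I("c", 199, 205, id="one_bp_less"),  # overlaps muscle by 1 bp
            I("c", 300, 350, id="nowhere"),
            I("c", 150, 450, id="both"),
        ]
        out = assign_tissue_categories(
            enhancers, {"muscle": muscle, "neuron": neuron}
        ).set_index("enhancer_id")["category"]
        assert out["in_muscle"] == "muscle"
        assert out["one_bp_less"] == "muscle"
        assert out["nowhere"] == "remaining"
        assert out["both"] == "ambiguous"
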