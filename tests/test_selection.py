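"""Ancestor inference, deltaSVM, empirical null and the selection test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from enhevo.genomic_io import AlignedTriple
from enhevo.gkm import ExternalWeightModel, GappedKmerClassifier
from enhevo.selection import (
    AncestorCall,
    DeltaScorer,
    alternative_base_probs,
    delta_svm,
    estimate_spectrum,
    flag_dinucleotides,
    infer_ancestor,
    null_distribution,
    positive_proportion_by_group,
    test_enhancers,
)
from enhevo.synthetic import EvolutionParams, evolve_triple, make_enhancer

from conftest import random_sequence

PAD = "ACGTACGT"  # shared context so single-column behavior is isolated


def _triple_for_column(f, s, o):
    return AlignedTriple("t", PAD + f + PAD, PAD + s + PAD, PAD + o + PAD)


class TestInferAncestor:
    def test_all_ungapped_columns_follow_parsimony(self):
        for f, s, o in itertools.product("ACGT", repeat=3):
            call = infer_ancestor(_triple_for_column(f, s, o))
            anc, sub = call.ancestor[len(PAD)], [
                x for x in call.substitutions if x[0] == len(PAD)
            ]
            if f == s:
                assert anc == f and not sub
                assert not call.excluded[len(PAD)]
            elif o == s:  # focal-branch substitution
                assert anc == s
                assert sub == [(len(PAD), s, f)]
            elif o == f:  # sister-branch change, focal kept ancestral
                assert anc == f and not sub
                assert not call.excluded[len(PAD)]
            else:  # three distinct bases: excluded from calling
                assert anc == f and not sub
                assert call.excluded[len(PAD)]

    @pytest.mark.parametrize("col", [("G", "-", "A"), ("G", "A", "-"),
                                     ("G", "N", "A"), ("N", "A", "A")])
    def test_gap_or_n_columns_are_excluded(self, col):
        call = infer_ancestor(_triple_for_column(*col))
        assert call.excluded[len(PAD)]
        assert not any(p == len(PAD) for p, _, _ in call.substitutions)

    def test_focal_gap_columns_are_dropped_from_coordinates(self):
        triple = AlignedTriple("t", PAD + "-" + PAD, PAD + "A" + PAD, PAD + "A" + PAD)
        call = infer_ancestor(triple)
        assert len(call.ancestor) == 2 * len(PAD)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            AlignedTriple("t", "ACGT", "ACGTA", "ACGT")

    def test_recovers_true_ancestor_and_substitutions_at_low_divergence(self):
        rng = np.random.default_rng(8)
        agree = total = 0
        for rep in range(20):
            anc = random_sequence(rng, 500)
            res = evolve_triple(anc, EvolutionParams(seed=rep))
            call = infer_ancestor(res.triple)
            agree += sum(a == b for a, b in zip(call.ancestor, anc))
            total += len(anc)
        assert agree / total > 0.99


class TestFlagDinucleotides:
    def _call(self, positions):
        anc = "A" * 30
        subs = [(p, "A", "G") for p in positions]
        call = AncestorCall("t", anc, subs, [False] * len(subs),
                            np.zeros(30, dtype=bool))
        return flag_dinucleotides(call)

    def test_adjacent_pair_both_flagged(self):
        assert self._call([10, 11]).dinucleotide_flags == [True, True]

    def test_gap_of_two_not_flagged(self):
        assert self._call([10, 12]).dinucleotide_flags == [False, False]

    def test_chain_of_three_all_flagged(self):
        assert self._call([10, 11, 12]).dinucleotide_flags == [True, True, True]


class TestSpectrum:
    def test_rate_is_count_over_ancestral_base_count(self):
        # ancestor has 10 C (non-CpG: no CG dinucleotide) and 10 A
        anc = "CA" * 10
        subs = [(0, "C", "T"), (2, "C", "T")]
        call = AncestorCall("t", anc, subs, [False, False],
                            np.zeros(20, dtype=bool))
        spec = estimate_spectrum([call])
        c, t = 1, 3
        assert spec.rates[0, c, t] == pytest.approx(0.2)

    def test_cpg_context_covers_both_positions_of_cg(self):
        call = AncestorCall("t", "ACGA", [], [], np.zeros(4, dtype=bool))
        spec = estimate_spectrum([call])
        # C at 1 and G at 2 are CpG opportunities; both A's are not
        assert spec.opportunities[1, 1] == 1  # C in CpG
        assert spec.opportunities[1, 2] == 1  # G in CpG
        assert spec.opportunities[0, 0] == 2  # A outside CpG

    def test_no_substitutions_gives_zero_rates(self):
        call = AncestorCall("t", "ACGT" * 5, [], [], np.zeros(20, dtype=bool))
        spec = estimate_spectrum([call])
        assert spec.counts.sum() == 0
        assert np.nansum(spec.rates) == 0

    def test_kappa_recovered_from_simulated_substitutions(self):
        rng = np.random.default_rng(0)
        calls = []
        for rep in range(60):
            anc = random_sequence(rng, 2000)
            res = evolve_triple(
                anc, EvolutionParams(branch_focal=0.05, kappa=3.0, seed=rep)
            )
            calls.append(infer_ancestor(res.triple))
        spec = estimate_spectrum(calls)
        n_subs = spec.counts.sum()
        assert n_subs >= 5000
        assert abs(spec.ts_tv_ratio - 3.0) / 3.0 < 0.1


def _call_from_pair(ancestor, positions, alts):
    """AncestorCall for an explicit ancestor/derived pair."""
    subs = [(p, ancestor[p], a) for p, a in sorted(zip(positions, alts))]
    call = AncestorCall("t", ancestor, subs, [False] * len(subs),
                        np.zeros(len(ancestor), dtype=bool))
    return flag_dinucleotides(call)


def _random_pair(rng, length, n_subs, min_gap=0):
    anc = random_sequence(rng, length)
    while True:
        positions = sorted(rng.choice(length, size=n_subs, replace=False))
        if min_gap == 0 or all(
            b - a >= min_gap for a, b in zip(positions, positions[1:])
        ):
            break
    alts = []
    for p in positions:
        choices = [b for b in "ACGT" if b != anc[p]]
        alts.append(choices[rng.integers(3)])
    return _call_from_pair(anc, positions, alts)


class TestDeltaSvm:
    def test_zero_substitutions_give_exactly_zero(self, small_model):
        call = _call_from_pair("ACGT" * 10, [], [])
        delta, n = delta_svm(small_model, call)
        assert delta == 0.0 and n == 0

    def test_uniform_weight_model_gives_zero_delta(self):
        rng = np.random.default_rng(0)
        model = ExternalWeightModel(4, np.ones(256))
        call = _random_pair(rng, 60, 3)
        delta, _ = delta_svm(model, call)
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_matches_full_sequence_rescoring(self, small_model):
        rng = np.random.default_rng(1)
        for n_subs in (1, 2, 4):
            call = _random_pair(rng, 120, n_subs)
            delta, _ = delta_svm(small_model, call)
            brute = small_model.sequence_score(
                call.focal_sequence()
            ) - small_model.sequence_score(call.ancestor)
            assert delta == pytest.approx(brute, abs=1e-9)

    def test_single_substitution_locality(self, small_model):
        # delta must equal the sum over only the windows covering the
        # substituted position, enumerated by hand with weight()
        rng = np.random.default_rng(2)
        l = small_model.l
        call = _random_pair(rng, 80, 1)
        pos = call.substitutions[0][0]
        anc, foc = call.ancestor, call.focal_sequence()
        expected = 0.0
        for w in range(max(0, pos - l + 1), min(pos, len(anc) - l) + 1):
            expected += small_model.weight(foc[w : w + l]) - small_model.weight(
                anc[w : w + l]
            )
        delta, _ = delta_svm(small_model, call)
        assert delta == pytest.approx(expected, abs=1e-9)

    def test_antisymmetry_under_swapping_focal_and_ancestor(self, small_model):
        rng = np.random.default_rng(3)
        call = _random_pair(rng, 100, 3)
        foc = call.focal_sequence()
        reverse = _call_from_pair(
            foc,
            [p for p, _, _ in call.substitutions],
            [a for _, a, _ in call.substitutions],
        )
        d_fwd, _ = delta_svm(small_model, call)
        d_rev, _ = delta_svm(small_model, reverse)
        assert d_fwd == -d_rev

    def test_dinucleotide_exclusion_drops_flagged_substitutions(self, small_model):
        anc = "ACGT" * 25
        call = _call_from_pair(anc, [10, 11, 40], ["C", "A", "T"])
        d_all, n_all = delta_svm(small_model, call, exclude_dinucleotides=False)
        d_excl, n_excl = delta_svm(small_model, call, exclude_dinucleotides=True)
        assert n_all == 3 and n_excl == 1
        lone = _call_from_pair(anc, [40], ["T"])
        assert d_excl == pytest.approx(delta_svm(small_model, lone)[0], abs=1e-12)


class TestDeltaTableAndNull:
    def test_delta_table_matches_exact_single_sub(self, small_model):
        rng = np.random.default_rng(4)
        call = _random_pair(rng, 60, 2)
        scorer = DeltaScorer(small_model, call)
        table = scorer.delta_table()
        for p in rng.choice(60, size=15, replace=False):
            for b in range(4):
                if b == scorer.anc_codes[p]:
                    assert table[p, b] == 0.0
                else:
                    exact = scorer.delta_exact(np.array([p]), np.array([b]))
                    assert table[p, b] == pytest.approx(exact, abs=1e-12)

    def test_distant_substitutions_are_additive(self, small_model):
        rng = np.random.default_rng(5)
        call = _random_pair(rng, 120, 3, min_gap=small_model.l)
        scorer = DeltaScorer(small_model, call)
        table = scorer.delta_table()
        positions = np.array([p for p, _, _ in call.substitutions])
        alts = scorer._sub_alt
        additive = table[positions, alts].sum()
        assert scorer.observed_delta == pytest.approx(additive, abs=1e-9)

    def test_null_sample_matches_exact_recomputation(self, small_model):
        rng = np.random.default_rng(6)
        call = _random_pair(rng, 60, 3)
        scorer = DeltaScorer(small_model, call)
        # regenerate the same draws and verify each against delta_exact
        sample = scorer.sample_null(50, rng=np.random.default_rng(9))
        rng2 = np.random.default_rng(9)
        allowed = np.flatnonzero(~call.excluded)
        keys = rng2.random((50, len(allowed)))
        sel = np.argpartition(keys, 2, axis=1)[:, :3]
        pos = allowed[sel]
        cum = np.cumsum(alternative_base_probs("uniform"), axis=1)
        u = rng2.random((50, 3))
        from enhevo.selection import _ALTS

        anc_b = scorer.anc_codes[pos].astype(np.int64)
        choice = (u[:, :, None] > cum[anc_b]).sum(axis=2).clip(max=2)
        alt = _ALTS[anc_b, choice]
        for i in range(50):
            assert sample[i] == pytest.approx(
                scorer.delta_exact(pos[i], alt[i]), abs=1e-9
            )

    def test_p_value_boundary_when_observed_exceeds_null(self, small_model):
        rng = np.random.default_rng(7)
        call = _random_pair(rng, 80, 2)
        summary = null_distribution(small_model, call, n_permutations=200, seed=1)
        assert 0 < summary.p_value("upper") <= 1
        max_null = summary.sample.max()
        # a fictitious observation above every null draw gets p = 1/(N+1)
        exceed = int((summary.sample >= max_null + 1.0).sum())
        assert (exceed + 1) / (200 + 1) == pytest.approx(1 / 201)

    def test_ts_tv_weighted_null_draws_transitions_three_to_one(self):
        probs = alternative_base_probs("ts_tv_weighted", ts_tv_ratio=3.0)
        assert np.allclose(probs[:, 0], 0.6) and np.allclose(probs[:, 1:], 0.2)
        # empirical check through the null machinery: score counts G's so
        # transition draws from an all-A ancestor are visible in the delta
        table = np.zeros(16)
        for idx in range(16):
            table[idx] = (idx // 4 == 2) + (idx % 4 == 2)  # G count of 2-mer
        model = ExternalWeightModel(2, table)
        call = _call_from_pair("A" * 50, [25], ["G"])
        scorer = DeltaScorer(model, call)
        sample = scorer.sample_null(
            10_000, base_sampling="ts_tv_weighted", rng=np.random.default_rng(3)
        )
        frac_transition = (sample >= 1.0).mean()  # alt G raises G count
        assert 0.55 < frac_transition < 0.65

    def test_spectrum_sampling_uses_estimated_rates(self):
        counts = np.zeros((2, 4, 4))
        counts[0, 0, 2] = 30  # A->G dominates
        counts[0, 0, 1] = 5
        counts[0, 0, 3] = 5
        from enhevo.selection import SubstitutionSpectrum

        spec = SubstitutionSpectrum(counts, np.full((2, 4), 100))
        probs = alternative_base_probs("spectrum", spectrum=spec)
        assert probs[0] == pytest.approx([0.75, 0.125, 0.125])


class TestTestEnhancers:
    def _calls(self, n, seed, length=200, branch=0.03):
        rng = np.random.default_rng(seed)
        calls = []
        for rep in range(n):
            anc = random_sequence(rng, length)
            res = evolve_triple(
                anc,
                EvolutionParams(branch_focal=branch, seed=seed * 1000 + rep),
            )
            calls.append(infer_ancestor(res.triple))
        return calls

    def test_deterministic_under_fixed_seed(self, small_model):
        calls = self._calls(10, seed=1)
        a = test_enhancers(small_model, calls, n_permutations=100, seed=5)
        b = test_enhancers(small_model, calls, n_permutations=100, seed=5)
        assert a.equals(b)

    def test_min_substitution_filter_and_logging(self, small_model):
        calls = self._calls(20, seed=2, branch=0.005)
        res = test_enhancers(small_model, calls, n_permutations=50, seed=1)
        assert res.attrs["n_dropped"] == 20 - len(res)
        assert (res["n_substitutions"] >= 2).all()

    def test_p_values_in_valid_range_and_q_monotone(self, small_model):
        calls = self._calls(15, seed=3)
        res = test_enhancers(small_model, calls, n_permutations=100, seed=2)
        assert ((res["p_value"] > 0) & (res["p_value"] <= 1)).all()
        merged = res.sort_values("p_value")
        assert (merged["q_value"].values >= merged["p_value"].values - 1e-12).all()
        assert (res["positive_call"] == (res["q_value"] < 0.05)).all()

    def test_two_sided_tail_doubles_smaller_tail(self, small_model):
        calls = self._calls(8, seed=4)
        up = test_enhancers(small_model, calls, n_permutations=100, tail="upper", seed=3)
        lo = test_enhancers(small_model, calls, n_permutations=100, tail="lower", seed=3)
        two = test_enhancers(
            small_model, calls, n_permutations=100, tail="two_sided", seed=3
        )
        expected = np.minimum(1.0, 2 * np.minimum(up["p_value"], lo["p_value"]))
        assert np.allclose(two["p_value"], expected)


class TestPositiveProportions:
    def test_grouped_proportions_and_fisher(self):
        results = pd.DataFrame(
            {
                "enhancer_id": [f"e{i}" for i in range(40)],
                "positive_call": [i % 4 == 0 for i in range(40)],
            }
        )
        groups = {f"e{i}": ("conserved" if i < 20 else "nonconserved")
                  for i in range(40)}
        props, fisher = positive_proportion_by_group(
            results, groups, reference="conserved"
        )
        assert set(props["group"]) == {"conserved", "nonconserved"}
        assert props["n"].sum() == 40
        assert (props["n_positive"] <= props["n"]).all()
        assert len(fisher) == 1

    def test_missing_labels_rejected(self):
        results = pd.DataFrame(
            {"enhancer_id": ["e0", "e1"], "positive_call": [True, False]}
        )
        with pytest.raises(ValueError, match="without a group label"):
            positive_proportion_by_group(results, {"e0": "a"})
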