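"""Sequence metrics: Hamming, neighborhoods, counting, developability scores."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from cdrgen.seqspace import (
    AB14_CDR_WT,
    ALPHABET,
    SearchConstraints,
    VariantSequence,
    WildType,
    charge_score,
    count_search_space,
    diversity,
    hamming,
    instability_index,
    neighborhood_size,
    novelty,
    overlap,
    random_neighbor,
)

seq_strategy = st.text(alphabet=ALPHABET, min_size=1, max_size=12)


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,d", [("AAA", "AAA", 0), ("AAA", "AAC", 1), ("ACDEF", "AWDEY", 2)]
    )
    def test_examples(self, a, b, d):
        assert hamming(a, b) == d

    def test_six_substitutions_in_wt(self):
        muts = {0: "W", 5: "A", 12: "C", 20: "P", 28: "M", 32: "K"}
        seq = "".join(muts.get(i, a) for i, a in enumerate(AB14_CDR_WT))
        assert hamming(seq, AB14_CDR_WT) == 6

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hamming("AA", "AAA")

    @given(st.integers(1, 8).flatmap(
        lambda n: st.tuples(*(st.text(alphabet=ALPHABET, min_size=n, max_size=n) for _ in range(3)))
    ))
    @settings(max_examples=200, deadline=None)
    def test_metric_axioms(self, triple):
        a, b, c = triple
        assert hamming(a, b) >= 0
        assert hamming(a, b) == hamming(b, a)
        assert (hamming(a, b) == 0) == (a == b)
        assert hamming(a, c) <= hamming(a, b) + hamming(b, c)


class TestRandomNeighbor:
    def test_neighbor_one_step_away_within_ball(self, wt, constraints, rng):
        x = VariantSequence.from_wildtype(wt.sequence, wt)
        for _ in range(200):
            y = random_neighbor(x, wt, constraints, rng)
            assert hamming(y.sequence, x.sequence) == 1
            assert y.n_mutations <= constraints.d_lim
            x = y

    def test_boundary_never_exceeded(self, wt, rng):
        c = SearchConstraints(d_lim=2)
        x = VariantSequence.from_wildtype(wt.sequence, wt)
        for _ in range(500):
            x = random_neighbor(x, wt, c, rng)
            assert x.n_mutations <= 2

    def test_tiny_space_neighborhood(self, rng):
        # L=3 over full alphabet, from WT the neighborhood is all 57 singles
        wt = WildType("ACD")
        c = SearchConstraints(d_lim=2)
        x = VariantSequence.from_wildtype("ACD", wt)
        seen = {random_neighbor(x, wt, c, rng).sequence for _ in range(3000)}
        expected = {
            "ACD"[:i] + a + "ACD"[i + 1 :]
            for i in range(3)
            for a in ALPHABET
            if a != "ACD"[i]
        }
        assert seen == expected

    def test_uniform_over_neighborhood(self, rng):
        # chi-square goodness of fit over >= 1e5 draws at alpha = 0.001
        wt = WildType("ACD")
        c = SearchConstraints(d_lim=6)
        x = VariantSequence.from_wildtype("ACD", wt)
        counts = {}
        n = 120_000
        for _ in range(n):
            s = random_neighbor(x, wt, c, rng).sequence
            counts[s] = counts.get(s, 0) + 1
        assert len(counts) == 57
        assert chisquare(list(counts.values())).pvalue > 0.001

    def test_boundary_uniform_over_shrunken_neighborhood(self, rng):
        # at distance d_lim only mutated positions may change (19 each)
        wt = WildType("ACD")
        c = SearchConstraints(d_lim=1)
        x = VariantSequence.from_wildtype("WCD", wt)
        seen = {random_neighbor(x, wt, c, rng).sequence for _ in range(2000)}
        expected = {a + "CD" for a in ALPHABET if a != "W"}
        assert seen == expected
        assert neighborhood_size("WCD", wt, c) == 19
        assert neighborhood_size("ACD", wt, c) == 3 * 19


class TestCountSearchSpace:
    def test_printed_design_space(self):
        assert count_search_space(33, 6, 20, "exact-d-positions") == 70_884_352_000_000
        assert count_search_space(33, 6, 20) == pytest.approx(7.088e13, rel=1e-4)

    def test_zero_distance(self):
        assert count_search_space(33, 0, 20, "up-to-d") == 1

    def test_binary_toy(self):
        assert count_search_space(3, 1, 2, "up-to-d") == 4

    @pytest.mark.parametrize("L,A,d", list(itertools.product([2, 3, 4, 5], [2, 3, 4], [0, 1, 2])))
    def test_up_to_d_matches_enumeration(self, L, A, d):
        alphabet = ALPHABET[:A]
        ref = alphabet[0] * L
        n = sum(
            1
            for s in itertools.product(alphabet, repeat=L)
            if hamming("".join(s), ref) <= d
        )
        assert count_search_space(L, d, A, "up-to-d") == n


class TestSetMetrics:
    def test_diversity_identical_records(self):
        assert diversity(["AAA", "AAA"]) == 0.0

    def test_diversity_single_pair(self):
        assert diversity(["AAA", "ACC"]) == 2.0

    def test_disjoint_six_mutation_sets_reach_twelve(self, wt):
        a = "".join({0: "W", 1: "A", 2: "C", 3: "P", 4: "M", 5: "K"}.get(i, x)
                    for i, x in enumerate(wt.sequence))
        b = "".join({10: "W", 11: "A", 12: "C", 13: "P", 14: "E", 15: "K"}.get(i, x)
                    for i, x in enumerate(wt.sequence))
        assert hamming(a, wt.sequence) == hamming(b, wt.sequence) == 6
        assert diversity([a, b]) == 12.0

    def test_diversity_requires_two(self):
        with pytest.raises(ValueError):
            diversity(["AAA"])

    def test_diversity_bounded_by_max_pairwise(self, rng):
        seqs = ["".join(rng.choice(list(ALPHABET), 8)) for _ in range(10)]
        dmax = max(hamming(a, b) for a in seqs for b in seqs)
        assert diversity(seqs) <= dmax

    def test_novelty_subset_is_zero(self):
        assert novelty(["AAA", "CCC"], ["AAA", "CCC", "DDD"]) == 0.0

    def test_novelty_single_pair(self):
        assert novelty(["AAA"], ["CCC"]) == 3.0

    def test_novelty_matches_double_loop(self, rng):
        S = ["".join(rng.choice(list(ALPHABET), 6)) for _ in range(15)]
        ref = ["".join(rng.choice(list(ALPHABET), 6)) for _ in range(7)]
        brute = np.mean([min(hamming(s, r) for r in ref) for s in S])
        assert novelty(S, ref) == pytest.approx(brute)

    def test_novelty_empty_ref(self):
        with pytest.raises(ValueError):
            novelty(["AAA"], [])

    def test_overlap_cases(self):
        assert overlap(["A", "C"], ["A", "C"]) == 1.0
        assert overlap(["A", "C"], ["D", "E"]) == 0.0
        assert overlap(["A", "C", "D", "E"], ["A", "F", "G", "H"]) == 0.25

    def test_overlap_min_denominator(self):
        assert overlap(["A"], ["A", "C", "D", "E"]) == 1.0


class TestDevelopability:
    def test_charge_examples(self):
        assert charge_score("GGGG") == 0.0
        assert charge_score("RKHDE") == pytest.approx(0.1)

    def test_charge_of_wt_is_exactly_zero(self):
        assert AB14_CDR_WT.count("R") == 3
        assert AB14_CDR_WT.count("D") == 3
        assert charge_score(AB14_CDR_WT) == 0.0

    def test_instability_matches_reference_implementation(self, rng):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        for _ in range(100):
            seq = "".join(rng.choice(list(ALPHABET), 33))
            assert instability_index(seq) == pytest.approx(
                ProteinAnalysis(seq).instability_index(), abs=1e-9
            )

    def test_instability_homopolymer_formula(self):
        # self-dipeptide weight w over L-1 dipeptides: 10 (L-1) w / L
        from Bio.SeqUtils import ProtParamData

        w = ProtParamData.DIWV["A"]["A"]
        for L in (2, 5, 33):
            assert instability_index("A" * L) == pytest.approx(10.0 * (L - 1) * w / L)

    def test_unknown_dipeptide_warns_and_uses_unit_weight(self, caplog):
        val = instability_index("AC", table={"A": {}})
        assert val == pytest.approx(10.0 / 2 * 1.0)
        assert "unknown dipeptide" in caplog.text
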