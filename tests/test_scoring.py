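"""Direction assignment, concordance and richness tails, filtering.

The binomial tail is checked against exact rational arithmetic and the
hypergeometric tail against literal enumeration of urn subsets, so every
comparison here is against an independent oracle or a closed form.
"""

from __future__ import annotations

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcr import (
    Hyp,
    ScoredHyp,
    assign_direction,
    concordance_pvalue,
    filter_significant,
    richness_pvalue,
    round_sig,
    score_all,
    score_hyp,
)
from rcr.hyps import compute_population

from .conftest import make_pop
from .oracles import binomial_upper_tail, hypergeom_upper_tail_enum


class TestAssignDirection:
    def test_star_network_majority_vote(self, star_hyp, star_states):
        # 3 nodes imply increase, 1 implies decrease, 1 ambiguous, 1 unchanged
        assert assign_direction(star_hyp, star_states) == (1, 3, 1, 1, 5)

    def test_all_unchanged_gives_no_direction(self, star_hyp):
        assert assign_direction(star_hyp, {}) == (0, 0, 0, 0, 0)

    def test_tie_gives_no_direction_with_tied_counts(self):
        hyp = Hyp("U", {"r(a)": 1, "r(b)": 1, "r(c)": -1, "r(d)": -1})
        states = {"r(a)": 1, "r(b)": 1, "r(c)": 1, "r(d)": 1}  # 2 up vs 2 down
        assert assign_direction(hyp, states) == (0, 2, 2, 0, 4)

    def test_decrease_on_repressive_edge_implies_increase(self):
        hyp = Hyp("U", {"r(a)": -1, "r(b)": -1, "r(c)": -1, "r(d)": -1})
        states = {"r(a)": -1, "r(b)": -1, "r(c)": -1, "r(d)": 1}
        direction, correct, contra, ambiguous, observed = assign_direction(hyp, states)
        assert (direction, correct, contra) == (1, 3, 1)

    def test_only_ambiguous_evidence_gives_no_direction(self):
        hyp = Hyp("U", {"r(a)": "ambiguous", "r(b)": "ambiguous"})
        states = {"r(a)": 1, "r(b)": -1}
        assert assign_direction(hyp, states) == (0, 0, 0, 2, 2)


class TestConcordance:
    @pytest.mark.parametrize(
        "correct,contra,ambiguous,printed",
        [
            (6, 1, 0, 6.3e-2),  # 8/128, prints as 6.3E-02 under half-up
            (7, 0, 0, 7.8e-3),  # 2**-7
            (6, 0, 0, 1.6e-2),  # 2**-6
            (5, 0, 0, 3.1e-2),  # 2**-5
            (4, 0, 0, 6.3e-2),  # 2**-4
            (69, 5, 2, 9.2e-16),  # deep tail, ambiguous excluded from trials
            (22, 9, 0, 1.5e-2),
        ],
    )
    def test_published_mechanism_scores(self, correct, contra, ambiguous, printed):
        p = concordance_pvalue(correct, contra, ambiguous)
        assert round_sig(p, 2) == printed

    def test_zero_trials_is_one(self):
        assert concordance_pvalue(0, 0, 0) == 1.0
        assert concordance_pvalue(0, 0, 5) == 1.0  # ambiguity alone: no trials

    def test_all_correct_is_half_power_trials(self):
        for t in range(1, 30):
            assert concordance_pvalue(t, 0) == pytest.approx(0.5**t, rel=1e-12)

    @settings(derandomize=True, max_examples=80)
    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 5))
    def test_matches_exact_rational_oracle(self, correct, contra, ambiguous):
        expected = binomial_upper_tail(correct, correct + contra)
        got = concordance_pvalue(correct, contra, ambiguous)
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_non_increasing_in_correct_for_fixed_trials(self):
        trials = 12
        vals = [concordance_pvalue(k, trials - k) for k in range(trials + 1)]
        assert vals == sorted(vals, reverse=True)

    def test_point_probabilities_normalize(self):
        # upper tail at k=0 covers the whole distribution
        for t in (1, 7, 40):
            assert concordance_pvalue(0, t) == pytest.approx(1.0, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            concordance_pvalue(-1, 0)


class TestRichness:
    @pytest.mark.parametrize(
        "k,n,N,m,printed",
        [
            (7, 27, 7594, 193, 3.5e-6),
            (76, 417, 6644, 330, 6.2e-25),
            (7, 16, 7500, 1126, 5.6e-3),
            (4, 47, 7594, 193, 3.1e-2),
            (5, 33, 7594, 193, 1.3e-3),
        ],
    )
    def test_published_mechanism_scores(self, k, n, N, m, printed):
        p = richness_pvalue(k, n, make_pop(N, m))
        assert round_sig(p, 2) == printed

    def test_zero_observed_is_one(self):
        assert richness_pvalue(0, 10, make_pop(100, 5)) == 1.0

    def test_small_urn_closed_form(self):
        # 2 of 3 drawn marked, 4 of 10 marked: exactly 1/3 by enumeration
        assert richness_pvalue(2, 3, make_pop(10, 4)) == pytest.approx(1 / 3, rel=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_exhaustive_enumeration_for_small_urns(self, data):
        N = data.draw(st.integers(2, 12))
        m = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(n, m)))
        expected = hypergeom_upper_tail_enum(k, N, m, n)
        got = richness_pvalue(k, n, make_pop(N, m))
        assert got == pytest.approx(float(expected), abs=1e-12)

    def test_non_increasing_in_k(self):
        pop = make_pop(50, 20)
        vals = [richness_pvalue(k, 15, pop) for k in range(16)]
        assert vals == sorted(vals, reverse=True)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            richness_pvalue(5, 200, make_pop(100, 50))  # possible > N
        with pytest.raises(ValueError):
            richness_pvalue(10, 20, make_pop(100, 5))  # observed > m


class TestScoreAll:
    def make_two_hyps(self):
        h1 = Hyp("U", {f"r(u{i})": 1 for i in range(4)})
        h2 = Hyp("V", {f"r(v{i})": 1 for i in range(4)})
        states = {f"r(u{i})": 1 for i in range(4)}  # U fully supported
        return [h1, h2], states

    def test_sorted_by_concordance_then_richness(self):
        hyps, states = self.make_two_hyps()
        pop = compute_population(hyps, states)
        scored = score_all(hyps, states, pop)
        assert [s.upstream for s in scored] == ["U", "V"]
        assert scored[1].richness == 1.0 and scored[1].concordance == 1.0
        assert scored[1].direction == 0

    def test_observed_identity_holds(self, star_hyp, star_states):
        pop = compute_population([star_hyp], star_states)
        s = score_hyp(star_hyp, star_states, pop)
        assert s.observed == s.correct + s.contra + s.ambiguous == 5

    def test_global_negation_flips_direction_and_preserves_pvalues(
        self, star_hyp, star_states
    ):
        pop = compute_population([star_hyp], star_states)
        s = score_hyp(star_hyp, star_states, pop)
        neg = score_hyp(star_hyp, {k: -v for k, v in star_states.items()}, pop)
        assert neg.direction == -s.direction
        assert (neg.correct, neg.contra, neg.ambiguous) == (
            s.correct,
            s.contra,
            s.ambiguous,
        )
        assert neg.concordance == s.concordance
        assert neg.richness == s.richness

    def test_node_relabeling_leaves_scores_unchanged(self, star_hyp, star_states):
        pop = compute_population([star_hyp], star_states)
        s = score_hyp(star_hyp, star_states, pop)
        relabel = {n: f"r(X{i})" for i, n in enumerate(star_hyp.downstream)}
        hyp2 = Hyp("W", {relabel[n]: sg for n, sg in star_hyp.downstream.items()})
        states2 = {relabel[n]: v for n, v in star_states.items()}
        pop2 = compute_population([hyp2], states2)
        s2 = score_hyp(hyp2, states2, pop2)
        assert (s2.concordance, s2.richness, s2.direction) == (
            s.concordance,
            s.richness,
            s.direction,
        )


def scored(richness, concordance, name="x"):
    return ScoredHyp(
        upstream=name,
        direction=1,
        correct=1,
        contra=0,
        ambiguous=0,
        possible=4,
        richness=richness,
        concordance=concordance,
    )


class TestFilterSignificant:
    def test_both_statistics_must_pass(self):
        keep = scored(0.05, 0.09)
        drop = scored(0.05, 0.2)
        assert filter_significant([keep, drop], alpha=0.1) == [keep]

    def test_threshold_is_inclusive(self):
        assert filter_significant([scored(0.1, 0.1)], alpha=0.1)

    def test_alpha_bounds_validated(self):
        with pytest.raises(ValueError):
            filter_significant([], alpha=0.0)
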