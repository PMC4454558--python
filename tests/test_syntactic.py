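"""Syntactic feature measures against closed forms and brute-force oracles."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sentsim.features.syntactic import (
    DegeneratePairError,
    bag_overlap,
    effective_set_similarity,
    jaccard,
    lemma_vector_cosine,
    length_ratio,
    polarity_feature,
    skipped_bigram_ratio,
    window_features,
)

from conftest import OUTCOME_A, OUTCOME_B

tokens_strategy = st.lists(st.sampled_from("abc"), min_size=0, max_size=8)


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------


def window_oracle(a, b):
    """Exhaustive enumeration over every (k, i, j) window triple."""
    n = min(len(a), len(b))
    if n < 2:
        return 0.0, 0.0
    total = 0
    longest = 0
    for k in range(2, n + 1):
        for i in range(len(a) - k + 1):
            for j in range(len(b) - k + 1):
                if tuple(a[i : i + k]) == tuple(b[j : j + k]):
                    total += 1
                    longest = max(longest, k)
    return min(1.0, total / math.comb(n, 2)), longest / n


def skipped_bigram_oracle(a, b):
    sa = {(a[i], a[j]) for i in range(len(a)) for j in range(i + 1, len(a))}
    sb = {(b[i], b[j]) for i in range(len(b)) for j in range(i + 1, len(b))}
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / max(len(sa), len(sb))


# --------------------------------------------------------------------------
# worked example values
# --------------------------------------------------------------------------


class TestWorkedExample:
    def test_word_bag_overlap(self, outcome_pair):
        sent_a, sent_b = outcome_pair
        shared = sum((Counter(sent_a.tokens) & Counter(sent_b.tokens)).values())
        assert shared == 14
        assert bag_overlap(sent_a.tokens, sent_b.tokens) == pytest.approx(0.7)

    def test_lemma_bag_overlap(self, outcome_pair):
        sent_a, sent_b = outcome_pair
        assert bag_overlap(sent_a.lemmas, sent_b.lemmas) == pytest.approx(0.7)

    def test_effective_set_similarity_printed_sets(self):
        s1 = {"event", "retention", "disturbance", "wound", "infection", "be",
              "report", "group"}
        s2 = {"event", "retention", "disturbance", "wound", "infection", "be"}
        assert effective_set_similarity(s1, s2) == pytest.approx(0.75)

    def test_jaccard_of_word_sets(self, outcome_pair):
        sent_a, sent_b = outcome_pair
        assert jaccard(set(sent_a.tokens), set(sent_b.tokens)) == pytest.approx(14 / 25)

    def test_length_ratio(self, outcome_pair):
        sent_a, sent_b = outcome_pair
        assert length_ratio(len(sent_a.tokens), len(sent_b.tokens)) == pytest.approx(0.95)

    def test_skipped_bigram_ratio_soft_target(self, outcome_pair):
        sent_a, sent_b = outcome_pair
        content_a = tuple(sent_a.tokens[i] for i in sent_a.content_indices())
        content_b = tuple(sent_b.tokens[i] for i in sent_b.content_indices())
        value = skipped_bigram_ratio(content_a, content_b)
        assert value == pytest.approx(0.6286, abs=0.05)  # tagger-dependent

    def test_polarity_feature_zero(self, outcome_pair):
        sent_a, sent_b = outcome_pair
        assert polarity_feature(sent_a.negated, sent_b.negated) == 0


# --------------------------------------------------------------------------
# closed forms and edge cases
# --------------------------------------------------------------------------


class TestClosedForms:
    def test_identical_and_disjoint_bags(self):
        assert bag_overlap(("a", "b"), ("a", "b")) == 1.0
        assert bag_overlap(("a", "b"), ("c", "d")) == 0.0

    def test_multiset_matching_without_replacement(self):
        # the duplicate "a" in the first bag matches only one "a" in the second
        assert bag_overlap(("a", "a", "b"), ("a", "c", "d")) == pytest.approx(1 / 3)

    @pytest.mark.parametrize(
        "func", [bag_overlap, effective_set_similarity, jaccard, lemma_vector_cosine]
    )
    def test_degenerate_pair_raises(self, func):
        with pytest.raises(DegeneratePairError):
            func((), ())

    def test_cosine_closed_form(self):
        # counts (1,1,0) vs (1,0,1)
        assert lemma_vector_cosine(("x", "y"), ("x", "z")) == pytest.approx(0.5)

    def test_polarity_disagreement(self):
        assert polarity_feature(True, False) == 1
        assert polarity_feature(False, False) == 0

    def test_length_ratio_rejects_zero(self):
        with pytest.raises(ValueError):
            length_ratio(0, 5)

    def test_window_short_sequence_warns_zero(self):
        assert window_features(("a",), ("a", "b")) == (0.0, 0.0)


# --------------------------------------------------------------------------
# oracle equivalence and invariants
# --------------------------------------------------------------------------


class TestOracles:
    @given(tokens_strategy, tokens_strategy)
    def test_window_features_match_brute_force(self, a, b):
        assert window_features(a, b) == pytest.approx(window_oracle(a, b))

    @given(tokens_strategy.filter(bool), tokens_strategy.filter(bool))
    def test_skipped_bigrams_match_brute_force(self, a, b):
        assert skipped_bigram_ratio(a, b) == pytest.approx(skipped_bigram_oracle(a, b))

    def test_shared_block_of_three(self):
        a = ["x", "p", "q", "r", "y"]
        b = ["z", "p", "q", "r", "w"]
        # equal windows: pqr (k=3), pq, qr (k=2) -> 3 / C(5,2); longest 3/5
        assert window_features(a, b) == pytest.approx((3 / 10, 3 / 5))
        assert window_features(a, b) == pytest.approx(window_oracle(a, b))


class TestInvariants:
    @given(tokens_strategy.filter(bool), tokens_strategy.filter(bool))
    def test_symmetry_and_bounds(self, a, b):
        for func in (bag_overlap, skipped_bigram_ratio):
            assert func(a, b) == pytest.approx(func(b, a))
            assert 0.0 <= func(a, b) <= 1.0
        for func in (effective_set_similarity, jaccard):
            assert func(set(a), set(b)) == pytest.approx(func(set(b), set(a)))
            assert 0.0 <= func(set(a), set(b)) <= 1.0
        wa, wb = window_features(a, b), window_features(b, a)
        assert wa == pytest.approx(wb)
        assert all(0.0 <= v <= 1.0 for v in wa)

    @given(tokens_strategy.filter(bool))
    def test_self_similarity_is_one(self, a):
        assert bag_overlap(a, a) == 1.0
        assert jaccard(set(a), set(a)) == 1.0
        assert lemma_vector_cosine(a, a) == pytest.approx(1.0)
        assert skipped_bigram_ratio(a, a) in (1.0, 0.0)  # 0 only if < 2 tokens
        assert length_ratio(len(a), len(a)) == 1.0
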