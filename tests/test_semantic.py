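"""Semantic features against hand-enumerated fixture values and a
brute-force alignment oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sentsim.backends import lin_similarity, wu_palmer_similarity
from sentsim.features import semantic
from sentsim.preprocess import process

tags_strategy = st.lists(st.sampled_from(["NN", "VB", "JJ"]), min_size=0, max_size=8)


def nw_oracle(a, b):
    """Exhaustive recursion over all global alignments (match 1, mismatch/gap -1)."""
    if not a:
        return -len(b)
    if not b:
        return -len(a)
    sub = 1 if a[0] == b[0] else -1
    return max(
        sub + nw_oracle(a[1:], b[1:]),
        -1 + nw_oracle(a[1:], b),
        -1 + nw_oracle(a, b[1:]),
    )


def taxonomy_pair_sim(lemma_a, lemma_b, taxonomy):
    """Direct evaluation of the Lin / Wu-Palmer average on first senses."""
    sa = taxonomy.synsets_of(lemma_a, "n")[0]
    sb = taxonomy.synsets_of(lemma_b, "n")[0]
    return 0.5 * (lin_similarity(sa, sb, taxonomy) + wu_palmer_similarity(sa, sb, taxonomy))


class TestNeedlemanWunsch:
    @given(tags_strategy, tags_strategy)
    def test_matches_exhaustive_alignment_oracle(self, a, b):
        assert semantic.needleman_wunsch_score(a, b) == pytest.approx(nw_oracle(a, b))

    def test_identical_sequences_score_one(self):
        assert semantic.pos_alignment(["NN", "VB", "JJ"], ["NN", "VB", "JJ"]) == 1.0

    def test_full_mismatch_clipped_to_zero(self):
        assert semantic.pos_alignment(["NN", "NN"], ["VB", "VB"]) == 0.0

    def test_empty_vs_nonempty_zero(self):
        assert semantic.pos_alignment([], ["NN"]) == 0.0

    def test_four_vs_three_toy(self):
        a, b = ["NN", "VB", "JJ", "NN"], ["NN", "JJ", "NN"]
        expected = max(nw_oracle(a, b), 0) / 4
        assert semantic.pos_alignment(a, b) == pytest.approx(expected)


class TestRoleSimilarity:
    def test_post_verb_empty_side_gives_zero(self, outcome_pair, bundle):
        sent_a, sent_b = outcome_pair
        assert semantic.role_similarity(sent_a, sent_b, "post_verb", bundle) == 0.0

    def test_identical_single_word_noun_bags(self, bundle):
        a = process("dogs bark")
        assert semantic.role_similarity(a, a, "pre_verb", bundle) == pytest.approx(1.0)

    def test_predicates_sharing_a_frame_are_identical(self, bundle):
        # run and walk share the Motion frame -> indicator 1
        a, b = process("dogs run"), process("cats walk")
        assert semantic.role_similarity(a, b, "predicate", bundle) == 1.0

    def test_pre_verb_value_matches_hand_evaluation(self, bundle):
        a, b = process("dogs run"), process("cats walk")
        expected = taxonomy_pair_sim("dog", "cat", bundle.taxonomy)
        assert semantic.role_similarity(a, b, "pre_verb", bundle) == pytest.approx(expected)

    def test_unknown_role_rejected(self, bundle):
        a = process("dogs run")
        with pytest.raises(ValueError):
            semantic.role_similarity(a, a, "subject", bundle)


class TestEffectiveSemanticSimilarity:
    def test_two_by_two_hand_average(self, bundle):
        # effective pairs: dog-cat (taxonomy), dog-walk 0, run-cat 0,
        # run-walk (shared Motion frame) = 1
        a, b = process("dogs run"), process("cats walk")
        expected = (taxonomy_pair_sim("dog", "cat", bundle.taxonomy) + 1.0) / 4.0
        assert semantic.effective_semantic_similarity(a, b, bundle) == pytest.approx(expected)

    def test_out_of_lexicon_sentences_give_zero(self, bundle):
        a, b = process("zorp glik"), process("mumble frotz")
        assert semantic.effective_semantic_similarity(a, b, bundle) == 0.0

    def test_single_shared_word_is_one(self, bundle):
        a = process("infection")
        assert semantic.effective_semantic_similarity(a, a, bundle) == pytest.approx(1.0)


class TestICVectorCosine:
    def test_identical_sentences_one(self, bundle):
        a = process("the infection was treated")
        assert semantic.ic_vector_cosine(a, a, bundle.taxonomy) == pytest.approx(1.0)

    def test_unknown_lemmas_zero_with_warning(self, bundle, caplog):
        a, b = process("zorp glik"), process("mumble frotz")
        with caplog.at_level("WARNING"):
            assert semantic.ic_vector_cosine(a, b, bundle.taxonomy) == 0.0
        assert "all-zero" in caplog.text

    def test_three_vs_two_lemma_closed_form(self, bundle):
        tax = bundle.taxonomy
        a, b = process("dog cat infection"), process("dog cat")
        ic = lambda l: tax.ic(tax.synsets_of(l)[0])
        va = np.array([ic("dog"), ic("cat"), ic("infection")])
        vb = np.array([ic("dog"), ic("cat"), 0.0])
        expected = va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))
        assert semantic.ic_vector_cosine(a, b, tax) == pytest.approx(expected)


class TestSynonymyFeatures:
    def test_lexically_disjoint_synonyms_share_synsets(self, bundle):
        # "drug" and "medication" are lemmas of the same synset
        a, b = process("the drug helped"), process("the medication helped")
        assert semantic.wordnet_synonym_similarity(a, b, bundle.taxonomy) == pytest.approx(1.0)

    def test_no_shared_synsets_zero(self, bundle):
        a, b = process("the dog barked"), process("the placebo failed")
        assert semantic.wordnet_synonym_similarity(a, b, bundle.taxonomy) == 0.0

    def test_frame_synonymy_over_nouns(self, bundle):
        # infection and disease share the Medical_condition frame
        a, b = process("an infection appeared"), process("the disease appeared")
        assert semantic.framenet_synonym_similarity(a, b, bundle) == pytest.approx(1.0)

    def test_identical_sentences_one(self, bundle):
        a = process("the infection was severe")
        assert semantic.wordnet_synonym_similarity(a, a, bundle.taxonomy) == 1.0
        assert semantic.framenet_synonym_similarity(a, a, bundle) == 1.0


class TestBestSenseFeatures:
    def test_identical_sentences_both_one(self, bundle):
        a = process("the patient received the drug")
        sense, related = semantic.best_sense_features(a, a, bundle.taxonomy)
        assert sense == 1.0 and related == 1.0

    def test_synonym_pair_shares_related_but_not_encodings(self, bundle):
        # "subject" (patient sense) vs "patient": different lemma encodings,
        # identical best-sense synset, hence identical related-synset sets
        a = process("the subject received medical treatment")
        b = process("the patient received medical treatment")
        sense, related = semantic.best_sense_features(a, b, bundle.taxonomy)
        assert related == pytest.approx(1.0)
        assert sense < 1.0

    def test_category_features_for_same_category_pair(self, bundle):
        a, b = process("the doctor spoke"), process("the patient spoke")
        set_sim, cos = semantic.sense_category_features(a, b, bundle.taxonomy)
        assert set_sim == pytest.approx(1.0)  # both noun.person
        assert 0.0 <= cos <= 1.0

    def test_sense_skipped_bigrams_on_category_sequences(self, bundle):
        a = process("the dog chased the cat")
        b = process("the cat chased the dog")
        # category sequence is (noun.animal, noun.animal) on both sides
        assert semantic.sense_skipped_bigram_similarity(a, b, bundle.taxonomy) == 1.0

    def test_undisambiguable_words_are_skipped(self, bundle):
        a = process("zorp dances")
        assert semantic.best_senses(a, bundle.taxonomy) == ()


class TestDistributionalFeatures:
    def test_identical_sentences_associated_terms_one(self, bundle):
        a = process("the dog chased the cat")
        assert semantic.associated_terms_set_similarity(a, a, bundle) == 1.0

    def test_term_matrix_cosine_identical_one(self, bundle):
        a = process("the dog chased the cat")
        assert semantic.term_matrix_cosine(a, a, bundle) == pytest.approx(1.0)

    def test_matrix_cosine_closed_forms(self):
        m1 = np.array([[1.0, 0.0], [0.0, 1.0]])
        m2 = np.array([[0.0, 1.0], [-1.0, 0.0]])
        assert semantic.matrix_cosine(m1, m1) == pytest.approx(1.0)
        assert semantic.matrix_cosine(m1, m2) == pytest.approx(0.0)

    def test_padded_frobenius_cosine_by_hand(self):
        a = np.array([[1.0, 2.0, 0.0], [0.0, 1.0, 1.0]])
        b = np.array([[1.0, 0.0, 1.0]])
        b_padded = np.vstack([b, np.zeros((1, 3))])
        expected = np.sum(a * b_padded) / (np.linalg.norm(a) * np.linalg.norm(b_padded))
        assert semantic.matrix_cosine(a, b_padded) == pytest.approx(expected)


class TestBackendAbsenceInvariance:
    @pytest.mark.parametrize(
        "feature",
        [
            lambda x, y, b: semantic.wordnet_synonym_similarity(x, y, b.taxonomy),
            lambda x, y, b: semantic.framenet_synonym_similarity(x, y, b),
            lambda x, y, b: semantic.best_sense_features(x, y, b.taxonomy)[0],
            lambda x, y, b: semantic.best_sense_features(x, y, b.taxonomy)[1],
            lambda x, y, b: semantic.sense_category_features(x, y, b.taxonomy)[0],
            lambda x, y, b: semantic.associated_terms_set_similarity(x, y, b),
        ],
    )
    def test_unknown_word_never_changes_set_features(self, bundle, feature):
        # a word absent from every backend contributes nothing to the
        # set-valued semantic features
        base = process("the dog chased the cat")
        extended = process("the dog chased the frobnicated cat")
        assert feature(extended, base, bundle) == pytest.approx(feature(base, base, bundle))
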