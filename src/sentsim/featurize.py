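"""Assemble the 34-feature similarity vector for a sentence pair.

:func:`compute_features` maps a pair of :class:`ProcessedSentence` objects
to the named feature dict; :class:`PairFeaturizer` is the sklearn
transformer over raw text pairs that the relatedness model consumes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .backends import LexicalBackendBundle, build_mini_lexicon
from .preprocess import EFFECTIVE_POLICIES, ProcessedSentence, process
from .registry import FEATURE_NAMES
from .features import semantic, structural, syntactic

logger = logging.getLogger(__name__)


class FeaturizationError(RuntimeError):
    """A sentence of the pair could not be processed; names the stage."""


def compute_features(
    sent_a: ProcessedSentence,
    sent_b: ProcessedSentence,
    backends: LexicalBackendBundle,
    associated_terms_k: int = 20,
) -> dict[str, float]:
    """All 34 features for one processed pair, in registry order.

    Degenerate sub-measures fall back to 0 (logged by the feature
    functions); the naive overlaps raise on a pair that is empty on both
    sides, surfacing corpus-level bugs.
    """
    f: dict[str, float] = {}

    tokens_a, tokens_b = sent_a.tokens, sent_b.tokens
    eff_a, eff_b = sent_a.effective_lemmas, sent_b.effective_lemmas

    # naive
    f["words_overlap"] = syntactic.bag_overlap(tokens_a, tokens_b)
    f["lemmas_overlap"] = syntactic.bag_overlap(sent_a.lemmas, sent_b.lemmas)
    f["stems_overlap"] = syntactic.bag_overlap(sent_a.stems, sent_b.stems)
    f["effective_lemma_set_sim"] = (
        syntactic.effective_set_similarity(set(eff_a), set(eff_b))
        if eff_a or eff_b
        else 0.0
    )
    f["jaccard_words"] = syntactic.jaccard(set(tokens_a), set(tokens_b))
    f["jaccard_lemmas"] = syntactic.jaccard(set(sent_a.lemmas), set(sent_b.lemmas))
    f["effective_lemma_cosine"] = (
        syntactic.lemma_vector_cosine(eff_a, eff_b) if eff_a or eff_b else 0.0
    )

    # window-based
    f["window_overlap_words"], f["longest_window_words"] = syntactic.window_features(
        tokens_a, tokens_b
    )
    f["window_overlap_effective"], f["longest_window_effective"] = (
        syntactic.window_features(eff_a, eff_b)
    )
    f["window_overlap_pos"], f["longest_window_pos"] = syntactic.window_features(
        sent_a.pos_tags, sent_b.pos_tags
    )

    # other syntactic
    content_a = tuple(sent_a.tokens[i] for i in sent_a.content_indices())
    content_b = tuple(sent_b.tokens[i] for i in sent_b.content_indices())
    f["skipped_bigram_ratio"] = syntactic.skipped_bigram_ratio(content_a, content_b)
    f["polarity_difference"] = syntactic.polarity_feature(sent_a.negated, sent_b.negated)
    f["length_ratio"] = syntactic.length_ratio(len(tokens_a), len(tokens_b))

    # structural
    f["clause_ratio"] = structural.clause_ratio(len(sent_a.clauses), len(sent_b.clauses))
    f["reduced_tree_overlap"] = structural.reduced_tree_overlap(
        sent_a.reduced_tree,
        sent_b.reduced_tree,
        [c.n_words for c in sent_a.clauses],
        [c.n_words for c in sent_b.clauses],
    )

    # basic semantic
    for role, name in (
        ("pre_verb", "role_sim_pre_verb"),
        ("predicate", "role_sim_predicate"),
        ("post_verb", "role_sim_post_verb"),
    ):
        f[name] = semantic.role_similarity(sent_a, sent_b, role, backends)
    f["effective_semantic_sim"] = semantic.effective_semantic_similarity(
        sent_a, sent_b, backends
    )
    f["ic_vector_cosine"] = semantic.ic_vector_cosine(sent_a, sent_b, backends.taxonomy)
    f["pos_alignment_pre_verb"] = semantic.pos_alignment(
        semantic.role_pos_tags(sent_a, "pre_verb"),
        semantic.role_pos_tags(sent_b, "pre_verb"),
    )
    f["pos_alignment_post_verb"] = semantic.pos_alignment(
        semantic.role_pos_tags(sent_a, "post_verb"),
        semantic.role_pos_tags(sent_b, "post_verb"),
    )

    # synonymy
    f["wordnet_synonym_sim"] = semantic.wordnet_synonym_similarity(
        sent_a, sent_b, backends.taxonomy
    )
    f["framenet_synonym_sim"] = semantic.framenet_synonym_similarity(
        sent_a, sent_b, backends
    )

    # word sense
    f["best_sense_set_sim"], f["related_synset_set_sim"] = semantic.best_sense_features(
        sent_a, sent_b, backends.taxonomy
    )
    f["sense_category_set_sim"], f["sense_category_cosine"] = (
        semantic.sense_category_features(sent_a, sent_b, backends.taxonomy)
    )
    f["sense_skipped_bigram_sim"] = semantic.sense_skipped_bigram_similarity(
        sent_a, sent_b, backends.taxonomy
    )

    # vector space
    f["associated_terms_sim"] = semantic.associated_terms_set_similarity(
        sent_a, sent_b, backends, k=associated_terms_k
    )
    # raw matrix cosine lives in [-1, 1]; clipped at 0 in the feature vector
    f["term_matrix_cosine"] = max(
        0.0, semantic.term_matrix_cosine(sent_a, sent_b, backends)
    )

    assert list(f) == list(FEATURE_NAMES)
    return f


def feature_vector(features: dict[str, float]) -> np.ndarray:
    """Dict -> dense vector in registry order."""
    return np.array([features[n] for n in FEATURE_NAMES], dtype=float)


class PairFeaturizer(TransformerMixin, BaseEstimator):
    """Transform raw sentence pairs into the 34-column feature matrix.

    Parameters
    ----------
    backends:
        A :class:`LexicalBackendBundle`, or None to build the bundled
        deterministic mini-lexicon at fit time (seeded by ``random_state``).
    effective_policy:
        Effective-word policy, ``"content"`` (default; drops closed-class
        words) or ``"nouns_verbs"``.
    associated_terms_k:
        Number of associated distributional terms per word.
    """

    def __init__(
        self,
        backends: LexicalBackendBundle | None = None,
        effective_policy: str = "content",
        associated_terms_k: int = 20,
        random_state: int = 0,
    ):
        self.backends = backends
        self.effective_policy = effective_policy
        self.associated_terms_k = associated_terms_k
        self.random_state = random_state

    def fit(self, X: Iterable[Sequence[str]] | None = None, y=None) -> "PairFeaturizer":
        if self.effective_policy not in EFFECTIVE_POLICIES:
            raise ValueError(f"unknown effective policy {self.effective_policy!r}")
        self.backends_ = (
            self.backends
            if self.backends is not None
            else build_mini_lexicon(self.random_state)
        )
        logger.info("featurizer ready (backends: %s)", self.backends_.manifest)
        return self

    def _process(self, text: str, side: str) -> ProcessedSentence:
        try:
            return process(text, effective_policy=self.effective_policy)
        except Exception as exc:
            raise FeaturizationError(
                f"preprocessing failed for sentence {side}: {text!r} ({exc})"
            ) from exc

    def transform(self, X: Iterable[Sequence[str]]) -> np.ndarray:
        """X is an iterable of (sentence_a, sentence_b) text pairs."""
        check_is_fitted(self, "backends_")
        rows = []
        for pair in X:
            a, b = pair[0], pair[1]
            sent_a = self._process(a, "A")
            sent_b = self._process(b, "B")
            rows.append(
                feature_vector(
                    compute_features(
                        sent_a, sent_b, self.backends_,
                        associated_terms_k=self.associated_terms_k,
                    )
                )
            )
        return np.vstack(rows) if rows else np.empty((0, len(FEATURE_NAMES)))

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(FEATURE_NAMES, dtype=object)
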