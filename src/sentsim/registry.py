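"""Fixed registry of the 34 pairwise similarity features.

The registry is the single source of truth for feature names, their order in
the numeric feature vector, and their grouping into the eight feature sets
used by the ablation protocol (naive, window-based, other syntactic,
sentence structure, basic semantic, synonymy, word sense, vector space).
"""

from __future__ import annotations

from collections import OrderedDict

#: Feature groups in canonical order.  Group sizes: 7/6/3/2/7/2/5/2 = 34.
FEATURE_GROUPS: "OrderedDict[str, tuple[str, ...]]" = OrderedDict(
    [
        (
            "naive",
            (
                "words_overlap",
                "lemmas_overlap",
                "stems_overlap",
                "effective_lemma_set_sim",
                "jaccard_words",
                "jaccard_lemmas",
                "effective_lemma_cosine",
            ),
        ),
        (
            "window",
            (
                "window_overlap_words",
                "longest_window_words",
                "window_overlap_effective",
                "longest_window_effective",
                "window_overlap_pos",
                "longest_window_pos",
            ),
        ),
        (
            "other_syntactic",
            (
                "skipped_bigram_ratio",
                "polarity_difference",
                "length_ratio",
            ),
        ),
        (
            "structure",
            (
                "clause_ratio",
                "reduced_tree_overlap",
            ),
        ),
        (
            "basic_semantic",
            (
                "role_sim_pre_verb",
                "role_sim_predicate",
                "role_sim_post_verb",
                "effective_semantic_sim",
                "ic_vector_cosine",
                "pos_alignment_pre_verb",
                "pos_alignment_post_verb",
            ),
        ),
        (
            "synonymy",
            (
                "wordnet_synonym_sim",
                "framenet_synonym_sim",
            ),
        ),
        (
            "word_sense",
            (
                "best_sense_set_sim",
                "related_synset_set_sim",
                "sense_category_set_sim",
                "sense_category_cosine",
                "sense_skipped_bigram_sim",
            ),
        ),
        (
            "vector_space",
            (
                "associated_terms_sim",
                "term_matrix_cosine",
            ),
        ),
    ]
)

#: All 34 feature names in vector order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    name for names in FEATURE_GROUPS.values() for name in names
)

#: name -> column index in the feature vector.
FEATURE_INDEX: dict[str, int] = {n: i for i, n in enumerate(FEATURE_NAMES)}

N_FEATURES: int = len(FEATURE_NAMES)

assert N_FEATURES == 34


def group_of(feature_name: str) -> str:
    """Return the group a feature belongs to."""
    for group, names in FEATURE_GROUPS.items():
        if feature_name in names:
            return group
    raise KeyError(f"unknown feature name: {feature_name!r}")


def group_columns(group: str) -> list[int]:
    """Column indices of the features in *group*."""
    if group not in FEATURE_GROUPS:
        raise KeyError(f"unknown feature group: {group!r}")
    return [FEATURE_INDEX[n] for n in FEATURE_GROUPS[group]]
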