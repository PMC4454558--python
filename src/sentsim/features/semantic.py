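"""Semantic similarity measures backed by the lexical knowledge bundle.

Role-based word-by-word similarity mixes Lin and Wu-Palmer taxonomy
similarity for pre-/post-verb components and a FrameNet-style shared-frame
indicator for predicates; further measures cover information-content
vectors, Needleman-Wunsch POS alignment, synset/frame synonymy, Lesk best
senses with lexicographer categories, and HAL-style distributional vectors.

Lookup failures (a word absent from a backend) contribute a word-pair
similarity of 0 rather than shrinking the denominators, so the printed
normalisers are preserved; the failures are logged at DEBUG level.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from ..backends import (
    LexicalBackendBundle,
    SenseAnnotation,
    Taxonomy,
    UnknownWordError,
    best_sense,
    lin_similarity,
    wu_palmer_similarity,
)
from ..preprocess import ProcessedSentence

logger = logging.getLogger(__name__)

ROLES = ("pre_verb", "predicate", "post_verb")


def _coarse_pos(tag: str) -> str | None:
    if tag.startswith("NN"):
        return "n"
    if tag.startswith("VB"):
        return "v"
    return None


# --------------------------------------------------------------------------
# word-pair similarities
# --------------------------------------------------------------------------


def taxonomy_word_similarity(lemma_a: str, lemma_b: str, taxonomy: Taxonomy) -> float:
    """Average of Lin and Wu-Palmer similarity between the best-matching
    synsets of the two lemmas (max over synset pairs); 0 when either lemma
    is absent from the taxonomy."""
    syns_a = taxonomy.synsets_of(lemma_a, "n")
    syns_b = taxonomy.synsets_of(lemma_b, "n")
    if not syns_a or not syns_b:
        logger.debug("taxonomy lookup failure for (%r, %r)", lemma_a, lemma_b)
        return 0.0
    best = 0.0
    for sa in syns_a:
        for sb in syns_b:
            sim = 0.5 * (
                lin_similarity(sa, sb, taxonomy)
                + wu_palmer_similarity(sa, sb, taxonomy)
            )
            best = max(best, sim)
    return best


def frame_word_similarity(lemma_a: str, lemma_b: str, bundle: LexicalBackendBundle) -> float:
    """1 if the two lemmas share any frame, else 0."""
    shared = bundle.frames.frames_of(lemma_a) & bundle.frames.frames_of(lemma_b)
    return 1.0 if shared else 0.0


# --------------------------------------------------------------------------
# role-based similarity (pre-verb / predicate / post-verb)
# --------------------------------------------------------------------------


def _bag_similarity_taxonomy(
    bag_a: Sequence[str], bag_b: Sequence[str], taxonomy: Taxonomy
) -> float:
    """Mean over all cross word pairs of the Lin/Wu-Palmer average."""
    if not bag_a or not bag_b:
        return 0.0
    total = sum(
        taxonomy_word_similarity(w, w2, taxonomy) for w in bag_a for w2 in bag_b
    )
    return total / (len(bag_a) * len(bag_b))


def _bag_similarity_frames(
    bag_a: Sequence[str], bag_b: Sequence[str], bundle: LexicalBackendBundle
) -> float:
    """Mean over all cross word pairs of the shared-frame indicator."""
    if not bag_a or not bag_b:
        return 0.0
    total = sum(
        frame_word_similarity(w, w2, bundle) for w in bag_a for w2 in bag_b
    )
    return total / (len(bag_a) * len(bag_b))


def role_similarity(
    sent_a: ProcessedSentence,
    sent_b: ProcessedSentence,
    role: str,
    bundle: LexicalBackendBundle,
) -> float:
    """Mean over all clause-bag pairs of the role's bag similarity
    (taxonomy mixture for pre-/post-verb, frame indicator for predicates)."""
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    bags_a = [getattr(c, role) for c in sent_a.clauses]
    bags_b = [getattr(c, role) for c in sent_b.clauses]
    if not bags_a or not bags_b:
        return 0.0
    total = 0.0
    for ba in bags_a:
        for bb in bags_b:
            if role == "predicate":
                total += _bag_similarity_frames(ba, bb, bundle)
            else:
                total += _bag_similarity_taxonomy(ba, bb, bundle.taxonomy)
    return total / (len(bags_a) * len(bags_b))


# --------------------------------------------------------------------------
# sentence-wide semantic similarity of effective words
# --------------------------------------------------------------------------


def effective_semantic_similarity(
    sent_a: ProcessedSentence,
    sent_b: ProcessedSentence,
    bundle: LexicalBackendBundle,
) -> float:
    """Mean word-pair similarity over all cross-sentence effective-word
    pairs: nouns through the taxonomy, verbs through the frame lexicon."""
    idx_a, idx_b = sorted(sent_a.effective_indices), sorted(sent_b.effective_indices)
    if not idx_a or not idx_b:
        return 0.0
    total = 0.0
    for i in idx_a:
        pos_i = _coarse_pos(sent_a.pos_tags[i])
        for j in idx_b:
            pos_j = _coarse_pos(sent_b.pos_tags[j])
            if pos_i == "n" and pos_j == "n":
                total += taxonomy_word_similarity(
                    sent_a.lemmas[i], sent_b.lemmas[j], bundle.taxonomy
                )
            elif pos_i == "v" and pos_j == "v":
                total += frame_word_similarity(
                    sent_a.lemmas[i], sent_b.lemmas[j], bundle
                )
    return total / (len(idx_a) * len(idx_b))


# --------------------------------------------------------------------------
# IC vectors
# --------------------------------------------------------------------------


def _lemma_ic(lemma: str, taxonomy: Taxonomy) -> float:
    synsets = taxonomy.synsets_of(lemma)
    return taxonomy.ic(synsets[0]) if synsets else 0.0


def ic_vector_cosine(
    sent_a: ProcessedSentence,
    sent_b: ProcessedSentence,
    taxonomy: Taxonomy,
) -> float:
    """Cosine of the ordered per-lemma information-content vectors (missing
    lemma -> 0; the shorter vector is zero-padded)."""
    va = np.array([_lemma_ic(l, taxonomy) for l in sent_a.lemmas])
    vb = np.array([_lemma_ic(l, taxonomy) for l in sent_b.lemmas])
    n = max(len(va), len(vb))
    va = np.pad(va, (0, n - len(va)))
    vb = np.pad(vb, (0, n - len(vb)))
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        logger.warning("all-zero IC vector; cosine 0")
        return 0.0
    return float(va @ vb / (na * nb))


# --------------------------------------------------------------------------
# Needleman-Wunsch POS alignment
# --------------------------------------------------------------------------


def needleman_wunsch_score(
    seq_a: Sequence[str], seq_b: Sequence[str],
    match: float = 1.0, mismatch: float = -1.0, gap: float = -1.0,
) -> float:
    """Global alignment score (linear gap penalty)."""
    la, lb = len(seq_a), len(seq_b)
    dp = np.empty((la + 1, lb + 1))
    dp[0, :] = gap * np.arange(lb + 1)
    dp[:, 0] = gap * np.arange(la + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            sub = match if seq_a[i - 1] == seq_b[j - 1] else mismatch
            dp[i, j] = max(dp[i - 1, j - 1] + sub, dp[i - 1, j] + gap, dp[i, j - 1] + gap)
    return float(dp[la, lb])


def pos_alignment(seq_a: Sequence[str], seq_b: Sequence[str]) -> float:
    """Needleman-Wunsch alignment of two POS-tag sequences, normalised as
    max(score, 0) / max(|a|, |b|); 0 when either sequence is empty."""
    if not seq_a or not seq_b:
        return 0.0
    score = needleman_wunsch_score(seq_a, seq_b)
    return max(score, 0.0) / max(len(seq_a), len(seq_b))


def role_pos_tags(sent: ProcessedSentence, role: str) -> tuple[str, ...]:
    """POS tags of the effective words in the given role across clauses,
    concatenated in sentence order."""
    if role not in ("pre_verb", "post_verb"):
        raise ValueError(f"role must be pre_verb or post_verb, got {role!r}")
    indices = []
    for clause in sent.clauses:
        indices.extend(
            i for i in getattr(clause, f"{role}_indices") if i in sent.effective_indices
        )
    return tuple(sent.pos_tags[i] for i in indices)


# --------------------------------------------------------------------------
# synonymy features
# --------------------------------------------------------------------------


def _min_normalised_set_sim(set_a: set, set_b: set, what: str) -> float:
    if not set_a or not set_b:
        if not set_a and not set_b:
            logger.warning("empty %s sets on both sides; similarity 0", what)
        return 0.0
    return len(set_a & set_b) / min(len(set_a), len(set_b))


def wordnet_synonym_similarity(
    sent_a: ProcessedSentence,
    sent_b: ProcessedSentence,
    taxonomy: Taxonomy,
) -> float:
    """Normalised intersection (by the smaller set) of the unions of synset
    ids over each sentence's effective lemmas."""
    sets = []
    for sent in (sent_a, sent_b):
        ids: set[str] = set()
        for lemma in sent.effective_lemmas:
            ids.update(taxonomy.synsets_of(lemma))
        sets.append(ids)
    return _min_normalised_set_sim(sets[0], sets[1], "synset")


def framenet_synonym_similarity(
    sent_a: ProcessedSentence,
    sent_b: ProcessedSentence,
    bundle: LexicalBackendBundle,
) -> float:
    """As above over frame ids, restricted to noun-family effective words."""
    sets = []
    for sent in (sent_a, sent_b):
        frames: set[str] = set()
        for i in sent.effective_indices:
            if _coarse_pos(sent.pos_tags[i]) == "n":
                frames.update(bundle.frames.frames_of(sent.lemmas[i]))
        sets.append(frames)
    return _min_normalised_set_sim(sets[0], sets[1], "frame")


# --------------------------------------------------------------------------
# best-sense features
# --------------------------------------------------------------------------


def best_senses(
    sent: ProcessedSentence, taxonomy: Taxonomy
) -> tuple[SenseAnnotation, ...]:
    """Lesk best sense for every effective word, in sentence order; words
    the taxonomy cannot disambiguate are skipped (logged at DEBUG level)."""
    out = []
    for i in sorted(sent.effective_indices):
        pos = _coarse_pos(sent.pos_tags[i])
        try:
            out.append(best_sense(sent.lemmas[i], sent.tokens, taxonomy, pos=pos))
        except UnknownWordError:
            logger.debug("cannot disambiguate %r; skipped", sent.lemmas[i])
    return tuple(out)


def best_sense_features(
    sent_a: ProcessedSentence,
    sent_b: ProcessedSentence,
    taxonomy: Taxonomy,
) -> tuple[float, float]:
    """(best-sense set similarity, related-synset set similarity), both
    normalised by the smaller set."""
    senses_a = best_senses(sent_a, taxonomy)
    senses_b = best_senses(sent_b, taxonomy)
    enc_a = {s.encode() for s in senses_a}
    enc_b = {s.encode() for s in senses_b}
    sense_sim = _min_normalised_set_sim(enc_a, enc_b, "best-sense")
    rel_a: set[str] = set()
    rel_b: set[str] = set()
    for s in senses_a:
        rel_a.update(taxonomy.related(s.synset_id))
    for s in senses_b:
        rel_b.update(taxonomy.related(s.synset_id))
    related_sim = _min_normalised_set_sim(rel_a, rel_b, "related-synset")
    return sense_sim, related_sim


def sense_category_features(
    sent_a: ProcessedSentence,
    sent_b: ProcessedSentence,
    taxonomy: Taxonomy,
) -> tuple[float, float]:
    """(category set similarity, positional category-vector cosine).

    The cosine variant encodes each sentence as a sequence of one-hot
    category vectors aligned by effective-word position (zero-padded to
    equal length) and takes the Frobenius cosine of the two matrices.
    """
    cats_a = [s.category for s in best_senses(sent_a, taxonomy)]
    cats_b = [s.category for s in best_senses(sent_b, taxonomy)]
    set_sim = _min_normalised_set_sim(set(cats_a), set(cats_b), "category")
    if not cats_a or not cats_b:
        return set_sim, 0.0
    vocab = {c: i for i, c in enumerate(sorted(set(cats_a) | set(cats_b)))}
    n = max(len(cats_a), len(cats_b))
    mat_a = np.zeros((n, len(vocab)))
    mat_b = np.zeros((n, len(vocab)))
    for i, c in enumerate(cats_a):
        mat_a[i, vocab[c]] = 1.0
    for i, c in enumerate(cats_b):
        mat_b[i, vocab[c]] = 1.0
    cos = matrix_cosine(mat_a, mat_b)
    return set_sim, max(0.0, cos)


def sense_skipped_bigram_similarity(
    sent_a: ProcessedSentence,
    sent_b: ProcessedSentence,
    taxonomy: Taxonomy,
) -> float:
    """Skipped bigrams over the best-sense category sequences, intersected
    and normalised by the smaller bigram set."""
    cats_a = [s.category for s in best_senses(sent_a, taxonomy)]
    cats_b = [s.category for s in best_senses(sent_b, taxonomy)]
    if len(cats_a) < 2 and len(cats_b) < 2:
        logger.warning("fewer than 2 categorisable words on both sides; similarity 0")
        return 0.0
    big_a = {(cats_a[i], cats_a[j]) for i in range(len(cats_a)) for j in range(i + 1, len(cats_a))}
    big_b = {(cats_b[i], cats_b[j]) for i in range(len(cats_b)) for j in range(i + 1, len(cats_b))}
    if not big_a or not big_b:
        return 0.0
    return len(big_a & big_b) / min(len(big_a), len(big_b))


# --------------------------------------------------------------------------
# distributional features
# --------------------------------------------------------------------------


def associated_terms_set_similarity(
    sent_a: ProcessedSentence,
    sent_b: ProcessedSentence,
    bundle: LexicalBackendBundle,
    k: int = 20,
) -> float:
    """Union of top-k associated terms over each sentence's effective
    lemmas, intersected and normalised by the larger set."""
    sets = []
    for sent in (sent_a, sent_b):
        assoc: set[str] = set()
        for lemma in sent.effective_lemmas:
            terms = bundle.vectors.associated_terms(lemma, k)
            if not terms:
                logger.debug("no associated terms for %r", lemma)
            assoc.update(terms)
        sets.append(assoc)
    if not sets[0] or not sets[1]:
        return 0.0
    return len(sets[0] & sets[1]) / max(len(sets[0]), len(sets[1]))


def matrix_cosine(mat_a: np.ndarray, mat_b: np.ndarray) -> float:
    """Frobenius cosine of two equal-shape matrices."""
    na = np.linalg.norm(mat_a)
    nb = np.linalg.norm(mat_b)
    if na == 0 or nb == 0:
        logger.warning("all-zero matrix; cosine 0")
        return 0.0
    return float(np.sum(mat_a * mat_b) / (na * nb))


def term_matrix_cosine(
    sent_a: ProcessedSentence,
    sent_b: ProcessedSentence,
    bundle: LexicalBackendBundle,
) -> float:
    """Frobenius cosine of the stacked effective-word term-vector matrices
    (rows in sentence order; the smaller matrix is zero-padded at the
    bottom).  Raw value in [-1, 1]."""
    dim = bundle.vectors.dim
    mats = []
    for sent in (sent_a, sent_b):
        rows = []
        for lemma in sent.effective_lemmas:
            v = bundle.vectors.vector(lemma)
            rows.append(np.zeros(dim) if v is None else v)
        mats.append(np.vstack(rows) if rows else np.zeros((1, dim)))
    n = max(mats[0].shape[0], mats[1].shape[0])
    mats = [np.pad(m, ((0, n - m.shape[0]), (0, 0))) for m in mats]
    return matrix_cosine(mats[0], mats[1])
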