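"""Syntactic similarity measures: bag/set overlaps, window features,
skipped bigrams, polarity and length ratio.

All measures are symmetric in the pair and bounded in [0, 1].  A pair that
is empty on both sides is a corpus-level bug, not a similarity of zero, so
it raises :class:`DegeneratePairError`.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


class DegeneratePairError(ValueError):
    """Both sides of a pair are empty after filtering."""


def bag_overlap(bag_a: Sequence[str], bag_b: Sequence[str]) -> float:
    """Naive overlap: multiset-matched common tokens (each token matched at
    most once) divided by the size of the larger bag."""
    if not bag_a and not bag_b:
        raise DegeneratePairError("both bags empty")
    if not bag_a or not bag_b:
        return 0.0
    shared = sum((Counter(bag_a) & Counter(bag_b)).values())
    return shared / max(len(bag_a), len(bag_b))


def effective_set_similarity(set_a: frozenset | set, set_b: frozenset | set) -> float:
    """Set intersection size over the larger set size."""
    if not set_a and not set_b:
        raise DegeneratePairError("both sets empty")
    if not set_a or not set_b:
        return 0.0
    return len(set(set_a) & set(set_b)) / max(len(set_a), len(set_b))


def jaccard(set_a: frozenset | set, set_b: frozenset | set) -> float:
    """Jaccard similarity |A∩B| / |A∪B|."""
    if not set_a and not set_b:
        raise DegeneratePairError("both sets empty")
    union = set(set_a) | set(set_b)
    return len(set(set_a) & set(set_b)) / len(union)


def lemma_vector_cosine(bag_a: Sequence[str], bag_b: Sequence[str]) -> float:
    """Cosine of term-frequency vectors over the union vocabulary."""
    if not bag_a and not bag_b:
        raise DegeneratePairError("both bags empty")
    ca, cb = Counter(bag_a), Counter(bag_b)
    vocab = sorted(set(ca) | set(cb))
    va = np.array([ca[t] for t in vocab], dtype=float)
    vb = np.array([cb[t] for t in vocab], dtype=float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(va @ vb / (na * nb))


def window_features(
    seq_a: Sequence[str], seq_b: Sequence[str]
) -> tuple[float, float]:
    """Sliding-window overlap over all window sizes k = 2..min(|a|,|b|).

    Returns ``(overlap_norm, longest_norm)``: the count of equal window
    position pairs normalised by C(n, 2) with n = min(|a|,|b|) (capped at
    1, since C(n, 2) is not a strict upper bound on the count), and the
    largest k with at least one equal window divided by n.
    """
    n = min(len(seq_a), len(seq_b))
    if n < 2:
        logger.warning("window features need sequences of length >= 2; returning 0")
        return 0.0, 0.0
    total = 0
    longest = 0
    for k in range(2, n + 1):
        grams_b = {}
        for j in range(len(seq_b) - k + 1):
            grams_b.setdefault(tuple(seq_b[j : j + k]), 0)
            grams_b[tuple(seq_b[j : j + k])] += 1
        found = False
        for i in range(len(seq_a) - k + 1):
            gram = tuple(seq_a[i : i + k])
            if gram in grams_b:
                total += grams_b[gram]
                found = True
        if found:
            longest = k
    overlap_norm = min(1.0, total / math.comb(n, 2))
    return overlap_norm, longest / n


def skipped_bigram_ratio(
    content_a: Sequence[str], content_b: Sequence[str]
) -> float:
    """Shared skipped bigrams over the larger bigram set.

    Skipped bigrams are ordered pairs (w_i, w_j), i < j, over the content
    words (nouns, verbs, adjectives, adverbs) of a sentence.
    """
    if len(content_a) < 2 and len(content_b) < 2:
        logger.warning("fewer than 2 content words on both sides; skipped-bigram ratio 0")
        return 0.0
    bigrams_a = {
        (content_a[i], content_a[j])
        for i in range(len(content_a))
        for j in range(i + 1, len(content_a))
    }
    bigrams_b = {
        (content_b[i], content_b[j])
        for i in range(len(content_b))
        for j in range(i + 1, len(content_b))
    }
    if not bigrams_a or not bigrams_b:
        return 0.0
    return len(bigrams_a & bigrams_b) / max(len(bigrams_a), len(bigrams_b))


def polarity_feature(negated_a: bool, negated_b: bool) -> int:
    """0 if both sentences share polarity, 1 otherwise."""
    return int(bool(negated_a) != bool(negated_b))


def length_ratio(len_a: int, len_b: int) -> float:
    """Smaller token count divided by the larger."""
    if len_a <= 0 or len_b <= 0:
        raise ValueError("sentence lengths must be positive")
    return min(len_a, len_b) / max(len_a, len_b)
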