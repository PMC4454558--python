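"""Structural similarity: clause-count ratio and reduced-parse-tree overlap."""

from __future__ import annotations

import logging
from typing import Sequence

from ..trees import Tree

logger = logging.getLogger(__name__)


def clause_ratio(count_a: int, count_b: int) -> float:
    """min/max of the two clause counts."""
    if count_a <= 0 or count_b <= 0:
        raise ValueError("clause counts must be >= 1")
    return min(count_a, count_b) / max(count_a, count_b)


def _identical_subtree_pairs(clause_a: Tree, clause_b: Tree) -> int:
    """Number of node pairs (u in clause_a, v in clause_b) whose rooted
    subtrees are identical (recursive label-and-child-order equality).
    Subtrees are enumerated at every node, leaves included."""
    subs_b = list(clause_b.subtrees())
    return sum(1 for u in clause_a.subtrees() for v in subs_b if u == v)


def reduced_tree_overlap(
    tree_a: Tree,
    tree_b: Tree,
    clause_word_counts_a: Sequence[int],
    clause_word_counts_b: Sequence[int],
    clip: bool = True,
) -> float:
    """Clause-based identical-subtree overlap of two reduced parse trees.

    For each clause pair the identical-subtree count is divided by the
    product of the clauses' word counts, the terms are summed, and the sum
    is divided by the product of the clause counts.  The word-count
    normaliser does not make the measure 1 on identical sentences and is
    not a strict bound, so by default the raw value is clipped to [0, 1]
    (the raw value is logged at DEBUG level).
    """
    clauses_a = tree_a.children
    clauses_b = tree_b.children
    if not clauses_a or not clauses_b:
        logger.warning("empty reduced tree; overlap 0")
        return 0.0
    if len(clauses_a) != len(clause_word_counts_a) or len(clauses_b) != len(clause_word_counts_b):
        raise ValueError("clause word counts must align with tree clauses")
    total = 0.0
    for ca, wa in zip(clauses_a, clause_word_counts_a):
        for cb, wb in zip(clauses_b, clause_word_counts_b):
            if wa <= 0 or wb <= 0:
                continue
            total += _identical_subtree_pairs(ca, cb) / (wa * wb)
    raw = total / (len(clauses_a) * len(clauses_b))
    logger.debug("reduced tree overlap raw value %.4f", raw)
    return min(1.0, max(0.0, raw)) if clip else raw
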