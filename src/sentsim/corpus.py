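"""Corpus I/O and construction: scored-pair TSV files (SICK dialect),
same-class pair building from rhetorically labelled sentences, seeded
sampling, and the synthetic pair generator used for offline evaluation."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .backends import mini_lexicon_vocabulary

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ("pair_ID", "sentence_A", "sentence_B", "relatedness_score",
                "entailment_judgment")

RHETORICAL_CLASSES = ("Background", "Intervention", "Outcome", "Population",
                      "StudyDesign")

#: Function words interleaved into synthetic sentences; they dilute the
#: naive word overlap exactly the way stopwords do in real sentences.
_FUNCTION_WORDS = ("the", "a", "of", "in", "on", "is", "are", "with", "for", "to")

#: Default shared-content-fraction grid for synthetic pairs.
DEFAULT_OVERLAP_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class ScoredPairRecord:
    pair_id: str
    sentence_a: str
    sentence_b: str
    relatedness: float | None = None
    entailment_label: str | None = None

    def __post_init__(self) -> None:
        if self.relatedness is not None and not (1.0 <= self.relatedness <= 5.0):
            raise ValueError(
                f"pair {self.pair_id}: relatedness {self.relatedness} outside [1, 5]"
            )


@dataclass(frozen=True)
class LabelledSentence:
    text: str
    rhetorical_class: str

    def __post_init__(self) -> None:
        if self.rhetorical_class not in RHETORICAL_CLASSES:
            raise ValueError(
                f"unknown rhetorical class {self.rhetorical_class!r} "
                f"(expected one of {RHETORICAL_CLASSES})"
            )


# --------------------------------------------------------------------------
# TSV I/O (SICK dialect)
# --------------------------------------------------------------------------


def read_pairs(path: str | Path) -> list[ScoredPairRecord]:
    """Read a 5-column SICK-style TSV; malformed lines are reported with
    their line numbers."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PAIR_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        score: float | None = None
        raw = row.get("relatedness_score", "")
        if raw not in ("", "NA"):
            try:
                score = float(raw)
            except ValueError:
                raise ValueError(f"{path} line {lineno}: malformed score {raw!r}")
        label = row.get("entailment_judgment", "") or None
        try:
            records.append(
                ScoredPairRecord(
                    pair_id=row["pair_ID"],
                    sentence_a=row["sentence_A"],
                    sentence_b=row["sentence_B"],
                    relatedness=score,
                    entailment_label=label,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: {exc}") from None
    return records


def write_pairs(records: Iterable[ScoredPairRecord], path: str | Path) -> None:
    rows = [
        {
            "pair_ID": r.pair_id,
            "sentence_A": r.sentence_a,
            "sentence_B": r.sentence_b,
            "relatedness_score": "" if r.relatedness is None else repr(r.relatedness),
            "entailment_judgment": r.entailment_label or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(PAIR_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_labelled_sentences(path: str | Path) -> list[LabelledSentence]:
    """2-column TSV ``text<TAB>class``."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path} line {lineno}: expected 2 tab-separated fields")
        try:
            out.append(LabelledSentence(parts[0], parts[1]))
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: {exc}") from None
    return out


# --------------------------------------------------------------------------
# pair-corpus construction
# --------------------------------------------------------------------------


def count_pairs(n_sentences: int) -> int:
    """Number of unordered same-class pairs, C(n, 2), without materialising
    them (the Outcome class alone yields over 10 million pairs)."""
    if n_sentences < 2:
        raise ValueError("need at least 2 sentences to build pairs")
    return n_sentences * (n_sentences - 1) // 2


def build_pair_corpus(
    sentences: Sequence[LabelledSentence],
    rhetorical_class: str,
) -> Iterator[tuple[str, str]]:
    """Stream all unordered pairs of same-class sentences in deterministic
    order; each pair is canonicalised lexicographically (all similarity
    features are symmetric)."""
    texts = [s.text for s in sentences if s.rhetorical_class == rhetorical_class]
    if len(texts) < 2:
        raise ValueError(
            f"need at least 2 sentences of class {rhetorical_class!r}, got {len(texts)}"
        )
    for a, b in itertools.combinations(texts, 2):
        yield (a, b) if a <= b else (b, a)


def sample_pairs(
    pairs: Sequence[tuple[str, str]], k: int, seed: int
) -> list[tuple[str, str]]:
    """Uniform sample of *k* pairs without replacement, seed-reproducible."""
    if k > len(pairs):
        raise ValueError(f"cannot sample {k} of {len(pairs)} pairs")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=k, replace=False)
    return [pairs[i] for i in sorted(idx)]


# --------------------------------------------------------------------------
# synthetic pairs
# --------------------------------------------------------------------------


def generate_synthetic_pairs(
    n: int,
    overlap_grid: Sequence[float] = DEFAULT_OVERLAP_GRID,
    noise_sd: float = 0.5,
    seed: int = 0,
    vocabulary: Sequence[str] | None = None,
    n_content: int = 8,
    n_function: int = 4,
) -> list[ScoredPairRecord]:
    """Generate scored sentence pairs with controlled lexical overlap.

    Each sentence holds ``n_content`` content words drawn from
    ``vocabulary`` (default: the mini-lexicon's noun and verb lemmas) with
    ``n_function`` function words interspersed at random positions.  For a
    pair with shared-content fraction rho (drawn uniformly from
    ``overlap_grid``), sentence B keeps ``round(rho * n_content)`` of A's
    content words and replaces the rest with words unused by A.  The gold
    score is ``clip(1 + 4*rho + eps, 1, 5)`` with ``eps ~ N(0, noise_sd)``.
    Output is a pure function of the arguments and the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    vocab = tuple(vocabulary) if vocabulary is not None else mini_lexicon_vocabulary()
    if len(vocab) < 2 * n_content:
        raise ValueError("vocabulary too small for disjoint replacement words")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        rho = float(rng.choice(overlap_grid))
        content_a = list(rng.choice(vocab, size=n_content, replace=False))
        n_shared = int(round(rho * n_content))
        shared_idx = rng.choice(n_content, size=n_shared, replace=False)
        shared = [content_a[j] for j in shared_idx]
        remaining = [w for w in vocab if w not in content_a]
        replacements = list(rng.choice(remaining, size=n_content - n_shared, replace=False))
        content_b = shared + replacements
        rng.shuffle(content_b)

        def build(content: list[str]) -> str:
            words = list(content)
            for fw in rng.choice(_FUNCTION_WORDS, size=n_function):
                words.insert(int(rng.integers(0, len(words) + 1)), str(fw))
            return " ".join(words) + "."

        score = float(np.clip(1.0 + 4.0 * rho + rng.normal(0.0, noise_sd), 1.0, 5.0))
        records.append(
            ScoredPairRecord(
                pair_id=f"syn-{i + 1}",
                sentence_a=build(content_a),
                sentence_b=build(content_b),
                relatedness=round(score, 4),
            )
        )
    return records
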