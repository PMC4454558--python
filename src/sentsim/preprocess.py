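"""Rule-based linguistic preprocessing of single English sentences.

Produces every derived layer the similarity features consume: normalised
tokens, lemmas, Porter stems, coarse Penn-style POS tags, effective-word
positions, a NegEx-style negation flag, a clause decomposition into crude
(pre-verb, predicate, post-verb) triples, and a reduced parse tree holding
only the NP/VP scaffold of each clause.

The components here are deliberately lightweight, deterministic rule
systems: a regex tokeniser (lower-cased, punctuation stripped, intra-word
hyphens kept), a closed-class-lexicon + suffix POS tagger, and a
suffix-rule lemmatiser with an irregular-form table.  They are pure
functions of the input text, so identical text always yields an identical
:class:`ProcessedSentence`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .porter import stem as porter_stem
from .trees import Tree

logger = logging.getLogger(__name__)

#: Identifier of the pinned rule resources, echoed in logs for reproducibility.
RESOURCE_MANIFEST = "sentsim-rules/1.0 (regex tokeniser, lexicon+suffix tagger, rule lemmatiser, porter stemmer)"

# --------------------------------------------------------------------------
# closed-class lexicons
# --------------------------------------------------------------------------

DETERMINERS = {
    "a", "an", "the", "this", "that", "these", "those", "each", "every",
    "no", "neither", "either", "some", "any", "all", "both", "another",
}
PREPOSITIONS = {
    "in", "on", "at", "of", "for", "with", "without", "from", "by", "as",
    "into", "onto", "over", "under", "between", "among", "during", "after",
    "before", "about", "against", "through", "within", "across", "toward",
    "towards", "upon", "per", "via", "near", "around", "behind", "beside",
    "above", "below", "off", "than",
}
COORDINATORS = {"and", "but", "or", "nor", "yet", "so"}
SUBORDINATORS = {
    "although", "because", "since", "unless", "while", "whereas", "if",
    "when", "whether", "though", "until",
}
PRONOUNS = {
    "i", "you", "he", "she", "it", "we", "they", "me", "him", "her", "us",
    "them", "my", "your", "his", "its", "our", "their", "mine", "yours",
    "hers", "ours", "theirs", "myself", "yourself", "himself", "herself",
    "itself", "ourselves", "themselves", "who", "whom", "which", "what",
    "whose", "something", "anything", "nothing", "everything", "someone",
    "anyone", "everyone",
}
MODALS = {"will", "would", "can", "could", "may", "might", "must", "shall", "should"}
BE_FORMS = {"am", "is", "are", "was", "were", "be", "been", "being"}
HAVE_FORMS = {"have", "has", "had", "having"}
DO_FORMS = {"do", "does", "did", "done", "doing"}
COMMON_ADVERBS = {
    "not", "n't", "very", "also", "too", "however", "quite", "rather",
    "never", "always", "often", "again", "here", "there", "then", "now",
    "only", "just", "still", "almost", "well",
}
COMMON_ADJECTIVES = {
    "adverse", "relevant", "old", "new", "young", "good", "bad", "high",
    "low", "large", "small", "big", "similar", "several", "many", "few",
    "same", "different", "clinical", "medical", "significant", "such",
    "other", "more", "most", "less", "least", "severe", "mild", "acute",
    "chronic", "main", "common", "present", "absent",
}
#: Open-class verb lemmas recognised by the tagger (beyond be/have/do).
VERB_LEMMAS = {
    "report", "observe", "show", "see", "say", "state", "note", "find",
    "include", "provide", "use", "make", "take", "give", "compare", "treat",
    "cure", "heal", "reduce", "increase", "decrease", "improve", "receive",
    "perform", "conduct", "assess", "measure", "evaluate", "occur", "cause",
    "follow", "play", "run", "walk", "stand", "sit", "look", "eat", "bark",
    "jump", "sleep", "chase", "require", "suggest", "indicate", "remain",
    "appear", "develop", "reveal", "confirm", "record", "happen", "exist",
    "administer", "randomise", "randomize", "enrol", "enroll", "recruit",
}

#: (inflected form -> (lemma, tag)) for irregular verbs and nouns.
IRREGULAR = {
    "was": ("be", "VBD"), "were": ("be", "VBD"), "is": ("be", "VBZ"),
    "am": ("be", "VBP"), "are": ("be", "VBP"), "been": ("be", "VBN"),
    "being": ("be", "VBG"), "be": ("be", "VB"),
    "has": ("have", "VBZ"), "had": ("have", "VBD"), "having": ("have", "VBG"),
    "have": ("have", "VBP"),
    "does": ("do", "VBZ"), "did": ("do", "VBD"), "done": ("do", "VBN"),
    "doing": ("do", "VBG"), "do": ("do", "VBP"),
    "took": ("take", "VBD"), "taken": ("take", "VBN"),
    "gave": ("give", "VBD"), "given": ("give", "VBN"),
    "found": ("find", "VBD"), "saw": ("see", "VBD"), "seen": ("see", "VBN"),
    "went": ("go", "VBD"), "gone": ("go", "VBN"), "got": ("get", "VBD"),
    "said": ("say", "VBD"), "made": ("make", "VBD"), "ran": ("run", "VBD"),
    "shown": ("show", "VBN"), "known": ("know", "VBN"), "knew": ("know", "VBD"),
    "ate": ("eat", "VBD"), "eaten": ("eat", "VBN"), "sat": ("sit", "VBD"),
    "stood": ("stand", "VBD"),
    "men": ("man", "NNS"), "women": ("woman", "NNS"),
    "children": ("child", "NNS"), "feet": ("foot", "NNS"),
    "teeth": ("tooth", "NNS"), "mice": ("mouse", "NNS"),
    "people": ("person", "NNS"), "data": ("datum", "NNS"),
    "criteria": ("criterion", "NNS"),
}

#: NegEx-style negation triggers (single tokens).
NEGATION_TRIGGERS = {
    "no", "not", "n't", "neither", "nor", "without", "never", "none",
    "cannot", "denies", "denied", "deny", "absence", "absent", "unlikely",
    "negative", "fails", "failed",
}

EFFECTIVE_POLICIES = ("content", "nouns_verbs")

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[-'][A-Za-z0-9]+)*")


class EmptySentenceError(ValueError):
    """Raised when a sentence is empty after whitespace trimming."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ClauseTriple:
    """Crude clause decomposition: tokens left of the main verb group, the
    verb group itself, and the remainder.  Index tuples refer to token
    positions in the owning sentence; lemma bags are derived from them."""

    pre_verb_indices: tuple[int, ...]
    predicate_indices: tuple[int, ...]
    post_verb_indices: tuple[int, ...]
    pre_verb: tuple[str, ...]
    predicate: tuple[str, ...]
    post_verb: tuple[str, ...]

    @property
    def indices(self) -> tuple[int, ...]:
        return self.pre_verb_indices + self.predicate_indices + self.post_verb_indices

    @property
    def n_words(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class ProcessedSentence:
    """A sentence with all derived linguistic layers."""

    text: str
    tokens: tuple[str, ...]
    lemmas: tuple[str, ...]
    stems: tuple[str, ...]
    pos_tags: tuple[str, ...]
    effective_indices: frozenset[int]
    effective_policy: str
    negated: bool
    clauses: tuple[ClauseTriple, ...]
    reduced_tree: Tree

    def __post_init__(self) -> None:
        n = len(self.tokens)
        if not (len(self.lemmas) == len(self.stems) == len(self.pos_tags) == n):
            raise ValueError("per-token layers are not aligned")
        if any(i < 0 or i >= n for i in self.effective_indices):
            raise ValueError("effective index out of range")

    @property
    def effective_lemmas(self) -> tuple[str, ...]:
        """Lemmas of effective words, in sentence order."""
        return tuple(self.lemmas[i] for i in sorted(self.effective_indices))

    @property
    def effective_tokens(self) -> tuple[str, ...]:
        return tuple(self.tokens[i] for i in sorted(self.effective_indices))

    def content_indices(self) -> tuple[int, ...]:
        """Positions of content words (nouns, verbs, adjectives, adverbs)."""
        return tuple(
            i
            for i, t in enumerate(self.pos_tags)
            if t.startswith(("NN", "VB", "JJ", "RB")) and self.tokens[i] not in COMMON_ADVERBS
        )


# --------------------------------------------------------------------------
# tokenisation
# --------------------------------------------------------------------------


def tokenize(text: str) -> tuple[str, ...]:
    """Lower-case word tokens; punctuation-only tokens removed; intra-word
    hyphens kept (``M-ADL`` -> ``m-adl``)."""
    if not text or not text.strip():
        raise EmptySentenceError("empty sentence")
    tokens = tuple(m.group(0).lower() for m in _TOKEN_RE.finditer(text))
    if not tokens:
        raise EmptySentenceError("empty sentence (no word tokens)")
    return tokens


# --------------------------------------------------------------------------
# POS tagging
# --------------------------------------------------------------------------


def _verb_tag_for(token: str) -> str | None:
    """Tag if *token* is an inflection of a known open-class verb lemma."""
    if token in VERB_LEMMAS:
        return "VBP"
    for suffix, tag in (("ing", "VBG"), ("ed", "VBD"), ("es", "VBZ"), ("s", "VBZ")):
        if token.endswith(suffix) and len(token) > len(suffix) + 1:
            base = token[: -len(suffix)]
            for candidate in (base, base + "e", base[:-1] if base[-1:] * 2 == base[-2:] else base):
                if candidate in VERB_LEMMAS:
                    return tag
    return None


def pos_tag(tokens: tuple[str, ...]) -> tuple[str, ...]:
    """Coarse Penn-style tags from closed-class lexicons and suffix rules."""
    tags: list[str] = []
    for i, tok in enumerate(tokens):
        if tok in IRREGULAR:
            tags.append(IRREGULAR[tok][1])
            continue
        if re.fullmatch(r"\d+(?:[.,]\d+)*", tok):
            tags.append("CD")
            continue
        if tok in DETERMINERS:
            tags.append("DT")
        elif tok in PRONOUNS:
            tags.append("PRP")
        elif tok in MODALS:
            tags.append("MD")
        elif tok in COORDINATORS:
            tags.append("CC")
        elif tok in SUBORDINATORS:
            tags.append("IN")
        elif tok == "to":
            tags.append("TO")
        elif tok in PREPOSITIONS:
            tags.append("IN")
        elif tok in COMMON_ADVERBS:
            tags.append("RB")
        elif tok in COMMON_ADJECTIVES:
            tags.append("JJ")
        elif (v := _verb_tag_for(tok)) is not None:
            # past participle after an auxiliary chain reads as VBN
            if v == "VBD" and _follows_aux(tags):
                v = "VBN"
            tags.append(v)
        elif tok.endswith("ly") and len(tok) > 3:
            tags.append("RB")
        elif "-" in tok:
            tags.append("JJ")
        elif tok.endswith("ing") and len(tok) > 4:
            tags.append("VBG")
        elif tok.endswith("ed") and len(tok) > 3:
            tags.append("VBN" if _follows_aux(tags) else "VBD")
        elif tok.endswith(
            ("ous", "ive", "al", "ic", "able", "ible", "ant", "ent", "ful",
             "less", "ary", "ory", "ish")
        ) and len(tok) > 4:
            tags.append("JJ")
        elif tok.endswith("s") and not tok.endswith(("ss", "us", "is")) and len(tok) > 2:
            tags.append("NNS")
        else:
            tags.append("NN")
    return tuple(tags)


def _follows_aux(tags: list[str]) -> bool:
    """True if the previous tags end in an auxiliary (be/have) chain,
    possibly with intervening adverbs."""
    for t in reversed(tags):
        if t == "RB":
            continue
        return t in {"VBD", "VBZ", "VBP", "VB", "MD"}
    return False


# --------------------------------------------------------------------------
# lemmatisation
# --------------------------------------------------------------------------


def _strip_plural(token: str) -> str:
    if token.endswith("sses"):
        return token[:-2]
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith(("xes", "ches", "shes", "zes", "oes")):
        return token[:-2]
    if token.endswith("s") and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    return token


def _strip_verb_suffix(token: str, suffix: str) -> str:
    base = token[: -len(suffix)]
    if not base:
        return token
    if base in VERB_LEMMAS:
        return base
    if base + "e" in VERB_LEMMAS:
        return base + "e"
    if len(base) >= 2 and base[-1] == base[-2] and base[-1] not in "aeiouls":
        return base[:-1]  # stopped -> stop
    if base.endswith("i"):
        return base[:-1] + "y"  # tried -> try
    if base.endswith(("v", "c", "z", "u", "rg", "at", "iz", "as")):
        return base + "e"  # observ -> observe, reduc -> reduce
    return base


def lemmatize(tokens: tuple[str, ...], pos_tags: tuple[str, ...]) -> tuple[str, ...]:
    """POS-guided rule lemmatiser; unknown words map to themselves."""
    if len(tokens) != len(pos_tags):
        raise ValueError("tokens and pos_tags must be aligned")
    lemmas: list[str] = []
    for tok, tag in zip(tokens, pos_tags):
        if tok in IRREGULAR:
            lemmas.append(IRREGULAR[tok][0])
        elif tag == "NNS":
            lemmas.append(_strip_plural(tok))
        elif tag in {"VBD", "VBN"} and tok.endswith("ed"):
            lemmas.append(_strip_verb_suffix(tok, "ed"))
        elif tag == "VBG" and tok.endswith("ing"):
            lemmas.append(_strip_verb_suffix(tok, "ing"))
        elif tag == "VBZ" and tok.endswith("s"):
            lemmas.append(_strip_plural(tok))
        else:
            lemmas.append(tok)
    return tuple(lemmas)


def stem_tokens(tokens: tuple[str, ...]) -> tuple[str, ...]:
    return tuple(porter_stem(t) for t in tokens)


# --------------------------------------------------------------------------
# effective words
# --------------------------------------------------------------------------

_CLOSED_TAGS = {"DT", "IN", "CC", "PRP", "MD", "TO", "CD", "EX", "WDT"}


def mark_effective(
    tokens: tuple[str, ...],
    pos_tags: tuple[str, ...],
    policy: str = "content",
) -> frozenset[int]:
    """Positions of effective (content-bearing) words.

    ``content`` (default) drops the closed classes — determiners,
    prepositions, conjunctions, pronouns, modals and the negative particle —
    keeping nouns, verbs, adjectives and adverbs.  ``nouns_verbs`` keeps
    nouns and verbs only (the stricter reading under which adjectives and
    adverbs are not effective).
    """
    if len(tokens) != len(pos_tags):
        raise ValueError("tokens and pos_tags must be aligned")
    if policy not in EFFECTIVE_POLICIES:
        raise ValueError(f"unknown effective-word policy: {policy!r}")
    out = set()
    for i, (tok, tag) in enumerate(zip(tokens, pos_tags)):
        if tok in {"not", "n't"}:
            continue
        if policy == "content":
            if tag not in _CLOSED_TAGS:
                out.add(i)
        else:
            if tag.startswith(("NN", "VB")):
                out.add(i)
    return frozenset(out)


# --------------------------------------------------------------------------
# polarity
# --------------------------------------------------------------------------


def detect_polarity(tokens: tuple[str, ...]) -> bool:
    """NegEx-style sentence-level negation: True iff a negation trigger
    occurs in the token sequence (scope is the whole sentence)."""
    return any(t in NEGATION_TRIGGERS for t in tokens)


# --------------------------------------------------------------------------
# clause decomposition
# --------------------------------------------------------------------------


def _verb_groups(tags: tuple[str, ...], start: int, end: int) -> list[tuple[int, int]]:
    """Maximal verb-group spans [i, j) in tags[start:end]; adverbs may sit
    inside a group but never start or end one."""
    groups: list[tuple[int, int]] = []
    i = start
    while i < end:
        if tags[i].startswith("VB") or tags[i] == "MD":
            j = i + 1
            last_verb = i
            while j < end and (tags[j].startswith("VB") or tags[j] in {"RB", "TO"}):
                if tags[j].startswith("VB"):
                    last_verb = j
                j += 1
            groups.append((i, last_verb + 1))
            i = j
        else:
            i += 1
    return groups


def _has_subject_before_verb(tags: tuple[str, ...], start: int, end: int) -> bool:
    for i in range(start, end):
        if tags[i].startswith("VB") or tags[i] == "MD":
            return False
        if tags[i].startswith("NN") or tags[i] == "PRP":
            return True
    return False


def split_clause_spans(
    tokens: tuple[str, ...], tags: tuple[str, ...]
) -> list[tuple[int, int]]:
    """Split the sentence into clause spans at coordinating conjunctions
    that join two finite-verb clauses (the sentential S nodes of a parse)."""
    n = len(tokens)
    spans: list[tuple[int, int]] = []
    start = 0
    for i in range(n):
        if tags[i] == "CC" and tokens[i] in COORDINATORS:
            left_has_verb = bool(_verb_groups(tags, start, i))
            right_has_verb = bool(_verb_groups(tags, i + 1, n))
            if left_has_verb and right_has_verb and _has_subject_before_verb(tags, i + 1, n):
                spans.append((start, i))
                start = i + 1
    spans.append((start, n))
    return [s for s in spans if s[1] > s[0]]


def parse_clauses(
    tokens: tuple[str, ...],
    tags: tuple[str, ...],
    lemmas: tuple[str, ...],
) -> tuple[ClauseTriple, ...]:
    """One :class:`ClauseTriple` per clause.  The main verb group is the
    first verb group of the clause; tokens to its left form the pre-verb
    component, the rest the post-verb component."""
    triples: list[ClauseTriple] = []
    for start, end in split_clause_spans(tokens, tags):
        groups = _verb_groups(tags, start, end)
        if groups:
            v0, v1 = groups[0]
            pre = tuple(range(start, v0))
            pred = tuple(range(v0, v1))
            post = tuple(range(v1, end))
        else:
            logger.warning("no verb group found; clause fallback with empty predicate: %r",
                           " ".join(tokens[start:end]))
            pre, pred, post = tuple(range(start, end)), (), ()
        triples.append(
            ClauseTriple(
                pre_verb_indices=pre,
                predicate_indices=pred,
                post_verb_indices=post,
                pre_verb=tuple(lemmas[i] for i in pre),
                predicate=tuple(lemmas[i] for i in pred),
                post_verb=tuple(lemmas[i] for i in post),
            )
        )
    return tuple(triples)


# --------------------------------------------------------------------------
# reduced parse tree
# --------------------------------------------------------------------------


def _chunk_labels(tags: tuple[str, ...], indices: tuple[int, ...]) -> list[str]:
    """Collapse a token-index span into a sequence of NP/VP leaf labels."""
    labels: list[str] = []
    current_np = False
    for i in indices:
        tag = tags[i]
        if tag.startswith("VB") or tag == "MD":
            if current_np:
                current_np = False
            if labels and labels[-1] == "VP":
                continue
            labels.append("VP")
        elif tag.startswith(("NN", "PRP")):
            if not current_np:
                labels.append("NP")
                current_np = True
        elif tag in {"DT", "JJ", "CD"}:
            # potential start of an NP; confirmed when a noun follows
            continue
        else:
            current_np = False
    return labels


def reduce_parse_tree(
    tags: tuple[str, ...], clauses: tuple[ClauseTriple, ...]
) -> Tree:
    """Reduced parse tree: a ROOT over one S node per clause whose leaves
    are the major phrase labels (NP/VP) of that clause, in order."""
    clause_nodes = []
    for clause in clauses:
        leaves = [Tree(lbl) for lbl in _chunk_labels(tags, clause.indices)]
        clause_nodes.append(Tree("S", tuple(leaves)))
    return Tree("ROOT", tuple(clause_nodes))


# --------------------------------------------------------------------------
# top-level pipeline
# --------------------------------------------------------------------------


def process(text: str, effective_policy: str = "content") -> ProcessedSentence:
    """Run the full preprocessing pipeline on one sentence."""
    tokens = tokenize(text)
    tags = pos_tag(tokens)
    lemmas = lemmatize(tokens, tags)
    stems = stem_tokens(tokens)
    effective = mark_effective(tokens, tags, policy=effective_policy)
    clauses = parse_clauses(tokens, tags, lemmas)
    tree = reduce_parse_tree(tags, clauses)
    return ProcessedSentence(
        text=text,
        tokens=tokens,
        lemmas=lemmas,
        stems=stems,
        pos_tags=tags,
        effective_indices=effective,
        effective_policy=effective_policy,
        negated=detect_polarity(tokens),
        clauses=clauses,
        reduced_tree=tree,
    )
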