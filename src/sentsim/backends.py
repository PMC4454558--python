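"""Lexical knowledge backends: taxonomy+IC, frame lexicon, term vectors.

Three uniform contracts back the semantic features:

* :class:`Taxonomy` — a WordNet-style synset graph with information-content
  (IC) values, depths, lexicographer-file categories, glosses and related
  synsets; supports Lin and Wu-Palmer similarity and Lesk best-sense
  disambiguation.
* :class:`FrameLexicon` — a FrameNet-style lemma -> frame-set map.
* :class:`VectorSpace` — a fixed-dimension distributional term-vector
  store (HAL-style) with top-k associated terms.

:func:`build_mini_lexicon` constructs a small deterministic offline bundle
covering a clinical-trial flavoured vocabulary, used both as the default
backend for tests/simulations and as the reference fixture.  File loaders
(:func:`load_backends`) accept simple text formats: a JSON taxonomy dump,
a TSV IC table, a TSV frame lexicon, and a word2vec-style text vector
store.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)


class UnknownSynsetError(KeyError):
    pass


class UnknownWordError(KeyError):
    pass


# --------------------------------------------------------------------------
# taxonomy backend
# --------------------------------------------------------------------------


@dataclass
class Synset:
    id: str
    pos: str                      # "n" or "v"
    lemmas: tuple[str, ...]
    parent: str | None            # hypernym id, None for the root
    category: str                 # lexicographer-file name
    gloss: tuple[str, ...]        # token bag
    ic: float


@dataclass(frozen=True)
class SenseAnnotation:
    """A disambiguated word sense, encodable as ``lemma#pos#rank``."""

    word: str
    pos: str
    sense_rank: int               # 1-based
    synset_id: str
    category: str

    def encode(self) -> str:
        return f"{self.word}#{self.pos}#{self.sense_rank}"


class Taxonomy:
    """IS-A taxonomy with IC values.

    ``synsets`` maps id -> :class:`Synset`; lemma senses are ordered by
    their position in each synset's registration order (sense rank 1 =
    first registered synset for the lemma).
    """

    def __init__(self, synsets: list[Synset]):
        self._synsets: dict[str, Synset] = {}
        self._lemma_index: dict[tuple[str, str], list[str]] = {}
        self._children: dict[str, list[str]] = {}
        for s in synsets:
            if s.id in self._synsets:
                raise ValueError(f"duplicate synset id {s.id!r}")
            self._synsets[s.id] = s
        for s in synsets:
            if s.parent is not None:
                if s.parent not in self._synsets:
                    raise ValueError(f"unknown parent {s.parent!r} of {s.id!r}")
                self._children.setdefault(s.parent, []).append(s.id)
            for lemma in s.lemmas:
                self._lemma_index.setdefault((lemma, s.pos), []).append(s.id)
        self._depth: dict[str, int] = {}
        for s in synsets:
            self._depth[s.id] = len(self._ancestors(s.id))  # root depth 1

    # -- basic lookups ----------------------------------------------------

    def __contains__(self, synset_id: str) -> bool:
        return synset_id in self._synsets

    def _get(self, synset_id: str) -> Synset:
        try:
            return self._synsets[synset_id]
        except KeyError:
            raise UnknownSynsetError(synset_id) from None

    def all_synsets(self) -> list[Synset]:
        return list(self._synsets.values())

    def synsets_of(self, lemma: str, pos: str | None = None) -> list[str]:
        """Synset ids of *lemma*, ordered by sense rank."""
        if pos is not None:
            return list(self._lemma_index.get((lemma, pos), []))
        out = []
        for p in ("n", "v"):
            out.extend(self._lemma_index.get((lemma, p), []))
        return out

    def ic(self, synset_id: str) -> float:
        return self._get(synset_id).ic

    def depth(self, synset_id: str) -> int:
        self._get(synset_id)
        return self._depth[synset_id]

    def category(self, synset_id: str) -> str:
        return self._get(synset_id).category

    def gloss(self, synset_id: str) -> tuple[str, ...]:
        return self._get(synset_id).gloss

    def _ancestors(self, synset_id: str) -> list[str]:
        """Path from *synset_id* to the root, inclusive."""
        path = [synset_id]
        seen = {synset_id}
        node = self._synsets[synset_id]
        while node.parent is not None:
            if node.parent in seen:
                raise ValueError(f"cycle at {node.parent!r}")
            path.append(node.parent)
            seen.add(node.parent)
            node = self._synsets[node.parent]
        return path

    def lcs(self, s1: str, s2: str) -> str:
        """Least common subsumer (deepest shared ancestor)."""
        a1 = self._ancestors(self._get(s1).id)
        a2 = set(self._ancestors(self._get(s2).id))
        for node in a1:  # a1 runs leaf -> root, so first hit is deepest
            if node in a2:
                return node
        raise ValueError(f"{s1!r} and {s2!r} share no ancestor")

    def related(self, synset_id: str) -> frozenset[str]:
        """Synsets linked by semantic pointers: hypernym, hyponyms and
        siblings (co-hyponyms)."""
        s = self._get(synset_id)
        out: set[str] = set(self._children.get(synset_id, []))
        if s.parent is not None:
            out.add(s.parent)
            out.update(c for c in self._children.get(s.parent, []) if c != synset_id)
        return frozenset(out)

    # -- invariant check (used by tests and loaders) ----------------------

    def validate(self) -> None:
        roots = [s for s in self._synsets.values() if s.parent is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        for s in self._synsets.values():
            if s.parent is not None and s.ic < self._synsets[s.parent].ic:
                raise ValueError(
                    f"IC not monotone along hypernym path at {s.id!r}"
                )
            if s.ic < 0:
                raise ValueError(f"negative IC at {s.id!r}")


def lin_similarity(s1: str, s2: str, taxonomy: Taxonomy) -> float:
    """Lin similarity 2*IC(lcs)/(IC(s1)+IC(s2)); 0 when the denominator
    vanishes (both synsets at the uninformative root)."""
    lcs = taxonomy.lcs(s1, s2)
    denom = taxonomy.ic(s1) + taxonomy.ic(s2)
    if denom <= 0:
        return 0.0
    return 2.0 * taxonomy.ic(lcs) / denom


def wu_palmer_similarity(s1: str, s2: str, taxonomy: Taxonomy) -> float:
    """Wu-Palmer similarity 2*depth(lcs)/(depth(s1)+depth(s2))."""
    lcs = taxonomy.lcs(s1, s2)
    return 2.0 * taxonomy.depth(lcs) / (taxonomy.depth(s1) + taxonomy.depth(s2))


def best_sense(
    word: str,
    context: tuple[str, ...],
    taxonomy: Taxonomy,
    pos: str | None = None,
) -> SenseAnnotation:
    """Lesk disambiguation: the sense whose gloss shares the most tokens
    with the sentence context; ties break toward the lowest sense rank."""
    synset_ids = taxonomy.synsets_of(word, pos)
    if not synset_ids:
        raise UnknownWordError(word)
    context_set = set(context) - {word}
    best_rank, best_overlap = 1, -1
    for rank, sid in enumerate(synset_ids, start=1):
        overlap = len(context_set & set(taxonomy.gloss(sid)))
        if overlap > best_overlap:
            best_rank, best_overlap = rank, overlap
    sid = synset_ids[best_rank - 1]
    syn = taxonomy._get(sid)
    return SenseAnnotation(
        word=word, pos=syn.pos, sense_rank=best_rank,
        synset_id=sid, category=syn.category,
    )


# --------------------------------------------------------------------------
# frame backend
# --------------------------------------------------------------------------


class FrameLexicon:
    """Lemma -> set of frame ids (FrameNet-style)."""

    def __init__(self, mapping: dict[str, frozenset[str]]):
        self._mapping = {k: frozenset(v) for k, v in mapping.items()}

    def frames_of(self, lemma: str) -> frozenset[str]:
        return self._mapping.get(lemma, frozenset())

    def lemmas(self) -> list[str]:
        return sorted(self._mapping)


# --------------------------------------------------------------------------
# distributional backend
# --------------------------------------------------------------------------


class VectorSpace:
    """Fixed-dimension term vectors with cosine-nearest associated terms."""

    def __init__(self, vectors: dict[str, np.ndarray]):
        dims = {len(v) for v in vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent vector dimensions: {sorted(dims)}")
        self.dim = dims.pop() if dims else 0
        self._vectors = {t: np.asarray(v, dtype=float) for t, v in vectors.items()}
        self._terms = sorted(self._vectors)

    def __contains__(self, term: str) -> bool:
        return term in self._vectors

    def terms(self) -> list[str]:
        return list(self._terms)

    def vector(self, term: str) -> np.ndarray | None:
        return self._vectors.get(term)

    def associated_terms(self, term: str, k: int = 20) -> frozenset[str]:
        """Top-*k* cosine neighbours of *term* (excluding itself); empty
        for out-of-vocabulary terms."""
        v = self._vectors.get(term)
        if v is None:
            return frozenset()
        nv = np.linalg.norm(v)
        if nv == 0:
            return frozenset()
        sims = []
        for other in self._terms:
            if other == term:
                continue
            w = self._vectors[other]
            nw = np.linalg.norm(w)
            if nw == 0:
                continue
            sims.append((float(v @ w / (nv * nw)), other))
        sims.sort(key=lambda x: (-x[0], x[1]))
        return frozenset(t for _, t in sims[:k])


@dataclass
class LexicalBackendBundle:
    """Handle holding the three knowledge interfaces."""

    taxonomy: Taxonomy
    frames: FrameLexicon
    vectors: VectorSpace
    manifest: str = "unversioned"


# --------------------------------------------------------------------------
# deterministic mini-lexicon
# --------------------------------------------------------------------------

# (id, pos, lemmas, parent, category, gloss)
_MINI_TAXONOMY: list[tuple[str, str, tuple[str, ...], str | None, str, str]] = [
    ("entity.n.01", "n", ("entity",), None, "noun.Tops",
     "that which is perceived to have its own existence"),
    ("event.n.01", "n", ("event",), "entity.n.01", "noun.event",
     "something that happens at a given place and time"),
    ("outcome.n.01", "n", ("outcome", "result"), "event.n.01", "noun.event",
     "a phenomenon that follows and is caused by some previous phenomenon"),
    ("complication.n.01", "n", ("complication",), "event.n.01", "noun.event",
     "any disease or disorder that occurs during the course of another disease"),
    ("infection.n.01", "n", ("infection",), "complication.n.01", "noun.state",
     "the invasion of the body by pathogenic germs causing disease"),
    ("disturbance.n.01", "n", ("disturbance",), "complication.n.01", "noun.event",
     "an unwanted change that interferes with normal function"),
    ("retention.n.01", "n", ("retention",), "event.n.01", "noun.event",
     "the abnormal holding of urine or fluid within the body"),
    ("state.n.01", "n", ("state", "condition"), "entity.n.01", "noun.state",
     "the way something is with respect to its main attributes"),
    ("wound.n.01", "n", ("wound", "injury"), "state.n.01", "noun.state",
     "damage to the body caused by physical harm"),
    ("disease.n.01", "n", ("disease", "illness"), "state.n.01", "noun.state",
     "an impairment of health or a condition of abnormal functioning"),
    ("object.n.01", "n", ("object",), "entity.n.01", "noun.Tops",
     "a tangible and visible thing"),
    ("organism.n.01", "n", ("organism",), "object.n.01", "noun.Tops",
     "a living thing that can act or function independently"),
    ("animal.n.01", "n", ("animal",), "organism.n.01", "noun.animal",
     "a living organism that feeds on organic matter"),
    ("dog.n.01", "n", ("dog",), "animal.n.01", "noun.animal",
     "a domesticated animal that barks and is kept as a pet"),
    ("cat.n.01", "n", ("cat",), "animal.n.01", "noun.animal",
     "a small domesticated animal with soft fur kept as a pet"),
    ("person.n.01", "n", ("person",), "organism.n.01", "noun.person",
     "a human being"),
    ("patient.n.01", "n", ("patient", "subject"), "person.n.01", "noun.person",
     "a person who receives medical treatment or care"),
    ("doctor.n.01", "n", ("doctor", "clinician"), "person.n.01", "noun.person",
     "a person licensed to practice medicine and treat disease"),
    ("artifact.n.01", "n", ("artifact",), "object.n.01", "noun.artifact",
     "a man-made object"),
    ("drug.n.01", "n", ("drug", "medication"), "artifact.n.01", "noun.artifact",
     "a substance used in the treatment or prevention of disease"),
    ("placebo.n.01", "n", ("placebo",), "drug.n.01", "noun.artifact",
     "an inactive substance given in the control arm of a trial"),
    ("device.n.01", "n", ("device", "instrument"), "artifact.n.01", "noun.artifact",
     "an instrument invented for a particular medical purpose"),
    ("group.n.01", "n", ("group", "cohort"), "entity.n.01", "noun.group",
     "a number of people or things considered together as a unit"),
    # a second, less common sense of "subject" (topic) for Lesk tests
    ("subject.n.02", "n", ("subject", "topic"), "entity.n.01", "noun.communication",
     "the topic that a sentence or study is about"),
    # a second sense of "event": social occasion
    ("event.n.02", "n", ("event", "occasion"), "entity.n.01", "noun.act",
     "a social occasion such as a party or ceremony with guests"),
]

_MINI_FRAMES: dict[str, tuple[str, ...]] = {
    # verbs
    "report": ("Statement",), "say": ("Statement",), "state": ("Statement",),
    "note": ("Statement", "Perception"),
    "observe": ("Perception", "Observation"), "see": ("Perception",),
    "watch": ("Perception",),
    "treat": ("Cure",), "cure": ("Cure",), "heal": ("Cure",),
    "improve": ("Change",), "increase": ("Change",), "reduce": ("Change",),
    "decrease": ("Change",),
    "be": ("Existence",), "exist": ("Existence",),
    "occur": ("Event",), "happen": ("Event",),
    "play": ("Performance",), "run": ("Motion",), "walk": ("Motion",),
    "stand": ("Posture",), "sit": ("Posture",),
    # nouns (used by the noun-family frame-synonymy feature)
    "infection": ("Medical_condition",), "disease": ("Medical_condition",),
    "illness": ("Medical_condition",), "wound": ("Medical_condition",),
    "injury": ("Medical_condition",),
    "patient": ("People",), "doctor": ("People",), "person": ("People",),
    "drug": ("Medicine",), "medication": ("Medicine",), "placebo": ("Medicine",),
    "event": ("Event",), "outcome": ("Event",), "result": ("Event",),
    "group": ("Aggregate",), "cohort": ("Aggregate",),
    "dog": ("Animals",), "cat": ("Animals",), "animal": ("Animals",),
}

_EXTRA_VECTOR_TERMS = (
    "therapy", "surgery", "trial", "study", "hospital", "nurse",
    "symptom", "fever", "pain", "recovery", "yard", "man", "kid",
)


def build_mini_lexicon(seed: int = 0) -> LexicalBackendBundle:
    """Deterministic offline backend bundle.

    The taxonomy topology, lemma inventory, categories and glosses are
    fixed; the seed controls the IC jitter and the distributional vectors.
    Identical seeds yield identical bundles.
    """
    rng = np.random.default_rng(seed)

    # IC: accumulate positive edge increments root->leaf so IC is monotone
    # non-decreasing with depth (root IC = 0, i.e. uninformative).
    ic: dict[str, float] = {}
    synsets: list[Synset] = []
    for sid, pos, lemmas, parent, category, gloss in _MINI_TAXONOMY:
        base = 0.0 if parent is None else ic[parent]
        ic[sid] = base if parent is None else base + 1.0 + 0.5 * rng.random()
        synsets.append(
            Synset(
                id=sid, pos=pos, lemmas=lemmas, parent=parent,
                category=category,
                gloss=tuple(gloss.lower().split()),
                ic=round(ic[sid], 4),
            )
        )
    taxonomy = Taxonomy(synsets)
    taxonomy.validate()

    frames = FrameLexicon({k: frozenset(v) for k, v in _MINI_FRAMES.items()})

    # Distributional space: one base direction per top-level branch plus
    # per-term noise, so taxonomic neighbours are distributional neighbours.
    dim = 8
    branch_of: dict[str, str] = {}
    for s in synsets:
        node = s
        while node.parent is not None and node.parent != "entity.n.01":
            node = taxonomy._get(node.parent)
        branch_of[s.id] = node.id
    branches = sorted(set(branch_of.values()) | {"_verbs", "_misc"})
    base_vec = {b: rng.normal(0.0, 1.0, dim) for b in branches}

    vectors: dict[str, np.ndarray] = {}
    for s in synsets:
        for lemma in s.lemmas:
            if lemma not in vectors:
                vectors[lemma] = base_vec[branch_of[s.id]] + 0.3 * rng.normal(0.0, 1.0, dim)
    for lemma in sorted(set(_MINI_FRAMES) - set(vectors)):
        vectors[lemma] = base_vec["_verbs"] + 0.3 * rng.normal(0.0, 1.0, dim)
    for term in _EXTRA_VECTOR_TERMS:
        if term not in vectors:
            vectors[term] = base_vec["_misc"] + 0.5 * rng.normal(0.0, 1.0, dim)

    bundle = LexicalBackendBundle(
        taxonomy=taxonomy,
        frames=frames,
        vectors=VectorSpace(vectors),
        manifest=f"mini-lexicon/seed={seed}",
    )
    logger.info("built %s: %d synsets, %d frame lemmas, %d vector terms (dim %d)",
                bundle.manifest, len(synsets), len(_MINI_FRAMES),
                len(vectors), dim)
    return bundle


#: Sorted content vocabulary (noun + verb lemmas) of the mini-lexicon;
#: used by the synthetic pair generator.
def mini_lexicon_vocabulary() -> tuple[str, ...]:
    nouns = sorted({l for _, _, lemmas, _, _, _ in _MINI_TAXONOMY for l in lemmas})
    verbs = sorted(_MINI_FRAMES)
    return tuple(sorted(set(nouns) | set(verbs)))


# --------------------------------------------------------------------------
# file loaders / writers
# --------------------------------------------------------------------------


def save_backends(bundle: LexicalBackendBundle, directory: str | Path) -> None:
    """Write a bundle as plain-text resources (JSON taxonomy, TSV IC table,
    TSV frame lexicon, word2vec-style text vectors)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tax = [
        {
            "id": s.id, "pos": s.pos, "lemmas": list(s.lemmas),
            "parent": s.parent, "category": s.category,
            "gloss": " ".join(s.gloss),
        }
        for s in bundle.taxonomy.all_synsets()
    ]
    (directory / "taxonomy.json").write_text(json.dumps(tax, indent=1))
    with open(directory / "ic.tsv", "w") as fh:
        for s in bundle.taxonomy.all_synsets():
            fh.write(f"{s.id}\t{s.ic}\n")
    with open(directory / "frames.tsv", "w") as fh:
        for lemma in bundle.frames.lemmas():
            for frame in sorted(bundle.frames.frames_of(lemma)):
                fh.write(f"{lemma}\t{frame}\n")
    with open(directory / "vectors.txt", "w") as fh:
        terms = bundle.vectors.terms()
        fh.write(f"{len(terms)} {bundle.vectors.dim}\n")
        for term in terms:
            vals = " ".join(f"{x:.6f}" for x in bundle.vectors.vector(term))
            fh.write(f"{term} {vals}\n")


def load_backends(directory: str | Path) -> LexicalBackendBundle:
    """Load a bundle written by :func:`save_backends` (or hand-authored in
    the same formats).  Raises specific errors on missing files, malformed
    records or dimension mismatches."""
    directory = Path(directory)
    for name in ("taxonomy.json", "ic.tsv", "frames.tsv", "vectors.txt"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"missing backend resource: {directory / name}")

    ic: dict[str, float] = {}
    for lineno, line in enumerate((directory / "ic.tsv").read_text().splitlines(), 1):
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"ic.tsv line {lineno}: expected 2 fields, got {len(parts)}")
        try:
            ic[parts[0]] = float(parts[1])
        except ValueError:
            raise ValueError(f"ic.tsv line {lineno}: malformed IC value {parts[1]!r}")

    raw = json.loads((directory / "taxonomy.json").read_text())
    synsets = []
    for rec in raw:
        if rec["id"] not in ic:
            raise ValueError(f"synset {rec['id']!r} has no IC entry")
        synsets.append(
            Synset(
                id=rec["id"], pos=rec["pos"], lemmas=tuple(rec["lemmas"]),
                parent=rec["parent"], category=rec["category"],
                gloss=tuple(rec["gloss"].split()), ic=ic[rec["id"]],
            )
        )
    taxonomy = Taxonomy(synsets)
    taxonomy.validate()

    frames_map: dict[str, set[str]] = {}
    for lineno, line in enumerate((directory / "frames.tsv").read_text().splitlines(), 1):
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"frames.tsv line {lineno}: expected 2 fields")
        frames_map.setdefault(parts[0], set()).add(parts[1])
    frames = FrameLexicon({k: frozenset(v) for k, v in frames_map.items()})

    lines = (directory / "vectors.txt").read_text().splitlines()
    if not lines:
        raise ValueError("vectors.txt is empty")
    header = lines[0].split()
    if len(header) != 2:
        raise ValueError("vectors.txt: malformed header")
    n_terms, dim = int(header[0]), int(header[1])
    vectors: dict[str, np.ndarray] = {}
    for lineno, line in enumerate(lines[1:], 2):
        parts = line.split()
        if len(parts) != dim + 1:
            raise ValueError(
                f"vectors.txt line {lineno}: dimension mismatch "
                f"(expected {dim}, got {len(parts) - 1})"
            )
        vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    if len(vectors) != n_terms:
        raise ValueError(
            f"vectors.txt: header declares {n_terms} terms, found {len(vectors)}"
        )

    bundle = LexicalBackendBundle(
        taxonomy=taxonomy, frames=frames, vectors=VectorSpace(vectors),
        manifest=f"loaded:{directory}",
    )
    logger.info("loaded backends from %s (%d synsets, dim %d)",
                directory, len(synsets), dim)
    return bundle
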