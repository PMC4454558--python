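"""Taxonomy/frames/vector backends, Lin & Wu-Palmer, Lesk, mini-lexicon."""

import numpy as np
import pytest

from sentsim.backends import (
    FrameLexicon,
    Synset,
    Taxonomy,
    UnknownSynsetError,
    UnknownWordError,
    best_sense,
    build_mini_lexicon,
    lin_similarity,
    load_backends,
    save_backends,
    wu_palmer_similarity,
)


@pytest.fixture(scope="module")
def chain_taxonomy():
    """root(ic 0) -> parent(ic 1) -> {a, b}(ic 2)."""
    return Taxonomy(
        [
            Synset("root", "n", ("thing",), None, "noun.Tops", ("any", "thing"), 0.0),
            Synset("parent", "n", ("kind",), "root", "noun.Tops", ("a", "kind"), 1.0),
            Synset("a", "n", ("alpha",), "parent", "noun.Tops", ("first", "kind"), 2.0),
            Synset("b", "n", ("beta",), "parent", "noun.Tops", ("second", "kind"), 2.0),
        ]
    )


class TestLinSimilarity:
    def test_fixture_value(self, chain_taxonomy):
        # 2*IC(parent) / (IC(a)+IC(b)) = 2*1/4
        assert lin_similarity("a", "b", chain_taxonomy) == pytest.approx(0.5)

    def test_self_similarity_one(self, chain_taxonomy):
        assert lin_similarity("a", "a", chain_taxonomy) == 1.0

    def test_root_lcs_gives_zero(self, chain_taxonomy):
        # siblings whose only shared ancestor is the zero-IC root
        tax = Taxonomy(
            [
                Synset("root", "n", ("t",), None, "c", (), 0.0),
                Synset("x", "n", ("x",), "root", "c", (), 2.0),
                Synset("y", "n", ("y",), "root", "c", (), 2.0),
            ]
        )
        assert lin_similarity("x", "y", tax) == 0.0

    def test_unknown_synset_raises(self, chain_taxonomy):
        with pytest.raises(UnknownSynsetError):
            lin_similarity("a", "nope", chain_taxonomy)


class TestWuPalmer:
    def test_self_one(self, chain_taxonomy):
        assert wu_palmer_similarity("b", "b", chain_taxonomy) == 1.0

    def test_chain_fixture(self, chain_taxonomy):
        # depths: parent=2, a=b=3 -> 2*2/6
        assert wu_palmer_similarity("a", "b", chain_taxonomy) == pytest.approx(2 / 3)

    def test_siblings_under_root(self):
        # lcs depth 1, both terms depth 2 -> 2*1/4
        tax = Taxonomy(
            [
                Synset("root", "n", ("t",), None, "c", (), 0.0),
                Synset("x", "n", ("x",), "root", "c", (), 1.0),
                Synset("y", "n", ("y",), "root", "c", (), 1.0),
            ]
        )
        assert wu_palmer_similarity("x", "y", tax) == pytest.approx(0.5)

    def test_symmetry(self, chain_taxonomy):
        assert wu_palmer_similarity("a", "b", chain_taxonomy) == wu_palmer_similarity(
            "b", "a", chain_taxonomy
        )
        assert chain_taxonomy.lcs("a", "b") == chain_taxonomy.lcs("b", "a")


class TestBestSense:
    def test_gloss_overlap_picks_engineered_sense(self, bundle):
        # "subject" sense 1 = trial participant, sense 2 = topic
        context = ("the", "subject", "of", "the", "sentence", "is", "a", "topic")
        ann = best_sense("subject", context, bundle.taxonomy, pos="n")
        assert ann.synset_id == "subject.n.02"
        assert ann.encode() == "subject#n#2"

    def test_medical_context_picks_patient_sense(self, bundle):
        context = ("the", "subject", "received", "medical", "treatment")
        ann = best_sense("subject", context, bundle.taxonomy, pos="n")
        assert ann.synset_id == "patient.n.01"
        assert ann.sense_rank == 1

    def test_single_sense_word(self, bundle):
        ann = best_sense("infection", ("a", "b"), bundle.taxonomy, pos="n")
        assert ann.synset_id == "infection.n.01"

    def test_tie_breaks_to_lowest_rank(self, bundle):
        # no gloss overlap at all: both senses score 0 -> rank 1 wins
        ann = best_sense("event", ("zzz",), bundle.taxonomy, pos="n")
        assert ann.sense_rank == 1

    def test_unknown_word_raises(self, bundle):
        with pytest.raises(UnknownWordError):
            best_sense("qwertyuiop", ("a",), bundle.taxonomy)


class TestMiniLexicon:
    def test_same_seed_identical(self):
        b1, b2 = build_mini_lexicon(7), build_mini_lexicon(7)
        assert [s.ic for s in b1.taxonomy.all_synsets()] == [
            s.ic for s in b2.taxonomy.all_synsets()
        ]
        for t in b1.vectors.terms():
            assert np.array_equal(b1.vectors.vector(t), b2.vectors.vector(t))

    def test_different_seeds_differ(self):
        b1, b2 = build_mini_lexicon(1), build_mini_lexicon(2)
        assert not np.array_equal(b1.vectors.vector("dog"), b2.vectors.vector("dog"))

    def test_size_and_structure_contract(self, bundle):
        synsets = bundle.taxonomy.all_synsets()
        assert len(synsets) >= 20
        assert max(bundle.taxonomy.depth(s.id) for s in synsets) >= 3
        assert len({s.category for s in synsets}) >= 5
        assert len(bundle.frames.lemmas()) >= 10
        assert len({f for l in bundle.frames.lemmas() for f in bundle.frames.frames_of(l)}) >= 4
        assert len(bundle.vectors.terms()) >= 30
        assert bundle.vectors.dim == 8

    def test_taxonomy_invariants_hold(self, bundle):
        bundle.taxonomy.validate()  # IC monotone, single root
        # lcs symmetric over a sample of synset pairs
        ids = [s.id for s in bundle.taxonomy.all_synsets()][:8]
        for s1 in ids:
            for s2 in ids:
                assert bundle.taxonomy.lcs(s1, s2) == bundle.taxonomy.lcs(s2, s1)

    def test_related_synsets_are_semantic_neighbours(self, bundle):
        rel = bundle.taxonomy.related("dog.n.01")
        assert "animal.n.01" in rel  # hypernym
        assert "cat.n.01" in rel     # sibling


class TestVectorSpace:
    def test_associated_terms_exclude_self(self, bundle):
        assert "dog" not in bundle.vectors.associated_terms("dog", 5)

    def test_taxonomic_neighbours_are_distributional_neighbours(self, bundle):
        assert "cat" in bundle.vectors.associated_terms("dog", 10)

    def test_oov_term_has_no_neighbours(self, bundle):
        assert bundle.vectors.associated_terms("qwerty", 5) == frozenset()


class TestFileRoundTrip:
    def test_save_load_identity(self, bundle, tmp_path):
        save_backends(bundle, tmp_path)
        loaded = load_backends(tmp_path)
        assert {s.id for s in loaded.taxonomy.all_synsets()} == {
            s.id for s in bundle.taxonomy.all_synsets()
        }
        assert loaded.taxonomy.ic("dog.n.01") == bundle.taxonomy.ic("dog.n.01")
        assert loaded.frames.frames_of("report") == bundle.frames.frames_of("report")
        assert loaded.vectors.dim == bundle.vectors.dim
        np.testing.assert_allclose(
            loaded.vectors.vector("dog"), bundle.vectors.vector("dog"), atol=1e-6
        )

    def test_missing_file_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_backends(tmp_path)

    def test_dimension_mismatch_error(self, bundle, tmp_path):
        save_backends(bundle, tmp_path)
        lines = (tmp_path / "vectors.txt").read_text().splitlines()
        lines[1] = lines[1].rsplit(" ", 1)[0]  # drop one component
        (tmp_path / "vectors.txt").write_text("\n".join(lines))
        with pytest.raises(ValueError, match="dimension mismatch"):
            load_backends(tmp_path)


class TestFrameLexicon:
    def test_lookup_and_miss(self):
        lex = FrameLexicon({"report": frozenset({"Statement"})})
        assert lex.frames_of("report") == {"Statement"}
        assert lex.frames_of("zzz") == frozenset()
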