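"""Title-keyword extraction, the MeSH-TK matrix, and both correlation modes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import pair_cooccurrence_brute
from meshnet.corpus_io import Corpus, MeshHeading, PublicationRecord
from meshnet.similarity import (
    MeshTkMatrix,
    build_mesh_tk_matrix,
    cooccurrence_matrix,
    corpus_keywords,
    cosine_similarity,
    extract_keywords,
    similarity_matrix,
    stopwords_sha256,
)

# Frozen checksum of the versioned stopword list: results are only
# comparable across runs if the list is byte-identical.
STOPWORDS_SHA256 = "24c0bf9c36171ca6691235276f8e8d0555506da8950d0d82c7788c936c29b1e5"


class TestKeywordExtraction:
    def test_unigrams_plus_noun_phrase(self):
        assert extract_keywords("The Tumor Microenvironment in Cancer") == {
            "tumor", "microenvironment", "cancer", "tumor microenvironment"
        }

    def test_all_stopwords_gives_empty_set(self):
        assert extract_keywords("of the in") == set()

    def test_repeated_word_counts_once(self):
        kws = extract_keywords("cancer and cancer")
        assert kws == {"cancer"}

    def test_punctuation_stripped_and_lowercased(self):
        kws = extract_keywords("T-Cells, Regulatory: a Review!")
        assert "regulatory" in kws and "review" in kws
        assert all(kw == kw.lower() for kw in kws)

    def test_empty_title_rejected(self):
        with pytest.raises(ValueError):
            extract_keywords("")

    def test_stopword_list_is_versioned(self):
        assert stopwords_sha256() == STOPWORDS_SHA256


TOY_TN = Corpus([
    PublicationRecord("1", "checkpoint blockade in melanoma", 2016,
                      (MeshHeading("M1"),)),
    PublicationRecord("2", "checkpoint inhibitor therapy", 2016,
                      (MeshHeading("M1"), MeshHeading("M2"))),
    PublicationRecord("3", "stromal fibroblast signaling", 2015,
                      (MeshHeading("M2"),)),
])


class TestMeshTkMatrix:
    def test_toy_matrix_cell_by_cell(self):
        # exhaustive manual count over the 3-publication toy corpus
        mtx = build_mesh_tk_matrix(TOY_TN, ["M1", "M2"])
        expected = {
            # keyword: (C(kw|M1), C(kw|M2))
            "checkpoint": (2, 1),
            "blockade": (1, 0),
            "melanoma": (1, 0),
            "checkpoint blockade": (1, 0),
            "inhibitor": (1, 1),
            "therapy": (1, 1),
            "checkpoint inhibitor therapy": (1, 1),
            "stromal": (0, 1),
            "fibroblast": (0, 1),
            "signaling": (0, 1),
            "stromal fibroblast signaling": (0, 1),
        }
        assert set(mtx.keywords) == set(expected)
        for kw, (c1, c2) in expected.items():
            j = mtx.keywords.index(kw)
            assert mtx.counts[0, j] == c1, kw
            assert mtx.counts[1, j] == c2, kw

    def test_k_spans_supplied_whole_set_vocabulary(self):
        vocabulary = corpus_keywords(TOY_TN) | {"keyword absent from tn"}
        mtx = build_mesh_tk_matrix(TOY_TN, ["M1"], vocabulary)
        assert mtx.k == len(vocabulary)
        j = mtx.keywords.index("keyword absent from tn")
        assert mtx.counts[0, j] == 0

    def test_term_without_publications_keeps_zero_row_with_warning(self):
        with pytest.warns(UserWarning, match="empty title-keyword profiles"):
            mtx = build_mesh_tk_matrix(TOY_TN, ["M1", "Absent"])
        assert not mtx.vector("Absent").any()


class TestCosine:
    def test_self_similarity_is_one(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors_are_zero(self):
        assert cosine_similarity(np.array([1, 0]), np.array([0, 1])) == 0.0

    def test_hand_computed_value(self):
        assert cosine_similarity(np.array([1, 2, 0]), np.array([2, 1, 0])) == pytest.approx(0.8)

    def test_zero_vector_convention(self):
        assert cosine_similarity(np.zeros(3), np.array([1, 2, 3])) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            cosine_similarity(np.ones(2), np.ones(3))


class TestSimilarityMatrix:
    def test_identical_rows_give_offdiagonal_one(self):
        mtx = MeshTkMatrix(("a", "b"), ("k1", "k2"), np.array([[2, 1], [2, 1]]))
        sim = similarity_matrix(mtx)
        assert sim.value("a", "b") == pytest.approx(1.0)

    def test_orthogonal_rows_give_zero(self):
        mtx = MeshTkMatrix(("a", "b"), ("k1", "k2"), np.array([[3, 0], [0, 5]]))
        assert similarity_matrix(mtx).value("a", "b") == 0.0

    def test_matches_pairwise_cosine_recomputation(self):
        mtx = build_mesh_tk_matrix(TOY_TN, ["M1", "M2"])
        sim = similarity_matrix(mtx)
        assert sim.value("M1", "M2") == pytest.approx(
            cosine_similarity(mtx.vector("M1"), mtx.vector("M2"))
        )

    @given(
        counts=st.lists(
            st.lists(st.integers(0, 9), min_size=4, max_size=4),
            min_size=2, max_size=6,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_cauchy_schwarz_bound(self, counts):
        terms = tuple(f"m{i}" for i in range(len(counts)))
        mtx = MeshTkMatrix(terms, ("a", "b", "c", "d"), np.array(counts))
        sim = similarity_matrix(mtx)
        assert np.allclose(sim.values, sim.values.T, atol=1e-12)
        assert sim.values.min() >= 0.0 and sim.values.max() <= 1.0
        nonzero = np.array(counts).any(axis=1)
        assert np.allclose(np.diagonal(sim.values)[nonzero], 1.0)


class TestCooccurrenceBaseline:
    def test_disjoint_supports_give_zero(self):
        sim = cooccurrence_matrix(TOY_TN, ["blank1", "blank2"])
        assert sim.value("blank1", "blank2") == 0.0

    def test_single_shared_publication_counts_one(self):
        sim = cooccurrence_matrix(TOY_TN, ["M1", "M2"])
        assert sim.value("M1", "M2") == 1.0
        assert sim.mode == "cooccurrence"

    def test_agrees_with_per_publication_pair_enumeration(self, planted):
        corpus, truth = planted
        terms = sorted(truth.trajectories)
        sim = cooccurrence_matrix(corpus, terms)
        brute = pair_cooccurrence_brute(corpus, terms)
        for i, a in enumerate(terms):
            for b in terms[i + 1:]:
                assert sim.value(a, b) == brute.get((a, b), 0)


class TestClusterSeparation:
    def test_intra_cluster_similarity_exceeds_inter_at_zero_noise(self, planted):
        corpus, truth = planted
        final = corpus.restrict_years(2014, 2016)
        emerging = sorted(truth.emerging_terms)
        mtx = build_mesh_tk_matrix(final, emerging, corpus_keywords(corpus))
        sim = similarity_matrix(mtx)
        intra, inter = [], []
        for i, a in enumerate(emerging):
            for b in emerging[i + 1:]:
                value = sim.value(a, b)
                same = truth.cluster_of[a] == truth.cluster_of[b]
                (intra if same else inter).append(value)
        assert min(intra) > max(inter)
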