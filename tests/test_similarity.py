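import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pscluster.similarity import (
    Document,
    SimilarityMatrix,
    journal_distance,
    load_corpus,
    similarity_matrix,
    tanimoto,
    tfidf_vectors,
    vector_distance,
)


def doc(i, abstract="", journal="j", keywords=(), title=""):
    return Document(
        id=f"d{i}", title=title, abstract=abstract, journal=journal,
        keywords=frozenset(keywords),
    )


class TestTfidf:
    def test_term_in_every_document_gets_zero_weight(self):
        corpus = [doc(0, "shared alpha"), doc(1, "shared beta")]
        vecs = tfidf_vectors(corpus)
        assert "shared" not in vecs["d0"] and "shared" not in vecs["d1"]

    def test_exclusive_max_frequency_term_scores_one(self):
        # term only in doc 0 at max frequency: TF=1, IDF=log2(2/1)=1
        corpus = [doc(0, "unique"), doc(1, "other")]
        vecs = tfidf_vectors(corpus)
        assert vecs["d0"]["unique"] == pytest.approx(1.0)

    def test_max_normalised_tf(self):
        # 'gamma' appears 2x, 'delta' 1x in doc 0; both absent from doc 1
        corpus = [doc(0, "gamma gamma delta"), doc(1, "filler")]
        vecs = tfidf_vectors(corpus)
        assert vecs["d0"]["delta"] == pytest.approx(0.5 * vecs["d0"]["gamma"] / 1.0)

    def test_empty_document_yields_zero_vector(self, caplog):
        corpus = [doc(0, ""), doc(1, "words here")]
        vecs = tfidf_vectors(corpus)
        assert vecs["d0"] == {}

    def test_stopwords_removed_and_punctuation_stripped(self):
        corpus = [doc(0, "The cell, the CELL!"), doc(1, "protein")]
        vecs = tfidf_vectors(corpus)
        assert set(vecs["d0"]) == {"cell"}

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            tfidf_vectors([])


class TestVectorDistance:
    def test_identical_vectors_distance_zero(self):
        v = {"x": 1.0, "y": 2.0}
        assert vector_distance(v, v) == pytest.approx(0.0)

    def test_disjoint_supports_cosine_distance_one(self):
        assert vector_distance({"x": 1.0}, {"y": 1.0}) == pytest.approx(1.0)

    def test_cosine_45_degrees(self):
        d = vector_distance({"x": 1.0}, {"x": 1.0, "y": 1.0})
        assert d == pytest.approx(1 - 1 / math.sqrt(2))

    def test_zero_vector_maximally_dissimilar(self):
        assert vector_distance({}, {"x": 1.0}) == 1.0

    def test_euclidean(self):
        d = vector_distance({"x": 3.0}, {"y": 4.0}, norm="euclidean")
        assert d == pytest.approx(5.0)


class TestTanimoto:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"A", "B"}, {"A", "B"}, 1.0),
            ({"A"}, {"B"}, 0.0),
            ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),
            (set(), set(), 1.0),
            (set(), {"A"}, 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert tanimoto(a, b) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.sets(st.sampled_from("ABCDEFGH"), min_size=1),
        st.sets(st.sampled_from("ABCDEFGH"), min_size=1),
        st.sampled_from("XY"),
    )
    def test_adding_shared_keyword_never_decreases(self, a, b, extra):
        # the union grows by at most 1 when the same new keyword joins both
        before = tanimoto(a, b)
        after = tanimoto(a | {extra}, b | {extra})
        assert after >= before


class TestJournalDistance:
    def test_same_journal(self):
        assert journal_distance(doc(0, journal="Cell"), doc(1, journal="cell")) == 0

    def test_different_journals(self):
        assert journal_distance(doc(0, journal="A"), doc(1, journal="B")) == 1

    def test_missing_journal(self):
        assert journal_distance(doc(0, journal=""), doc(1, journal="B")) == 1


class TestSimilarityMatrix:
    def test_identical_abstracts_d2_similarity_one(self):
        corpus = [doc(0, "same words here"), doc(1, "same words here"),
                  doc(2, "totally different content")]
        m = similarity_matrix(corpus, measure="d2")
        assert m.get("d0", "d1") == pytest.approx(1.0)

    def test_d1_halves_journal_penalty(self):
        corpus = [doc(0, "same words", journal="A"), doc(1, "same words", journal="B"),
                  doc(2, "unrelated content", journal="A")]
        m = similarity_matrix(corpus, measure="d1")
        # identical abstracts (d_V = 0) in different journals: sim = 1 - 1/2
        assert m.get("d0", "d1") == pytest.approx(0.5)

    def test_d3_matches_tanimoto_elementwise(self):
        corpus = [doc(0, keywords={"A", "B"}), doc(1, keywords={"B", "C"}),
                  doc(2, keywords={"C"})]
        m = similarity_matrix(corpus, measure="d3")
        for a in corpus:
            for b in corpus:
                assert m.get(a.id, b.id) == pytest.approx(
                    tanimoto(a.keywords, b.keywords)
                )

    def test_symmetric_and_in_unit_range(self, topic_corpus):
        for measure in ("d1", "d2", "d3"):
            m = similarity_matrix(topic_corpus, measure=measure)
            assert np.array_equal(m.values, m.values.T)
            assert m.values.min() >= 0.0 and m.values.max() <= 1.0

    def test_singleton_corpus_rejected(self):
        with pytest.raises(ValueError, match="nothing to compare"):
            similarity_matrix([doc(0)], measure="d2")

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            SimilarityMatrix(["a", "b"], np.array([[1.0, 0.2], [0.3, 1.0]]))

    def test_tsv_dump(self, tmp_path, two_block_matrix):
        out = tmp_path / "sim.tsv"
        two_block_matrix.to_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t")[1:] == two_block_matrix.ids
        assert len(lines) == 9


class TestCorpusIO:
    def test_jsonl_roundtrip(self, tmp_path):
        path = tmp_path / "corpus.jsonl"
        records = [
            {"id": "a", "title": "T", "abstract": "body", "journal": "J",
             "year": 1999, "keywords": ["K1", "K2"]},
            {"id": "b", "title": "U", "abstract": "", "journal": "J2",
             "year": 2001, "keywords": []},
        ]
        path.write_text("\n".join(json.dumps(r) for r in records))
        docs = load_corpus(path)
        assert [d.id for d in docs] == ["a", "b"]
        assert docs[0].keywords == frozenset({"K1", "K2"})
        assert docs[1].year == 2001

    def test_csv_with_pipe_keywords(self, tmp_path):
        path = tmp_path / "corpus.csv"
        path.write_text(
            "id,title,abstract,journal,year,keywords\n"
            "a,T,body,J,1999,K1|K2\n"
            "b,U,more text,J2,2001,\n"
        )
        docs = load_corpus(path)
        assert docs[0].keywords == frozenset({"K1", "K2"})
        assert docs[1].keywords == frozenset()

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "corpus.jsonl"
        path.write_text('{"id": "a"}\n{"id": "a"}\n')
        with pytest.raises(ValueError, match="duplicate"):
            load_corpus(path)
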