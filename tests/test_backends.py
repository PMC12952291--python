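"""Similarity backends: word overlap, BM25 (lucene variant), hashed TF-IDF,
chunking, chunk-mean embedding, and the external-vector adapter."""

import io
import math
import string

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geosift import (
    ChunkingConfig,
    CleaningPolicy,
    CorpusStats,
    HashedTfidfEmbedder,
    bm25_score,
    build_bm25_index,
    chunk_text,
    embed_document,
    hashed_tfidf_embed,
    load_external_vectors,
    word_overlap_similarity,
)
from geosift.backends import DEFAULT_B, DEFAULT_K1, write_external_vectors

from conftest import make_doc


class TestWordOverlap:
    def test_identity(self):
        d = make_doc("a", "parkinson disease brain")
        assert word_overlap_similarity(d, d) == 1.0

    def test_disjoint(self):
        a = make_doc("a", "parkinson disease")
        b = make_doc("b", "neuroblastoma tumor")
        assert word_overlap_similarity(a, b) == 0.0

    def test_hand_worked_example(self):
        a = make_doc("a", "parkinson disease brain cortex")
        b = make_doc("b", "parkinson disease blood")
        assert word_overlap_similarity(a, b) == pytest.approx(2 / 5)

    def test_empty_union_is_zero(self):
        a = make_doc("a", "")
        assert word_overlap_similarity(a, a) == 0.0

    @given(
        st.lists(st.text(alphabet="abcde", min_size=1, max_size=3), max_size=8),
        st.lists(st.text(alphabet="abcde", min_size=1, max_size=3), max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_one_iff_equal_sets(self, ta, tb):
        a = make_doc("a", " ".join(ta))
        b = make_doc("b", " ".join(tb))
        s = word_overlap_similarity(a, b)
        assert s == word_overlap_similarity(b, a)
        assert 0.0 <= s <= 1.0
        if a.unique_tokens() or b.unique_tokens():
            assert (s == 1.0) == (a.unique_tokens() == b.unique_tokens())


class TestBm25Index:
    def test_one_token_documents(self):
        docs = [make_doc(i, t) for i, t in zip("xyz", ["a", "a", "b"])]
        idx = build_bm25_index(docs)
        assert idx.doc_frequencies == {"a": 2, "b": 1}
        assert idx.avg_doc_length == 1.0

    def test_singleton_corpus_mean(self):
        idx = build_bm25_index([make_doc("x", "one two three")])
        assert idx.avg_doc_length == 3.0

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_bm25_index([])

    def test_mode_policy_mismatch(self):
        plain = make_doc("x", "running studies")
        with pytest.raises(ValueError, match="incompatible"):
            build_bm25_index([plain], mode="plus")
        stemmed = make_doc("y", "running studies",
                           CleaningPolicy(remove_stopwords=True, stem=True))
        with pytest.raises(ValueError, match="incompatible"):
            build_bm25_index([stemmed], mode="default")


class TestBm25Score:
    def test_absent_query_tokens_score_zero(self):
        idx = build_bm25_index([make_doc("x", "alpha beta")])
        assert bm25_score(idx, ["gamma", "delta"], "x") == 0.0

    def test_singleton_closed_form(self):
        idx = build_bm25_index([make_doc("x", "alpha")])
        # idf = ln(1 + 0.5/1.5); tf = 1/(1 + k1*(1 - b + b*1/1)) = 1/(1+k1)
        expected = math.log(1 + 0.5 / 1.5) / (1 + DEFAULT_K1)
        assert bm25_score(idx, ["alpha"], "x") == pytest.approx(expected, abs=1e-12)

    def test_unknown_doc_id(self):
        idx = build_bm25_index([make_doc("x", "alpha")])
        with pytest.raises(KeyError, match="nope"):
            bm25_score(idx, ["alpha"], "nope")

    def test_additive_over_query_tokens(self):
        docs = [make_doc(i, t) for i, t in
                zip("abc", ["alpha beta beta", "beta gamma", "alpha gamma gamma"])]
        idx = build_bm25_index(docs)
        q1, q2 = ["alpha"], ["beta", "gamma"]
        s_both = bm25_score(idx, q1 + q2, "a")
        assert s_both == pytest.approx(
            bm25_score(idx, q1, "a") + bm25_score(idx, q2, "a"), abs=1e-12
        )
        # dropping a query token never increases the score
        assert bm25_score(idx, q1, "a") <= s_both + 1e-12


class TestHashedTfidf:
    def stats(self, docs):
        return CorpusStats.from_documents(docs)

    def test_empty_document_is_zero_vector(self):
        doc = make_doc("x", "")
        vec = hashed_tfidf_embed(doc, 64, self.stats([doc]))
        assert vec.is_zero and vec.dim == 64

    def test_deterministic_byte_identical(self):
        docs = [make_doc("x", "parkinson brain tissue expression")]
        a = hashed_tfidf_embed(docs[0], 128, self.stats(docs))
        b = hashed_tfidf_embed(docs[0], 128, self.stats(docs))
        assert a.values.tobytes() == b.values.tobytes()

    def test_unit_norm_when_nonzero(self):
        # two documents so df < N and the idf weights are nonzero
        docs = [make_doc("x", "some tokens here"), make_doc("y", "other words")]
        vec = hashed_tfidf_embed(docs[0], 64, self.stats(docs))
        assert np.linalg.norm(vec.values) == pytest.approx(1.0)

    def test_singleton_corpus_gives_zero_idf(self):
        # every token then appears in every document: no discriminative mass
        doc = make_doc("x", "some tokens here")
        assert hashed_tfidf_embed(doc, 64, self.stats([doc])).is_zero

    def test_minimum_dimension_enforced(self):
        doc = make_doc("x", "a")
        with pytest.raises(ValueError, match="16"):
            hashed_tfidf_embed(doc, 8, self.stats([doc]))

    def test_disjoint_documents_nearly_orthogonal(self):
        # brute-force over seeded token sets: at dim 256, 10-token documents
        # sharing no tokens are nearly orthogonal.  Signed-hash collisions
        # can stack, so |cos| < 0.2 holds for the bulk of draws rather than
        # every draw; the mean sits near zero.
        rng = np.random.default_rng(42)
        letters = list(string.ascii_lowercase)
        coss = []
        for _ in range(500):
            words = ["".join(rng.choice(letters, 6)) for _ in range(20)]
            a = make_doc("a", " ".join(words[:10]))
            b = make_doc("b", " ".join(words[10:]))
            stats = self.stats([a, b])
            va = hashed_tfidf_embed(a, 256, stats)
            vb = hashed_tfidf_embed(b, 256, stats)
            coss.append(abs(float(va.values @ vb.values)))
        coss = np.asarray(coss)
        assert coss.mean() < 0.1
        assert (coss < 0.2).mean() >= 0.95


class TestChunkText:
    CFG = ChunkingConfig(enabled=True)

    def test_below_threshold_single_chunk(self):
        text = "x" * 200
        assert chunk_text(text, self.CFG) == [text]

    def test_stride_arithmetic(self):
        text = "".join(chr(97 + i % 26) for i in range(500))
        chunks = chunk_text(text, self.CFG)
        assert chunks == [text[0:256], text[236:492], text[472:500]]

    def test_empty_text(self):
        assert chunk_text("", self.CFG) == [""]

    def test_disabled_config_rejected(self):
        with pytest.raises(ValueError, match="enabled"):
            chunk_text("x", ChunkingConfig(enabled=False))

    @given(st.integers(min_value=0, max_value=2000), st.integers(min_value=0))
    @settings(max_examples=300, deadline=None)
    def test_round_trip(self, length, seed):
        rng = np.random.default_rng(seed)
        text = "".join(rng.choice(list(string.ascii_letters + " "), size=length))
        chunks = chunk_text(text, self.CFG)
        rebuilt = chunks[0] + "".join(c[self.CFG.overlap_chars:] for c in chunks[1:])
        assert rebuilt == text

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ChunkingConfig(overlap_chars=256, chunk_size_chars=256)
        with pytest.raises(ValueError):
            ChunkingConfig(enabled=True, threshold_chars=512, chunk_size_chars=256)


class TestEmbedDocument:
    class ConstantBackend:
        backend_id = "const"

        def __init__(self, mapping):
            self.mapping = mapping

        def embed(self, text):
            return np.array(self.mapping[text], dtype=float)

    def test_single_chunk_equals_backend_vector(self):
        doc = make_doc("x", "short text")
        backend = self.ConstantBackend({doc.text: [1.0, 2.0]})
        vec = embed_document(backend, doc, ChunkingConfig(enabled=True))
        assert vec.values.tolist() == [1.0, 2.0]

    def test_mean_of_two_chunks(self):
        text = "a" * 300
        cfg = ChunkingConfig(enabled=True, threshold_chars=256,
                             overlap_chars=20, chunk_size_chars=256)
        chunks = chunk_text(text, cfg)
        backend = self.ConstantBackend({chunks[0]: [1.0, 0.0], chunks[1]: [0.0, 1.0]})
        doc = make_doc("x", text)
        vec = embed_document(backend, doc, cfg)
        assert vec.values.tolist() == [0.5, 0.5]

    def test_inconsistent_dims_rejected(self):
        text = "b" * 300
        cfg = ChunkingConfig(enabled=True)
        chunks = chunk_text(text, cfg)
        backend = self.ConstantBackend({chunks[0]: [1.0, 0.0], chunks[1]: [1.0]})
        with pytest.raises(ValueError, match="inconsistent"):
            embed_document(backend, make_doc("x", text), cfg)

    def test_chunked_hashed_tfidf_runs(self):
        doc = make_doc("x", "alpha beta " * 40)
        stats = CorpusStats.from_documents([doc])
        backend = HashedTfidfEmbedder(stats=stats, dim=64)
        vec = embed_document(backend, doc, ChunkingConfig(enabled=True))
        assert vec.dim == 64 and not vec.is_zero


class TestExternalVectors:
    TABLE = "#backend_id=toy\tdim=3\nGSE1\t1.0\t0.0\t0.5\nGSE2\t0.0\t1.0\t-0.5\n"

    def test_shape_and_backend_id(self):
        vectors = load_external_vectors(io.StringIO(self.TABLE))
        assert len(vectors) == 2
        assert all(v.dim == 3 for v in vectors)
        assert {v.backend_id for v in vectors} == {"external:toy"}

    def test_ragged_row_names_row(self):
        bad = "#backend_id=toy\tdim=3\nGSE1\t1.0\t0.0\n"
        with pytest.raises(ValueError, match="row 1"):
            load_external_vectors(io.StringIO(bad))

    def test_non_numeric_field(self):
        bad = "#backend_id=toy\tdim=2\nGSE1\t1.0\tabc\n"
        with pytest.raises(ValueError, match="row 1"):
            load_external_vectors(io.StringIO(bad))

    def test_round_trip(self):
        vectors = load_external_vectors(io.StringIO(self.TABLE))
        buf = io.StringIO()
        write_external_vectors(vectors, buf, "toy")
        again = load_external_vectors(io.StringIO(buf.getvalue()))
        for v, w in zip(vectors, again):
            assert v.accession == w.accession
            assert np.array_equal(v.values, w.values)
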