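"""Document representations and similarities.

Four backend families are provided:

* ``word_overlap`` — Jaccard similarity of unique-token sets.
* ``bm25`` / ``bm25plus`` — the lucene variant of BM25; ``bm25plus``
  additionally expects stop words removed and Porter stemming applied.
* ``hashed_tfidf`` — a deterministic signed-hash TF-IDF embedder, a
  fixed-dimension vector backend that makes cosine retrieval testable
  offline without any neural model.
* ``external:<id>`` — precomputed vectors loaded from a TSV table,
  the adapter contract for neural embedding backends.

Long texts can be split into overlapping character chunks whose per-chunk
vectors are averaged (mean pooling).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Protocol, Sequence

import numpy as np

from .records import CleanDocument

#: Built-in backend identifiers; external backends use the "external:<id>" form.
BACKEND_IDS = ("word_overlap", "bm25", "bm25plus", "hashed_tfidf")

DEFAULT_K1 = 1.5
DEFAULT_B = 0.75


@dataclass(frozen=True)
class EmbeddingVector:
    """Fixed-length numeric representation of one document under one backend."""

    accession: str
    values: np.ndarray
    backend_id: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 1:
            raise ValueError("embedding values must be one-dimensional")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite embedding values for {self.accession!r}")
        object.__setattr__(self, "values", arr)

    @property
    def dim(self) -> int:
        return int(self.values.shape[0])

    @property
    def is_zero(self) -> bool:
        return not np.any(self.values)


@dataclass(frozen=True)
class ChunkingConfig:
    """Character-window chunking: texts longer than ``threshold_chars`` are
    split into ``chunk_size_chars`` windows overlapping by ``overlap_chars``."""

    enabled: bool = False
    threshold_chars: int = 256
    overlap_chars: int = 20
    chunk_size_chars: int = 256

    def __post_init__(self) -> None:
        if self.threshold_chars <= 0 or self.chunk_size_chars <= 0:
            raise ValueError("chunk threshold and size must be positive")
        if self.overlap_chars < 0 or self.overlap_chars >= self.chunk_size_chars:
            raise ValueError("overlap_chars must be in [0, chunk_size_chars)")
        if self.enabled and self.threshold_chars > self.chunk_size_chars:
            raise ValueError(
                "threshold_chars may not exceed chunk_size_chars when chunking "
                "is enabled (texts between the two would escape chunking)"
            )

    def to_dict(self) -> dict:
        return {
            "enabled": self.enabled,
            "threshold_chars": self.threshold_chars,
            "overlap_chars": self.overlap_chars,
            "chunk_size_chars": self.chunk_size_chars,
        }


def word_overlap_similarity(a: CleanDocument, b: CleanDocument) -> float:
    """Jaccard index of the two documents' unique-token sets.

    The proportion of the words spanning both documents that occur in each:
    ``|A ∩ B| / |A ∪ B|``, with 0 for an empty union.
    """
    sa, sb = a.unique_tokens(), b.unique_tokens()
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union


@dataclass
class Bm25Index:
    """Corpus statistics for BM25 scoring (lucene variant)."""

    doc_ids: list[str]
    doc_lengths: dict[str, int]
    avg_doc_length: float
    doc_frequencies: dict[str, int]
    term_frequencies: dict[str, Counter]
    k1: float = DEFAULT_K1
    b: float = DEFAULT_B
    mode: str = "default"


def build_bm25_index(
    corpus: Sequence[CleanDocument],
    k1: float = DEFAULT_K1,
    b: float = DEFAULT_B,
    mode: str = "default",
) -> Bm25Index:
    """Build an inverted-frequency index over ``corpus``.

    ``mode="plus"`` requires documents cleaned with stop-word removal and
    stemming; ``mode="default"`` requires both unset (mirroring the two ways
    the ranking function is applied).
    """
    if not corpus:
        raise ValueError("cannot build a BM25 index over an empty corpus")
    if mode not in ("default", "plus"):
        raise ValueError(f"unknown BM25 mode {mode!r}")
    if k1 <= 0:
        raise ValueError("k1 must be positive")
    if not 0.0 <= b <= 1.0:
        raise ValueError("b must lie in [0, 1]")
    for doc in corpus:
        wants = mode == "plus"
        if doc.policy.remove_stopwords != wants or doc.policy.stem != wants:
            raise ValueError(
                f"document {doc.accession!r} cleaned with "
                f"remove_stopwords={doc.policy.remove_stopwords}, "
                f"stem={doc.policy.stem}; incompatible with mode {mode!r}"
            )
    doc_ids = [d.accession for d in corpus]
    term_frequencies = {d.accession: Counter(d.tokens) for d in corpus}
    doc_lengths = {d.accession: len(d.tokens) for d in corpus}
    doc_frequencies: Counter = Counter()
    for d in corpus:
        doc_frequencies.update(d.unique_tokens())
    return Bm25Index(
        doc_ids=doc_ids,
        doc_lengths=doc_lengths,
        avg_doc_length=sum(doc_lengths.values()) / len(doc_lengths),
        doc_frequencies=dict(doc_frequencies),
        term_frequencies=term_frequencies,
        k1=k1,
        b=b,
        mode=mode,
    )


def bm25_score(index: Bm25Index, query_tokens: Sequence[str], doc_id: str) -> float:
    """Lucene-variant BM25 score of one document for a bag of query tokens.

    score(q, d) = sum_t idf(t) * f(t,d) / (f(t,d) + k1 * (1 - b + b*|d|/avgdl))
    with idf(t) = ln(1 + (N - df(t) + 0.5) / (df(t) + 0.5)).  Query tokens
    absent from the corpus contribute zero.
    """
    if doc_id not in index.term_frequencies:
        raise KeyError(f"unknown document {doc_id!r}")
    tf = index.term_frequencies[doc_id]
    n_docs = len(index.doc_ids)
    norm = index.k1 * (
        1.0 - index.b + index.b * index.doc_lengths[doc_id] / index.avg_doc_length
    )
    score = 0.0
    for t in query_tokens:
        f = tf.get(t, 0)
        if f == 0:
            continue
        df = index.doc_frequencies[t]
        idf = math.log(1.0 + (n_docs - df + 0.5) / (df + 0.5))
        score += idf * f / (f + norm)
    return score


@dataclass(frozen=True)
class CorpusStats:
    """Document frequencies over a candidate corpus, for TF-IDF weighting."""

    doc_frequencies: Mapping[str, int]
    n_docs: int

    @classmethod
    def from_documents(cls, docs: Iterable[CleanDocument]) -> "CorpusStats":
        df: Counter = Counter()
        n = 0
        for d in docs:
            df.update(d.unique_tokens())
            n += 1
        return cls(doc_frequencies=dict(df), n_docs=n)


_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = (1 << 64) - 1


def _fnv1a64(token: str) -> int:
    """FNV-1a 64-bit hash; fixed constants, platform-independent."""
    h = _FNV_OFFSET
    for byte in token.encode("utf-8"):
        h = ((h ^ byte) * _FNV_PRIME) & _MASK64
    return h


def _hashed_tfidf_values(
    tokens: Sequence[str], dim: int, stats: CorpusStats
) -> np.ndarray:
    vec = np.zeros(dim, dtype=np.float64)
    if not tokens:
        return vec
    counts = Counter(tokens)
    n = stats.n_docs
    for token, tf in counts.items():
        h = _fnv1a64(token)
        bucket = h % dim
        sign = 1.0 if (h >> 63) & 1 == 0 else -1.0
        df = stats.doc_frequencies.get(token, 0)
        vec[bucket] += sign * tf * math.log((n + 1.0) / (df + 1.0))
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return vec


def hashed_tfidf_embed(
    doc: CleanDocument, dim: int, corpus_stats: CorpusStats
) -> EmbeddingVector:
    """Deterministic signed-hash TF-IDF embedding of one document.

    Each token hashes to a bucket in ``[0, dim)`` with a sign bit; buckets
    accumulate ``tf * ln((N+1)/(df+1))`` and the vector is L2-normalised
    unless all-zero.  Byte-identical across runs and platforms.
    """
    if dim < 16:
        raise ValueError("dim must be at least 16")
    values = _hashed_tfidf_values(doc.tokens, dim, corpus_stats)
    return EmbeddingVector(accession=doc.accession, values=values, backend_id="hashed_tfidf")


def chunk_text(text: str, config: ChunkingConfig) -> list[str]:
    """Split ``text`` into overlapping character windows.

    Texts no longer than ``threshold_chars`` come back as a single chunk.
    Otherwise windows of ``chunk_size_chars`` advance by
    ``chunk_size_chars - overlap_chars``; the last window may be shorter.
    Dropping the first ``overlap_chars`` characters of every chunk after the
    first and concatenating reconstructs the input exactly.
    """
    if not config.enabled:
        raise ValueError("chunk_text requires an enabled ChunkingConfig")
    if len(text) <= config.threshold_chars:
        return [text]
    stride = config.chunk_size_chars - config.overlap_chars
    chunks = []
    i = 0
    while True:
        chunks.append(text[i : i + config.chunk_size_chars])
        if i + config.chunk_size_chars >= len(text):
            break
        i += stride
    return chunks


class TextEmbedder(Protocol):
    """Anything that maps a text to a fixed-dimension vector."""

    backend_id: str

    def embed(self, text: str) -> np.ndarray: ...


@dataclass
class HashedTfidfEmbedder:
    """Callable backend wrapping the signed-hash TF-IDF representation."""

    stats: CorpusStats
    dim: int = 256
    backend_id: str = "hashed_tfidf"

    def __post_init__(self) -> None:
        if self.dim < 16:
            raise ValueError("dim must be at least 16")

    def embed(self, text: str) -> np.ndarray:
        return _hashed_tfidf_values(text.split(), self.dim, self.stats)


@dataclass
class PrecomputedEmbedder:
    """Backend serving externally computed per-accession vectors."""

    vectors: Mapping[str, EmbeddingVector]
    backend_id: str = "external"

    def vector_for(self, accession: str) -> EmbeddingVector:
        try:
            return self.vectors[accession]
        except KeyError:
            raise KeyError(f"no external vector for accession {accession!r}") from None


def embed_document(
    backend: TextEmbedder,
    doc: CleanDocument,
    config: ChunkingConfig,
    normalize_before_mean: bool = False,
) -> EmbeddingVector:
    """Embed one document, chunk-and-averaging when chunking is enabled.

    With chunking on, the document text is split into overlapping windows,
    each window is embedded, and the unweighted arithmetic mean of the
    per-chunk vectors is returned.  ``normalize_before_mean`` L2-normalises
    each chunk vector before averaging (off by default).
    """
    if not config.enabled:
        values = np.asarray(backend.embed(doc.text), dtype=np.float64)
        return EmbeddingVector(doc.accession, values, backend.backend_id)
    chunks = chunk_text(doc.text, config)
    mats = []
    dim = None
    for chunk in chunks:
        v = np.asarray(backend.embed(chunk), dtype=np.float64)
        if dim is None:
            dim = v.shape[0]
        elif v.shape[0] != dim:
            raise ValueError(
                f"backend {backend.backend_id!r} returned inconsistent "
                f"dimensions ({dim} then {v.shape[0]}) for {doc.accession!r}"
            )
        if normalize_before_mean:
            norm = np.linalg.norm(v)
            if norm > 0:
                v = v / norm
        mats.append(v)
    return EmbeddingVector(doc.accession, np.mean(mats, axis=0), backend.backend_id)


def load_external_vectors(stream: Iterable[str] | IO[str]) -> list[EmbeddingVector]:
    """Read a vector table: header ``#backend_id=<id>\\tdim=<d>`` then rows
    ``accession\\tv1..vd``.  Ragged or non-numeric rows raise with the
    1-based row number."""
    it = iter(stream)
    try:
        header = next(it).rstrip("\n")
    except StopIteration:
        raise ValueError("empty vector table") from None
    fields = header.split("\t")
    if len(fields) != 2 or not fields[0].startswith("#backend_id=") or not fields[1].startswith("dim="):
        raise ValueError("vector table must start with '#backend_id=<id>\\tdim=<d>'")
    backend_id = fields[0].removeprefix("#backend_id=")
    try:
        dim = int(fields[1].removeprefix("dim="))
    except ValueError:
        raise ValueError(f"invalid dim in header: {fields[1]!r}") from None
    vectors = []
    for rowno, line in enumerate(it, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != dim + 1:
            raise ValueError(
                f"row {rowno}: expected {dim + 1} fields, found {len(parts)}"
            )
        try:
            values = np.array([float(x) for x in parts[1:]], dtype=np.float64)
        except ValueError:
            raise ValueError(f"row {rowno}: non-numeric vector component") from None
        vectors.append(EmbeddingVector(parts[0], values, f"external:{backend_id}"))
    return vectors


def write_external_vectors(
    vectors: Sequence[EmbeddingVector], stream: IO[str], backend_id: str
) -> None:
    """Inverse of :func:`load_external_vectors`."""
    if not vectors:
        raise ValueError("no vectors to write")
    dim = vectors[0].dim
    stream.write(f"#backend_id={backend_id}\tdim={dim}\n")
    for v in vectors:
        if v.dim != dim:
            raise ValueError("mixed dimensions in vector table")
        row = "\t".join(repr(float(x)) for x in v.values)
        stream.write(f"{v.accession}\t{row}\n")
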