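"""Ranking candidate series against a reference set of known-relevant series.

The retrieval flow mirrors how a researcher searches: the series they have
already found form the *reference set*; candidates are ranked by similarity
to it.  For vector backends the reference documents are embedded and
averaged, and candidates are ordered by cosine similarity to the mean
embedding.  For the frequency baselines the reference is aggregated as a
pooled unique-token set (word overlap) or as a concatenated token query
(BM25).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .backends import (
    BACKEND_IDS,
    Bm25Index,
    ChunkingConfig,
    CorpusStats,
    EmbeddingVector,
    HashedTfidfEmbedder,
    bm25_score,
    build_bm25_index,
    embed_document,
    word_overlap_similarity,
)
from .ingest import clean_record
from .records import CleanDocument, CleaningPolicy, SeriesRecord


def cosine_similarity(u: EmbeddingVector, v: EmbeddingVector) -> float:
    """Cosine of the angle between two embeddings; 0 when either is zero."""
    if u.dim != v.dim:
        raise ValueError(f"dimension mismatch: {u.dim} vs {v.dim}")
    nu = np.linalg.norm(u.values)
    nv = np.linalg.norm(v.values)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u.values, v.values) / (nu * nv))


def mean_embedding(vectors: Sequence[EmbeddingVector]) -> EmbeddingVector:
    """Element-wise unweighted mean of same-backend embeddings."""
    if not vectors:
        raise ValueError("cannot average an empty list of embeddings")
    backend_ids = {v.backend_id for v in vectors}
    if len(backend_ids) > 1:
        raise ValueError(f"mixed backends in mean: {sorted(backend_ids)}")
    dims = {v.dim for v in vectors}
    if len(dims) > 1:
        raise ValueError(f"mixed dimensions in mean: {sorted(dims)}")
    values = np.mean([v.values for v in vectors], axis=0)
    return EmbeddingVector("reference_mean", values, vectors[0].backend_id)


@dataclass(frozen=True)
class RankEntry:
    accession: str
    score: float
    relevant: Optional[bool] = None


@dataclass
class RankedResult:
    """Ordered candidate list with similarity scores and relevance labels.

    Entries are sorted by descending score, ties broken by ascending
    accession; reference accessions never appear.  ``flagged_empty`` lists
    candidates whose cleaned text was empty (scored 0).
    """

    condition: str
    backend_id: str
    entries: list[RankEntry]
    flagged_empty: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        keys = [(-e.score, e.accession) for e in self.entries]
        if keys != sorted(keys):
            raise ValueError("entries must be sorted by descending score, then accession")
        accs = [e.accession for e in self.entries]
        if len(accs) != len(set(accs)):
            raise ValueError("duplicate accessions among ranked entries")

    def accessions(self) -> list[str]:
        return [e.accession for e in self.entries]


def _sorted_entries(
    scores: Mapping[str, float], relevant: Optional[frozenset[str]]
) -> list[RankEntry]:
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        RankEntry(acc, sc, None if relevant is None else acc in relevant)
        for acc, sc in items
    ]


def rank_by_reference(
    reference: Sequence[SeriesRecord],
    candidates: Sequence[SeriesRecord],
    backend_id: str,
    config: ChunkingConfig = ChunkingConfig(),
    policy: CleaningPolicy = CleaningPolicy(),
    *,
    condition: str = "",
    relevant: Optional[frozenset[str]] = None,
    external_vectors: Optional[Mapping[str, EmbeddingVector]] = None,
    dim: int = 256,
    normalize_before_mean: bool = False,
) -> RankedResult:
    """Rank ``candidates`` by similarity to the ``reference`` set.

    Backends: ``word_overlap`` scores each candidate against the pooled
    unique-token set of the reference documents; ``bm25``/``bm25plus`` build
    an index over the candidates and score them against the concatenated
    reference tokens (the policy's stop-word/stemming flags are coerced to
    match the mode); ``hashed_tfidf`` and ``external:<id>`` embed candidates
    and compare them, by cosine, to the mean reference embedding.

    Candidates sharing an accession with the reference are excluded before
    ranking.  Candidates whose cleaned text is empty are kept with score 0
    and reported in ``flagged_empty``.
    """
    if not reference:
        raise ValueError("reference set must not be empty")
    is_external = backend_id.startswith("external:")
    if backend_id not in BACKEND_IDS and not is_external:
        raise ValueError(f"unknown backend {backend_id!r}")

    ref_accessions = {r.accession for r in reference}
    candidates = [c for c in candidates if c.accession not in ref_accessions]

    if backend_id == "bm25":
        policy = policy.with_frequency_mode(remove_stopwords=False, stem=False)
    elif backend_id == "bm25plus":
        policy = policy.with_frequency_mode(remove_stopwords=True, stem=True)

    ref_docs = [clean_record(r, policy) for r in reference]
    cand_docs = [clean_record(c, policy) for c in candidates]
    empty = frozenset(d.accession for d in cand_docs if d.is_empty)
    scores: dict[str, float] = {acc: 0.0 for acc in empty}
    nonempty = [d for d in cand_docs if not d.is_empty]

    if backend_id == "word_overlap":
        pooled: set[str] = set()
        for d in ref_docs:
            pooled |= d.unique_tokens()
        pooled_doc = CleanDocument(
            accession="reference_pool",
            text=" ".join(sorted(pooled)),
            tokens=tuple(sorted(pooled)),
            policy=policy,
        )
        for d in nonempty:
            scores[d.accession] = word_overlap_similarity(pooled_doc, d)
    elif backend_id in ("bm25", "bm25plus"):
        mode = "plus" if backend_id == "bm25plus" else "default"
        if nonempty:
            index = build_bm25_index(nonempty, mode=mode)
            query: list[str] = [t for d in ref_docs for t in d.tokens]
            for d in nonempty:
                scores[d.accession] = bm25_score(index, query, d.accession)
    elif backend_id == "hashed_tfidf":
        stats = CorpusStats.from_documents(nonempty)
        embedder = HashedTfidfEmbedder(stats=stats, dim=dim)
        ref_vecs = [
            embed_document(embedder, d, config, normalize_before_mean)
            for d in ref_docs
        ]
        query_vec = mean_embedding(ref_vecs)
        for d in nonempty:
            vec = embed_document(embedder, d, config, normalize_before_mean)
            scores[d.accession] = cosine_similarity(query_vec, vec)
    else:  # external:<id>
        if external_vectors is None:
            raise ValueError("external backend requires precomputed vectors")
        missing = sorted(
            acc
            for acc in ({d.accession for d in nonempty} | ref_accessions)
            if acc not in external_vectors
        )
        if missing:
            raise ValueError(f"missing external vectors for: {', '.join(missing)}")
        query_vec = mean_embedding([external_vectors[r.accession] for r in reference])
        for d in nonempty:
            scores[d.accession] = cosine_similarity(query_vec, external_vectors[d.accession])

    return RankedResult(
        condition=condition,
        backend_id=backend_id,
        entries=_sorted_entries(scores, relevant),
        flagged_empty=empty,
    )
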