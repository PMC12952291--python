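"""Benchmark protocol: splits, ranked-retrieval metrics, imbalance sweeps.

For each condition the annotated series are randomly halved into a
*reference set* (the query; one extra member when the count is odd) and a
held-out *comparison set A* of relevant candidates.  Every other series in
the labeled universe forms *comparison set B*, the irrelevant pool, which
can be subsampled to a fixed irrelevant:relevant ratio to simulate varying
class imbalance.  Rankings are scored by average precision (AUPRC) and
recall at fixed cut-offs; backends are compared across conditions by their
median AUPRC rank.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .backends import ChunkingConfig
from .records import CleaningPolicy, SeriesRecord
from .retrieval import RankedResult, rank_by_reference

Ratio = Union[int, str]  # positive int, or "all"

#: recall cut-offs reported by run_benchmark
RECALL_NS = (10, 100, 1000)


@dataclass(frozen=True)
class SplitPlan:
    """Per-condition assignment of annotated series to reference /
    comparison set A, plus the irrelevant pool (comparison set B)."""

    condition: str
    reference: frozenset[str]
    comparison_a: frozenset[str]
    comparison_b: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        if self.reference & self.comparison_a:
            raise ValueError("reference and comparison set A overlap")
        if (self.reference | self.comparison_a) & self.comparison_b:
            raise ValueError("comparison set B overlaps the annotated split")
        diff = len(self.reference) - len(self.comparison_a)
        n = len(self.reference) + len(self.comparison_a)
        if diff != (n % 2):
            raise ValueError("reference must exceed comparison set A only for odd counts")


def make_split(
    annotated: Sequence[str],
    all_annotated: Sequence[str],
    condition: str,
    seed: int,
) -> SplitPlan:
    """Randomly halve the condition's annotated series.

    The accessions are sorted, permuted uniformly under ``seed``, and the
    first ceil(n/2) become the reference set; the rest are comparison set A.
    Comparison set B is every series in ``all_annotated`` not annotated for
    the condition.
    """
    annotated_set = set(annotated)
    if len(annotated_set) < 2:
        raise ValueError(
            f"condition {condition!r} has {len(annotated_set)} annotated series; need >= 2"
        )
    universe = set(all_annotated)
    if not annotated_set <= universe:
        stray = sorted(annotated_set - universe)[:5]
        raise ValueError(f"annotated accessions missing from universe: {stray}")
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(sorted(annotated_set)))
    k = math.ceil(len(perm) / 2)
    return SplitPlan(
        condition=condition,
        reference=frozenset(perm[:k]),
        comparison_a=frozenset(perm[k:]),
        comparison_b=frozenset(universe - annotated_set),
        seed=seed,
    )


def subsample_imbalance(
    comparison_b: Iterable[str],
    comparison_a_size: int,
    ratio: Ratio,
    seed: int,
) -> frozenset[str]:
    """Subsample the irrelevant pool to ``ratio`` irrelevant per relevant.

    ``ratio="all"`` returns the pool unchanged; an integer ratio draws
    ``ratio * comparison_a_size`` accessions uniformly without replacement.
    """
    pool = sorted(set(comparison_b))
    if ratio == "all":
        return frozenset(pool)
    if not isinstance(ratio, int) or ratio < 1:
        raise ValueError(f"ratio must be a positive integer or 'all', got {ratio!r}")
    k = ratio * comparison_a_size
    if k > len(pool):
        raise ValueError(
            f"requested {k} irrelevant series but the pool has only {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=k, replace=False)
    return frozenset(chosen.tolist())


def precision_recall_auc(result: RankedResult) -> float:
    """Average precision of a ranked list with binary relevance labels.

    The mean over relevant entries, at their ranks k, of precision@k.  Ties
    are already resolved by the ranking's ordering contract.
    """
    labels = [e.relevant for e in result.entries]
    if any(lab is None for lab in labels):
        raise ValueError("all relevance labels must be known to compute AUPRC")
    n_rel = sum(labels)
    if n_rel == 0:
        raise ValueError("no relevant entries in ranking")
    if n_rel == len(labels):
        raise ValueError("no irrelevant entries in ranking")
    total = 0.0
    seen = 0
    for rank, lab in enumerate(labels, start=1):
        if lab:
            seen += 1
            total += seen / rank
    return total / n_rel


def recall_at_n(result: RankedResult, n: int) -> float:
    """Fraction of all relevant entries appearing in the top ``n``."""
    if n < 0:
        raise ValueError("n must be non-negative")
    labels = [bool(e.relevant) for e in result.entries]
    n_rel = sum(labels)
    if n_rel == 0:
        return 0.0
    return sum(labels[:n]) / n_rel


def median_rank_table(
    results: Mapping[tuple[str, str], float]
) -> dict[str, float]:
    """Median across conditions of each backend's AUPRC rank.

    Within each condition, backends are ranked by descending AUPRC with
    average ranks for ties; lower median rank means better overall.
    """
    conditions = sorted({c for c, _ in results})
    backends = sorted({b for _, b in results})
    missing = [
        (c, b) for c in conditions for b in backends if (c, b) not in results
    ]
    if missing:
        raise ValueError(f"missing AUPRC cells: {missing}")
    ranks_per_backend: dict[str, list[float]] = {b: [] for b in backends}
    for c in conditions:
        scores = np.array([results[(c, b)] for b in backends])
        ranks = rankdata(-scores, method="average")
        for b, r in zip(backends, ranks):
            ranks_per_backend[b].append(float(r))
    return {b: float(np.median(r)) for b, r in ranks_per_backend.items()}


@dataclass(frozen=True)
class BenchmarkResult:
    """One benchmark cell: condition x backend x imbalance ratio x chunking."""

    condition: str
    backend_id: str
    ratio: Ratio
    chunking: bool
    auprc: float
    recall_curve: dict[int, float]
    seed: int
    n_candidates: int
    n_relevant: int


def derive_cell_seed(
    master_seed: int, condition: str, backend_id: str, ratio: Ratio,
    chunking: bool, stage: str,
) -> int:
    """Deterministic per-cell seed: SHA-256 of the cell key, below 2^31."""
    key = f"{master_seed}|{condition}|{backend_id}|{ratio}|{chunking}|{stage}"
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_benchmark(
    corpus: Sequence[SeriesRecord],
    conditions: Sequence[str],
    backends: Sequence[str],
    ratios: Sequence[Ratio],
    chunking: Sequence[bool] = (False,),
    policy: CleaningPolicy = CleaningPolicy(remove_stopwords=True),
    seed: int = 0,
    chunking_config: ChunkingConfig = ChunkingConfig(enabled=True),
    dim: int = 256,
) -> list[BenchmarkResult]:
    """Full factorial benchmark over conditions x backends x ratios x chunking.

    Each cell derives its own seed from the master ``seed`` so cells are
    independently reproducible; rerunning with the same master seed yields
    identical results.
    """
    by_acc = {r.accession: r for r in corpus}
    all_accessions = list(by_acc)
    annotated_by_condition = {
        c: sorted(a for a, r in by_acc.items() if c in r.condition_labels)
        for c in conditions
    }
    for c, annotated in annotated_by_condition.items():
        if len(annotated) < 2:
            raise ValueError(
                f"condition {c!r} has {len(annotated)} annotated series; need >= 2"
            )
    results = []
    for condition in conditions:
        for backend_id in backends:
            for ratio in ratios:
                for chunk in chunking:
                    try:
                        results.append(
                            _run_cell(
                                by_acc, all_accessions,
                                annotated_by_condition[condition],
                                condition, backend_id, ratio, chunk,
                                policy, seed, chunking_config, dim,
                            )
                        )
                    except ValueError as exc:
                        raise ValueError(
                            f"benchmark cell ({condition}, {backend_id}, "
                            f"{ratio}, chunking={chunk}): {exc}"
                        ) from exc
    return results


def _run_cell(
    by_acc, all_accessions, annotated, condition, backend_id, ratio, chunk,
    policy, master_seed, chunking_config, dim,
) -> BenchmarkResult:
    split_seed = derive_cell_seed(master_seed, condition, backend_id, ratio, chunk, "split")
    sub_seed = derive_cell_seed(master_seed, condition, backend_id, ratio, chunk, "subsample")
    split = make_split(annotated, all_accessions, condition, split_seed)
    pool = subsample_imbalance(split.comparison_b, len(split.comparison_a), ratio, sub_seed)
    candidates = [by_acc[a] for a in sorted(split.comparison_a | pool)]
    reference = [by_acc[a] for a in sorted(split.reference)]
    config = ChunkingConfig(
        enabled=chunk,
        threshold_chars=chunking_config.threshold_chars,
        overlap_chars=chunking_config.overlap_chars,
        chunk_size_chars=chunking_config.chunk_size_chars,
    )
    ranked = rank_by_reference(
        reference, candidates, backend_id,
        config=config, policy=policy,
        condition=condition, relevant=split.comparison_a, dim=dim,
    )
    return BenchmarkResult(
        condition=condition,
        backend_id=backend_id,
        ratio=ratio,
        chunking=chunk,
        auprc=precision_recall_auc(ranked),
        recall_curve={n: recall_at_n(ranked, n) for n in RECALL_NS},
        seed=split_seed,
        n_candidates=len(ranked.entries),
        n_relevant=len(split.comparison_a),
    )


def results_to_frame(results: Sequence[BenchmarkResult]) -> pd.DataFrame:
    """Tabulate benchmark results (one row per cell)."""
    rows = []
    for r in results:
        row = {
            "condition": r.condition,
            "backend_id": r.backend_id,
            "ratio": str(r.ratio),
            "chunking": r.chunking,
            "auprc": r.auprc,
        }
        for n in RECALL_NS:
            row[f"recall@{n}"] = r.recall_curve.get(n, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
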