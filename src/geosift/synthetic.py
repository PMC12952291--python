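"""Synthetic GEO-like labeled corpora with controllable vocabulary structure.

Real series descriptions are ad hoc free text in which condition-specific
terminology (disease names, tissue types, assay jargon) is embedded in
generic methods prose.  The generator emulates exactly that structure:
each condition owns a vocabulary of pseudo-words, a configurable fraction
of which is shared with a neighbouring condition (controlling how
confusable conditions are), and every document mixes condition tokens with
shared background tokens at a configurable rate.  Distractor series draw
background tokens only.  Everything is deterministic under the seed.

The pseudo-word alphabet is generated from consonant-vowel syllables so
documents look superficially like prose without copying any real
vocabulary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Optional, Sequence

import numpy as np

from .records import SeriesRecord

_CONSONANTS = "bcdfghjklmnprstvz"
_VOWELS = "aeiou"

#: Annotated-series counts for the six default conditions, smallest to
#: largest, plus enough distractors for a 5997-series labeled universe.
DEFAULT_CONDITION_SIZES = (12, 24, 30, 34, 109, 121)
DEFAULT_N_DISTRACTORS = 5997 - sum(DEFAULT_CONDITION_SIZES)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generated corpus.

    ``cross_condition_overlap`` is the fraction of each condition's
    vocabulary shared pairwise with the other condition vocabularies (a
    common confusion pool); ``condition_token_rate`` is the per-token
    probability that a document token comes from the condition vocabulary
    rather than the shared background.
    """

    n_conditions: int = 6
    series_per_condition: int = 30
    per_condition_sizes: Optional[tuple[int, ...]] = DEFAULT_CONDITION_SIZES
    n_distractors: int = DEFAULT_N_DISTRACTORS
    condition_vocab_size: int = 40
    shared_vocab_size: int = 500
    cross_condition_overlap: float = 0.2
    condition_token_rate: float = 0.25
    doc_length_range: tuple[int, int] = (60, 300)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions < 1:
            raise ValueError("n_conditions must be positive")
        if self.series_per_condition < 1:
            raise ValueError("series_per_condition must be positive")
        if self.per_condition_sizes is not None:
            if len(self.per_condition_sizes) != self.n_conditions:
                raise ValueError(
                    "per_condition_sizes must have one entry per condition"
                )
            if any(s < 1 for s in self.per_condition_sizes):
                raise ValueError("per-condition sizes must be positive")
        if self.n_distractors < 0:
            raise ValueError("n_distractors must be non-negative")
        if self.condition_vocab_size < 1 or self.shared_vocab_size < 0:
            raise ValueError("vocabulary sizes must be non-negative (condition >= 1)")
        if not 0.0 <= self.cross_condition_overlap <= 1.0:
            raise ValueError("cross_condition_overlap must lie in [0, 1]")
        if self.cross_condition_overlap > 0.0 and self.n_conditions < 2:
            raise ValueError(
                "cross-condition overlap requires at least two conditions"
            )
        if not 0.0 < self.condition_token_rate <= 1.0:
            raise ValueError("condition_token_rate must lie in (0, 1]")
        lo, hi = self.doc_length_range
        if lo < 3 or hi < lo:
            raise ValueError("doc_length_range must satisfy 3 <= min <= max")
        if self.condition_token_rate < 1.0 and self.shared_vocab_size == 0:
            raise ValueError("background tokens requested but shared vocabulary is empty")

    def sizes(self) -> tuple[int, ...]:
        if self.per_condition_sizes is not None:
            return self.per_condition_sizes
        return (self.series_per_condition,) * self.n_conditions

    def condition_names(self) -> tuple[str, ...]:
        return tuple(f"condition_{i + 1:02d}" for i in range(self.n_conditions))

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d["per_condition_sizes"] = (
            list(self.per_condition_sizes) if self.per_condition_sizes else None
        )
        d["doc_length_range"] = list(self.doc_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown synthetic-config fields: {sorted(unknown)}")
        d = dict(d)
        if d.get("per_condition_sizes") is not None:
            d["per_condition_sizes"] = tuple(d["per_condition_sizes"])
        if "doc_length_range" in d:
            d["doc_length_range"] = tuple(d["doc_length_range"])
        return cls(**d)


def _pseudo_words(rng: np.random.Generator, count: int) -> list[str]:
    """Distinct pronounceable pseudo-words (2-4 CV syllables)."""
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < count:
        n_syll = int(rng.integers(2, 5))
        word = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syll)
        )
        if word not in seen:
            seen.add(word)
            words.append(word)
    return words


def _partition_tokens(tokens: list[str]) -> tuple[str, str, str]:
    """Split a token stream into title / summary / overall-design text."""
    n = len(tokens)
    t_end = max(1, n // 10)
    s_end = max(t_end + 1, (7 * n) // 10)
    return (
        " ".join(tokens[:t_end]),
        " ".join(tokens[t_end:s_end]),
        " ".join(tokens[s_end:]),
    )


def generate_corpus(config: SyntheticConfig) -> list[SeriesRecord]:
    """Generate a labeled GEO-like corpus under ``config`` (deterministic).

    Condition series come first (grouped by condition), then distractors;
    accessions are sequential.  All records carry filler values that pass
    the ingest filter (human, array, Affymetrix, not retired/SubSeries).
    """
    rng = np.random.default_rng(config.seed)
    names = config.condition_names()
    sizes = config.sizes()

    # Conditions share a common "confusion pool" making up an exact
    # cross_condition_overlap fraction of every condition vocabulary, so the
    # pairwise shared fraction equals the overlap parameter for any number
    # of conditions and grows monotonically with it; overlap 0 leaves the
    # vocabularies pairwise disjoint, overlap 1 makes them identical.
    k_overlap = int(round(config.cross_condition_overlap * config.condition_vocab_size))
    n_own = config.condition_vocab_size - k_overlap
    words = _pseudo_words(
        rng,
        config.shared_vocab_size + k_overlap + n_own * config.n_conditions,
    )
    shared = words[: config.shared_vocab_size]
    pool = words[config.shared_vocab_size : config.shared_vocab_size + k_overlap]
    vocabs: list[list[str]] = []
    start = config.shared_vocab_size + k_overlap
    for i in range(config.n_conditions):
        vocabs.append(words[start + i * n_own : start + (i + 1) * n_own] + pool)

    records: list[SeriesRecord] = []
    counter = 1

    def make_record(tokens: list[str], labels: frozenset[str]) -> SeriesRecord:
        nonlocal counter
        title, summary, design = _partition_tokens(tokens)
        rec = SeriesRecord(
            accession=f"GSE{counter:06d}",
            title=title,
            summary=summary,
            overall_design=design,
            species="Homo sapiens",
            experiment_types=frozenset({"expression profiling by array"}),
            platform_vendor="Affymetrix",
            condition_labels=labels,
        )
        counter += 1
        return rec

    lo, hi = config.doc_length_range
    for name, size, vocab in zip(names, sizes, vocabs):
        vocab_arr = np.array(vocab)
        shared_arr = np.array(shared) if shared else None
        for _ in range(size):
            length = int(rng.integers(lo, hi + 1))
            use_cond = rng.random(length) < config.condition_token_rate
            tokens = []
            for is_cond in use_cond:
                if is_cond or shared_arr is None:
                    tokens.append(str(vocab_arr[rng.integers(len(vocab_arr))]))
                else:
                    tokens.append(str(shared_arr[rng.integers(len(shared_arr))]))
            records.append(make_record(tokens, frozenset({name})))

    shared_arr = np.array(shared) if shared else None
    for _ in range(config.n_distractors):
        if shared_arr is None:
            raise ValueError("distractors require a non-empty shared vocabulary")
        length = int(rng.integers(lo, hi + 1))
        tokens = [str(shared_arr[rng.integers(len(shared_arr))]) for _ in range(length)]
        records.append(make_record(tokens, frozenset()))
    return records


_TAG_PAIRS = (("<b>", "</b>"), ("<i>", "</i>"), ("<em>", "</em>"), ("<br>", ""))
_PUNCT = ",.;:!?"


def degrade_corpus(
    corpus: Sequence[SeriesRecord],
    html_noise: float = 0.0,
    url_noise: float = 0.0,
    casing_noise: float = 0.0,
    seed: int = 0,
) -> list[SeriesRecord]:
    """Inject removable noise into the free-text fields, per token.

    ``html_noise`` wraps tokens in HTML tags, ``url_noise`` inserts URL
    tokens after them, and ``casing_noise`` randomises letter case and
    attaches a punctuation character.  All injected material is removed by
    the default cleaning policy, so labels and (lowercased) token multisets
    are preserved.  With every document longer than one token, a rate of
    1.0 guarantees at least one injection per document.
    """
    for rate, name in ((html_noise, "html_noise"), (url_noise, "url_noise"),
                       (casing_noise, "casing_noise")):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def degrade_field(text: str) -> str:
        if not text:
            return text
        out = []
        for token in text.split(" "):
            if casing_noise and rng.random() < casing_noise:
                token = "".join(
                    c.upper() if rng.random() < 0.5 else c for c in token
                )
                token = token + _PUNCT[rng.integers(len(_PUNCT))]
            if html_noise and rng.random() < html_noise:
                open_tag, close_tag = _TAG_PAIRS[rng.integers(len(_TAG_PAIRS))]
                token = f"{open_tag}{token}{close_tag}"
            out.append(token)
            if url_noise and rng.random() < url_noise:
                out.append(f"https://example.org/s/{rng.integers(10**6)}")
        return " ".join(out)

    degraded = []
    for rec in corpus:
        degraded.append(
            SeriesRecord(
                accession=rec.accession,
                title=degrade_field(rec.title),
                summary=degrade_field(rec.summary),
                overall_design=degrade_field(rec.overall_design),
                species=rec.species,
                experiment_types=rec.experiment_types,
                platform_vendor=rec.platform_vendor,
                retired=rec.retired,
                is_subseries=rec.is_subseries,
                condition_labels=rec.condition_labels,
            )
        )
    return degraded


def records_to_jsonl(records: Sequence[SeriesRecord], stream: IO[str]) -> None:
    """Serialise records in the JSON-lines metadata dialect (stable key and
    set ordering, so equal corpora produce byte-identical files)."""
    for r in records:
        obj = {
            "accession": r.accession,
            "title": r.title,
            "summary": r.summary,
            "overall_design": r.overall_design,
            "species": r.species,
            "experiment_types": sorted(r.experiment_types),
            "platform_vendor": r.platform_vendor,
            "retired": r.retired,
            "is_subseries": r.is_subseries,
            "condition_labels": sorted(r.condition_labels),
        }
        stream.write(json.dumps(obj, sort_keys=False) + "\n")
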