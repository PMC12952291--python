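"""Core record types for series metadata and cleaned documents.

A *series* is a study-level record in a GEO-style repository: an accession
plus free-text title, summary, and overall-design fields, annotated with
organism, assay type, and platform vendor.  Condition labels (when present)
come from an external curation resource and serve as ground-truth relevance
labels for retrieval benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class CleaningPolicy:
    """Flags controlling text normalisation, applied in a fixed order.

    The order is: strip HTML tags, strip URLs, lowercase, replace
    non-alphanumeric characters with spaces, collapse whitespace,
    tokenize, remove stop words, stem.  All flags are independent.
    """

    lowercase: bool = True
    strip_html: bool = True
    strip_urls: bool = True
    strip_non_alphanumeric: bool = True
    collapse_whitespace: bool = True
    remove_stopwords: bool = False
    stem: bool = False

    def with_frequency_mode(self, remove_stopwords: bool, stem: bool) -> "CleaningPolicy":
        """Return a copy with the stop-word/stemming flags overridden."""
        return replace(self, remove_stopwords=remove_stopwords, stem=stem)

    def to_dict(self) -> dict:
        return {
            "lowercase": self.lowercase,
            "strip_html": self.strip_html,
            "strip_urls": self.strip_urls,
            "strip_non_alphanumeric": self.strip_non_alphanumeric,
            "collapse_whitespace": self.collapse_whitespace,
            "remove_stopwords": self.remove_stopwords,
            "stem": self.stem,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CleaningPolicy":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown cleaning-policy fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SeriesRecord:
    """One GEO-style series: identifiers, free text, and annotations."""

    accession: str
    title: str = ""
    summary: str = ""
    overall_design: str = ""
    species: str = ""
    experiment_types: frozenset[str] = field(default_factory=frozenset)
    platform_vendor: str = ""
    retired: bool = False
    is_subseries: bool = False
    condition_labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("SeriesRecord requires a non-empty accession")
        self.experiment_types = frozenset(self.experiment_types)
        self.condition_labels = frozenset(self.condition_labels)


@dataclass(frozen=True)
class CleanDocument:
    """Cleaned, composed text for one series plus its token list.

    ``text`` is the space-join of ``tokens`` (or the post-transform string
    when no token-level step ran), so ``tokens`` is always exactly the
    whitespace split of ``text``.  The policy used is carried along as
    provenance.
    """

    accession: str
    text: str
    tokens: tuple[str, ...]
    policy: CleaningPolicy

    def __post_init__(self) -> None:
        if tuple(self.text.split()) != self.tokens:
            raise ValueError(
                f"tokens must equal the whitespace split of text ({self.accession!r})"
            )

    @property
    def char_length(self) -> int:
        """Number of characters after cleaning."""
        return len(self.text)

    @property
    def is_empty(self) -> bool:
        return not self.tokens

    def unique_tokens(self) -> frozenset[str]:
        return frozenset(self.tokens)
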