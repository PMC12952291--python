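"""Reading, filtering, and cleaning GEO-style series metadata.

Two input dialects are supported: a JSON-lines metadata format (one object
per line) and a minimal subset of the SOFT format (``^SERIES`` blocks with
``!Series_*`` attribute lines).  Filtering retains the human transcriptomic
series a dataset-discovery benchmark targets: non-retired, non-SubSeries
records profiled by array (Affymetrix/Illumina/Agilent) or by
high-throughput sequencing (Illumina).

Cleaning composes title + summary + overall design and applies, in order:
HTML-tag stripping, URL removal, lowercasing, replacement of
non-alphanumeric characters with spaces, whitespace collapsing,
tokenization, stop-word removal, and Porter stemming — each step gated by a
:class:`~geosift.records.CleaningPolicy` flag.
"""

from __future__ import annotations

import json
import re
from html.parser import HTMLParser
from importlib import resources
from typing import IO, Iterable

from ._porter import porter_stem
from .records import CleanDocument, CleaningPolicy, SeriesRecord


class MetadataError(ValueError):
    """Malformed or inconsistent metadata input."""


class EmptyDocumentError(ValueError):
    """A series has no usable free text."""


def load_stopwords() -> frozenset[str]:
    """Bundled English stop-word list (lowercase, one token per line)."""
    text = resources.files("geosift").joinpath("data/stopwords.txt").read_text("utf-8")
    return frozenset(line.strip() for line in text.splitlines() if line.strip())


_STOPWORDS = load_stopwords()

_JSONL_KEYS = {
    "accession", "title", "summary", "overall_design", "species",
    "experiment_types", "platform_vendor", "retired", "is_subseries",
    "condition_labels",
}


def _record_from_obj(obj: dict, where: str) -> SeriesRecord:
    if not isinstance(obj, dict):
        raise MetadataError(f"{where}: expected a JSON object")
    accession = obj.get("accession", "")
    if not accession:
        raise MetadataError(f"{where}: missing or empty accession")
    return SeriesRecord(
        accession=accession,
        title=obj.get("title") or "",
        summary=obj.get("summary") or "",
        overall_design=obj.get("overall_design") or "",
        species=obj.get("species") or "",
        experiment_types=frozenset(obj.get("experiment_types") or ()),
        platform_vendor=obj.get("platform_vendor") or "",
        retired=bool(obj.get("retired", False)),
        is_subseries=bool(obj.get("is_subseries", False)),
        condition_labels=frozenset(obj.get("condition_labels") or ()),
    )


def _parse_jsonl(stream: Iterable[str]) -> list[SeriesRecord]:
    records: list[SeriesRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise MetadataError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
        rec = _record_from_obj(obj, f"line {lineno}")
        if rec.accession in seen:
            raise MetadataError(f"duplicate accession {rec.accession!r} (line {lineno})")
        seen.add(rec.accession)
        records.append(rec)
    return records


def _parse_soft(stream: Iterable[str]) -> list[SeriesRecord]:
    # Attribute subset: title, summary (repeatable), overall design,
    # organism, type (repeatable).  Other lines are ignored.
    records: list[SeriesRecord] = []
    seen: set[str] = set()
    current: dict | None = None

    def flush() -> None:
        nonlocal current
        if current is None:
            return
        records.append(
            SeriesRecord(
                accession=current["accession"],
                title=current["title"],
                summary=" ".join(current["summary"]),
                overall_design=current["overall_design"],
                species=current["species"],
                experiment_types=frozenset(current["types"]),
            )
        )
        current = None

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("^SERIES"):
            flush()
            _, _, acc = line.partition("=")
            acc = acc.strip()
            if not acc:
                raise MetadataError(f"line {lineno}: ^SERIES without accession")
            if acc in seen:
                raise MetadataError(f"duplicate accession {acc!r} (line {lineno})")
            seen.add(acc)
            current = {
                "accession": acc, "title": "", "summary": [],
                "overall_design": "", "species": "", "types": [],
            }
        elif line.startswith("!Series_"):
            if current is None:
                raise MetadataError(f"line {lineno}: attribute before any ^SERIES block")
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key == "!Series_title":
                current["title"] = value
            elif key == "!Series_summary":
                current["summary"].append(value)
            elif key == "!Series_overall_design":
                current["overall_design"] = value
            elif key == "!Series_sample_organism":
                current["species"] = value
            elif key == "!Series_type":
                current["types"].append(value)
    flush()
    return records


def parse_series_metadata(stream: Iterable[str] | IO[str], dialect: str) -> list[SeriesRecord]:
    """Parse series metadata from a character stream.

    Parameters
    ----------
    stream
        Iterable of lines (an open text file works).
    dialect
        ``"jsonl"`` or ``"soft"``.

    Returns one :class:`SeriesRecord` per series, in order of appearance;
    missing optional text fields become empty strings.  Raises
    :class:`MetadataError` on malformed records or duplicate accessions.
    """
    if dialect == "jsonl":
        return _parse_jsonl(stream)
    if dialect == "soft":
        return _parse_soft(stream)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'jsonl' or 'soft')")


_ARRAY_TYPE = "expression profiling by array"
_HTS_TYPE = "expression profiling by high throughput sequencing"
_ARRAY_VENDORS = {"affymetrix", "illumina", "agilent"}


def filter_series(records: list[SeriesRecord]) -> list[SeriesRecord]:
    """Retain human, non-retired, non-SubSeries expression series.

    Array series must come from an Affymetrix, Illumina, or Agilent
    platform; high-throughput-sequencing series must be Illumina.  Relative
    order is preserved and the result may be empty.
    """
    kept = []
    for r in records:
        if r.retired or r.is_subseries:
            continue
        if r.species.strip().lower() != "homo sapiens":
            continue
        types = {t.strip().lower() for t in r.experiment_types}
        vendor = r.platform_vendor.strip().lower()
        array_ok = _ARRAY_TYPE in types and vendor in _ARRAY_VENDORS
        hts_ok = _HTS_TYPE in types and vendor == "illumina"
        if array_ok or hts_ok:
            kept.append(r)
    return kept


def compose_document(record: SeriesRecord) -> str:
    """Concatenate title, summary, and overall design with single spaces,
    skipping empty fields; error if all three are empty."""
    parts = [p for p in (record.title, record.summary, record.overall_design) if p.strip()]
    if not parts:
        raise EmptyDocumentError(
            f"series {record.accession!r} has no title, summary, or overall design"
        )
    return " ".join(parts)


class _TagStripper(HTMLParser):
    def __init__(self) -> None:
        super().__init__(convert_charrefs=True)
        self.pieces: list[str] = []

    def handle_data(self, data: str) -> None:
        self.pieces.append(data)

    def handle_starttag(self, tag, attrs) -> None:  # tags act as separators
        self.pieces.append(" ")

    def handle_endtag(self, tag) -> None:
        self.pieces.append(" ")

    def handle_startendtag(self, tag, attrs) -> None:
        self.pieces.append(" ")


def _strip_html(text: str) -> str:
    if "<" not in text and "&" not in text:
        return text
    parser = _TagStripper()
    parser.feed(text)
    parser.close()
    return "".join(parser.pieces)


_URL_RE = re.compile(r"(?:(?:https?|ftp)://|www\.)\S+", re.IGNORECASE)
_NON_ALNUM_RE = re.compile(r"[^0-9A-Za-z]+")
_WS_RE = re.compile(r"\s+")


def clean_text(raw: str, policy: CleaningPolicy, accession: str = "") -> CleanDocument:
    """Apply the cleaning pipeline to ``raw`` under ``policy``.

    May yield an empty document (flagged downstream via
    :attr:`CleanDocument.is_empty`); never raises on content.
    """
    text = raw
    if policy.strip_html:
        text = _strip_html(text)
    if policy.strip_urls:
        text = _URL_RE.sub(" ", text)
    if policy.lowercase:
        text = text.lower()
    if policy.strip_non_alphanumeric:
        text = _NON_ALNUM_RE.sub(" ", text)
    if policy.collapse_whitespace:
        text = _WS_RE.sub(" ", text).strip()
    tokens = text.split()
    if policy.remove_stopwords:
        tokens = [t for t in tokens if t.casefold() not in _STOPWORDS]
    if policy.stem:
        tokens = [porter_stem(t) for t in tokens]
    # Preserve original spacing only when no token-level step rewrites it.
    if policy.collapse_whitespace or policy.remove_stopwords or policy.stem:
        text = " ".join(tokens)
    return CleanDocument(accession=accession, text=text, tokens=tuple(tokens), policy=policy)


def clean_record(record: SeriesRecord, policy: CleaningPolicy) -> CleanDocument:
    """Compose and clean one series record."""
    return clean_text(compose_document(record), policy, accession=record.accession)
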