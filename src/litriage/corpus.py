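"""Abstract corpora: reading, validation and filtering.

The unit of work for triage is the abstract record: PMID, title, abstract
text, publication date and publication-type labels. Two on-disk dialects are
supported: the PubMed/MEDLINE ``PubmedArticleSet`` XML subset and a simple
tab-separated format convenient for fixtures and synthetic corpora.
"""

from __future__ import annotations

import csv
import datetime as dt
import io
import logging
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "DocumentSet",
    "FilterSpec",
    "CorpusError",
    "read_medline_xml",
    "read_tsv_corpus",
    "write_tsv_corpus",
    "apply_filters",
]

_MONTHS = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}


class CorpusError(ValueError):
    """Raised for malformed corpus input."""


@dataclass(frozen=True)
class Document:
    """One abstract record.

    ``pub_date`` is a complete calendar date or ``None``; sources that give
    only a year (or year+month) are completed with January / the 1st so date
    comparisons reduce to year comparisons when only the year is known.
    """

    pmid: int
    title: str
    abstract: str = ""
    pub_date: dt.date | None = None
    pub_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pmid <= 0:
            raise CorpusError(f"pmid must be a positive integer, got {self.pmid!r}")
        if self.pub_date is not None and self.pub_date.year < 1800:
            raise CorpusError(f"publication year {self.pub_date.year} precedes 1800")

    @property
    def text(self) -> str:
        """Title and abstract joined by a single space: the coordinate system
        used for annotation offsets and indexing."""
        if not self.abstract:
            return self.title
        return f"{self.title} {self.abstract}"


class DocumentSet(Sequence[Document]):
    """An ordered collection of documents with unique PMIDs."""

    def __init__(self, documents: Iterable[Document] = ()) -> None:
        self._docs: list[Document] = list(documents)
        self._by_pmid: dict[int, Document] = {}
        for doc in self._docs:
            if doc.pmid in self._by_pmid:
                raise CorpusError(f"duplicate pmid {doc.pmid} in corpus")
            self._by_pmid[doc.pmid] = doc

    def __len__(self) -> int:
        return len(self._docs)

    def __getitem__(self, i):  # type: ignore[override]
        return self._docs[i]

    def __iter__(self) -> Iterator[Document]:
        return iter(self._docs)

    def __contains__(self, item: object) -> bool:
        if isinstance(item, Document):
            return self._by_pmid.get(item.pmid) == item
        return item in self._by_pmid

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DocumentSet):
            return NotImplemented
        return self._docs == other._docs

    def __repr__(self) -> str:
        return f"DocumentSet(n={len(self)})"

    def get(self, pmid: int) -> Document | None:
        return self._by_pmid.get(pmid)

    @property
    def pmids(self) -> list[int]:
        return [d.pmid for d in self._docs]


@dataclass(frozen=True)
class FilterSpec:
    """Corpus filters: temporal window, publication-type and PMID exclusion.

    Publication-type labels are compared case-insensitively because MEDLINE
    exports vary in capitalization. Documents without a date are kept unless
    a date bound is set, in which case they are dropped with a warning
    (conservative reading of a hard temporal cut-off).
    """

    date_after: dt.date | None = None
    date_before: dt.date | None = None
    exclude_pub_types: frozenset[str] = frozenset()
    excluded_pmids: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if (
            self.date_after is not None
            and self.date_before is not None
            and not self.date_after < self.date_before
        ):
            raise CorpusError("date_after must precede date_before")
        object.__setattr__(
            self, "exclude_pub_types", frozenset(t.lower() for t in self.exclude_pub_types)
        )
        object.__setattr__(self, "excluded_pmids", frozenset(self.excluded_pmids))

    def admits(self, doc: Document) -> bool:
        if doc.pmid in self.excluded_pmids:
            return False
        if any(t.lower() in self.exclude_pub_types for t in doc.pub_types):
            return False
        has_date_bound = self.date_after is not None or self.date_before is not None
        if doc.pub_date is None:
            if has_date_bound:
                logger.warning("document %d has no date; dropped by date filter", doc.pmid)
                return False
            return True
        if self.date_after is not None and doc.pub_date <= self.date_after:
            return False
        if self.date_before is not None and doc.pub_date > self.date_before:
            return False
        return True


def apply_filters(docs: DocumentSet, spec: FilterSpec) -> DocumentSet:
    """Return the documents admitted by ``spec``, in their original order.

    Pure and idempotent; the input set is never mutated.
    """
    return DocumentSet(d for d in docs if spec.admits(d))


# ---------------------------------------------------------------------------
# MEDLINE XML
# ---------------------------------------------------------------------------

def _parse_pubdate(node: etree._Element | None) -> dt.date | None:
    if node is None:
        return None
    year_el = node.find("Year")
    if year_el is None or not (year_el.text or "").strip():
        # MedlineDate fallback: take a leading 4-digit year if present.
        md = node.findtext("MedlineDate", default="").strip()
        if len(md) >= 4 and md[:4].isdigit():
            return dt.date(int(md[:4]), 1, 1)
        return None
    year = int(year_el.text.strip())
    month = _parse_month(node.findtext("Month", default=""))
    day_text = node.findtext("Day", default="").strip()
    day = int(day_text) if day_text.isdigit() else 1
    try:
        return dt.date(year, month, day)
    except ValueError:
        return dt.date(year, month, 1)


def _parse_month(raw: str) -> int:
    raw = raw.strip()
    if not raw:
        return 1
    if raw.isdigit():
        return max(1, min(12, int(raw)))
    return _MONTHS.get(raw[:3].lower(), 1)


def read_medline_xml(stream) -> DocumentSet:
    """Read a ``PubmedArticleSet`` XML stream into a :class:`DocumentSet`.

    Articles without a PMID are skipped with a warning; a missing Abstract
    element yields an empty abstract (warned); multiple ``AbstractText``
    sections (structured abstracts) are concatenated with single spaces in
    document order.
    """
    if isinstance(stream, (str, bytes)):
        stream = io.BytesIO(stream.encode() if isinstance(stream, str) else stream)
    try:
        tree = etree.parse(stream)
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"malformed MEDLINE XML: {exc}") from exc

    docs: list[Document] = []
    for article in tree.iter("PubmedArticle"):
        citation = article.find("MedlineCitation")
        if citation is None:
            logger.warning("PubmedArticle without MedlineCitation skipped")
            continue
        pmid_text = (citation.findtext("PMID") or "").strip()
        if not pmid_text.isdigit():
            logger.warning("article without a valid PMID skipped")
            continue
        pmid = int(pmid_text)
        art = citation.find("Article")
        title = "" if art is None else " ".join((art.findtext("ArticleTitle") or "").split())
        abstract = ""
        if art is not None:
            abstract_el = art.find("Abstract")
            if abstract_el is None:
                logger.warning("PMID %d has no abstract", pmid)
            else:
                parts = [
                    " ".join("".join(sec.itertext()).split())
                    for sec in abstract_el.findall("AbstractText")
                ]
                abstract = " ".join(p for p in parts if p)
        pub_types = frozenset(
            (pt.text or "").strip()
            for pt in (() if art is None else art.iter("PublicationType"))
            if (pt.text or "").strip()
        )
        pub_date = None
        if art is not None:
            pub_date = _parse_pubdate(art.find("Journal/JournalIssue/PubDate"))
        docs.append(
            Document(pmid=pmid, title=title, abstract=abstract,
                     pub_date=pub_date, pub_types=pub_types)
        )
    return DocumentSet(docs)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["pmid", "title", "abstract", "year", "pub_types"]


def read_tsv_corpus(stream) -> DocumentSet:
    """Read the TSV corpus dialect (columns pmid, title, abstract, year,
    pub_types pipe-separated; header mandatory, UTF-8)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.reader(stream, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise CorpusError("empty TSV corpus: header row missing") from None
    if header != _TSV_COLUMNS:
        raise CorpusError(f"bad TSV header {header!r}; expected {_TSV_COLUMNS!r}")
    docs = []
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) != len(_TSV_COLUMNS):
            raise CorpusError(f"line {lineno}: expected {len(_TSV_COLUMNS)} columns, got {len(row)}")
        pmid_text, title, abstract, year_text, types_text = row
        if not pmid_text.strip().isdigit():
            raise CorpusError(f"line {lineno}: non-integer pmid {pmid_text!r}")
        pub_date = None
        if year_text.strip():
            if not year_text.strip().isdigit():
                raise CorpusError(f"line {lineno}: non-integer year {year_text!r}")
            pub_date = dt.date(int(year_text), 1, 1)
        pub_types = frozenset(t for t in types_text.split("|") if t)
        docs.append(
            Document(pmid=int(pmid_text), title=title, abstract=abstract,
                     pub_date=pub_date, pub_types=pub_types)
        )
    return DocumentSet(docs)


def write_tsv_corpus(docs: DocumentSet, stream) -> None:
    """Write ``docs`` in the TSV dialect (inverse of :func:`read_tsv_corpus`
    up to the year-only date resolution). Embedded tabs/newlines in text
    fields are replaced by spaces."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(_TSV_COLUMNS)
    for d in docs:
        clean = lambda s: " ".join(s.split("\t")).replace("\n", " ").replace("\r", " ")
        writer.writerow([
            d.pmid,
            clean(d.title),
            clean(d.abstract),
            "" if d.pub_date is None else d.pub_date.year,
            "|".join(sorted(d.pub_types)),
        ])
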