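"""Bibliographic corpus model and I/O.

The analysis unit throughout the package is the MEDLINE-style record: a
PMID, a free-text title, a publication year and a list of MeSH headings
(Main Heading descriptor plus optional Subheading qualifiers).  Three ways
in exist: the standard PubMed XML export (``PubmedArticleSet``), a
line-delimited JSON fixture format for tests and offline runs, and a thin,
fully mockable Entrez retrieval wrapper.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from io import BytesIO
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

from lxml import etree

__all__ = [
    "MeshHeading",
    "PublicationRecord",
    "Corpus",
    "ParseReport",
    "CorpusError",
    "ParseError",
    "FixtureFormatError",
    "EntrezError",
    "parse_pubmed_xml",
    "read_fixture",
    "write_fixture",
    "fetch_entrez",
]


class CorpusError(Exception):
    """Base class for corpus construction and I/O errors."""


class ParseError(CorpusError):
    """Malformed PubMed XML."""


class FixtureFormatError(CorpusError):
    """Schema violation in the line-delimited fixture format."""


class EntrezError(CorpusError):
    """Entrez retrieval failure after exhausting retries."""


@dataclass(frozen=True)
class MeshHeading:
    """One MeSH heading line: a Main Heading descriptor plus qualifiers.

    Descriptors are compared case-sensitively as provided by the source;
    MeSH is a controlled vocabulary and needs no cleansing.
    """

    descriptor: str
    qualifiers: tuple[str, ...] = ()
    major_topic: bool = False

    def __post_init__(self) -> None:
        if not self.descriptor:
            raise ValueError("MeshHeading descriptor must be non-empty")
        if len(set(self.qualifiers)) != len(self.qualifiers):
            raise ValueError(
                f"duplicate qualifiers on {self.descriptor!r}: {self.qualifiers}"
            )


@dataclass(frozen=True)
class PublicationRecord:
    """One bibliographic record.

    ``headings`` may be empty (the record then contributes to annual counts
    and lifetime measurement but not to MeSH-term analysis).
    """

    pmid: str
    title: str
    year: int
    headings: tuple[MeshHeading, ...] = ()

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")
        if self.year <= 1800:
            raise ValueError(f"implausible year {self.year} for pmid {self.pmid}")

    @property
    def descriptors(self) -> frozenset[str]:
        """Distinct Main Heading descriptors (qualifiers ignored)."""
        return frozenset(h.descriptor for h in self.headings)


@dataclass(frozen=True)
class ParseReport:
    """Accounting of a PubMed XML parse: every citation is either parsed
    or attributed to exactly one drop reason."""

    n_citations: int = 0
    n_parsed: int = 0
    n_dropped_no_year: int = 0
    n_dropped_no_pmid: int = 0
    n_dropped_duplicate_pmid: int = 0

    @property
    def n_dropped(self) -> int:
        return (
            self.n_dropped_no_year
            + self.n_dropped_no_pmid
            + self.n_dropped_duplicate_pmid
        )


@dataclass
class Corpus:
    """A set of publication records with unique PMIDs."""

    records: list[PublicationRecord] = field(default_factory=list)
    provenance: str = ""
    report: ParseReport | None = None

    def __post_init__(self) -> None:
        pmids = [r.pmid for r in self.records]
        if len(set(pmids)) != len(pmids):
            seen: set[str] = set()
            dup = next(p for p in pmids if p in seen or seen.add(p))
            raise ValueError(f"duplicate pmid in corpus: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PublicationRecord]:
        return iter(self.records)

    def restrict_years(self, first: int, last: int) -> "Corpus":
        """Records with ``first <= year <= last`` (both inclusive)."""
        kept = [r for r in self.records if first <= r.year <= last]
        return Corpus(kept, provenance=f"{self.provenance} [{first}-{last}]")


# ---------------------------------------------------------------------------
# PubMed XML


def _text(elem: etree._Element | None) -> str:
    if elem is None:
        return ""
    return "".join(elem.itertext()).strip()


_MEDLINE_DATE_YEAR = re.compile(r"\b(1[89]\d\d|20\d\d)\b")


def _resolve_year(citation: etree._Element) -> int | None:
    """Publication calendar year for a MedlineCitation.

    Preference order: Article PubDate <Year>; leading four-digit year of
    <MedlineDate>; DateCompleted <Year>.  Records resolving to none are
    dropped by the caller.  The chain is a package choice — MEDLINE does
    not designate a single canonical year field.
    """
    pubdate = citation.find("Article/Journal/JournalIssue/PubDate")
    if pubdate is not None:
        year = _text(pubdate.find("Year"))
        if year.isdigit():
            return int(year)
        m = _MEDLINE_DATE_YEAR.search(_text(pubdate.find("MedlineDate")))
        if m:
            return int(m.group(1))
    completed = _text(citation.find("DateCompleted/Year"))
    if completed.isdigit():
        return int(completed)
    return None


def _parse_heading(elem: etree._Element) -> MeshHeading | None:
    dname = elem.find("DescriptorName")
    descriptor = _text(dname)
    if not descriptor:
        return None
    major = (dname.get("MajorTopicYN", "N") == "Y") if dname is not None else False
    qualifiers: list[str] = []
    for q in elem.findall("QualifierName"):
        qt = _text(q)
        if qt and qt not in qualifiers:
            qualifiers.append(qt)
    return MeshHeading(descriptor, tuple(qualifiers), major)


def parse_pubmed_xml(source) -> Corpus:
    """Parse a PubMed XML export into a :class:`Corpus`.

    ``source`` is a path, file object or bytes containing a
    ``PubmedArticleSet`` or ``MedlineCitationSet`` document.  One record is
    produced per citation; records without a resolvable year are dropped
    and accounted for in ``corpus.report``.  Zero citations is a warning,
    not an error.
    """
    if isinstance(source, bytes):
        source = BytesIO(source)
    elif isinstance(source, str) and source.lstrip().startswith("<"):
        source = BytesIO(source.encode("utf-8"))
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise ParseError(
            f"malformed XML at line {exc.position[0]}, column {exc.position[1]}: {exc.msg}"
        ) from exc

    citations = tree.findall(".//MedlineCitation")
    n_no_year = n_no_pmid = n_dup = 0
    records: list[PublicationRecord] = []
    seen: set[str] = set()
    for citation in citations:
        pmid = _text(citation.find("PMID"))
        if not pmid:
            n_no_pmid += 1
            continue
        if pmid in seen:
            n_dup += 1
            continue
        year = _resolve_year(citation)
        if year is None:
            n_no_year += 1
            continue
        title = _text(citation.find("Article/ArticleTitle"))
        headings = tuple(
            h
            for elem in citation.findall("MeshHeadingList/MeshHeading")
            if (h := _parse_heading(elem)) is not None
        )
        records.append(PublicationRecord(pmid, title, year, headings))
        seen.add(pmid)

    if not citations:
        warnings.warn("PubMed XML document contains no citations", stacklevel=2)
    report = ParseReport(
        n_citations=len(citations),
        n_parsed=len(records),
        n_dropped_no_year=n_no_year,
        n_dropped_no_pmid=n_no_pmid,
        n_dropped_duplicate_pmid=n_dup,
    )
    return Corpus(records, provenance="pubmed-xml", report=report)


# ---------------------------------------------------------------------------
# Line-delimited fixture format
#
# One JSON object per line:
#   {"pmid": "1", "year": 2016, "title": "...",
#    "headings": [{"descriptor": "...", "qualifiers": [...], "major": false}]}

_REQUIRED_KEYS = ("pmid", "year", "title")


def write_fixture(corpus: Corpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in corpus.records:
            obj = {
                "pmid": r.pmid,
                "year": r.year,
                "title": r.title,
                "headings": [
                    {
                        "descriptor": h.descriptor,
                        "qualifiers": list(h.qualifiers),
                        "major": h.major_topic,
                    }
                    for h in r.headings
                ],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_fixture(path) -> Corpus:
    records: list[PublicationRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FixtureFormatError(f"line {lineno}: invalid JSON: {exc}") from exc
            for key in _REQUIRED_KEYS:
                if key not in obj:
                    raise FixtureFormatError(f"line {lineno}: missing {key}")
            try:
                headings = tuple(
                    MeshHeading(
                        h["descriptor"],
                        tuple(h.get("qualifiers", ())),
                        bool(h.get("major", False)),
                    )
                    for h in obj.get("headings", ())
                )
                records.append(
                    PublicationRecord(obj["pmid"], obj["title"], int(obj["year"]), headings)
                )
            except (ValueError, KeyError, TypeError) as exc:
                raise FixtureFormatError(f"line {lineno}: {exc}") from exc
    return Corpus(records, provenance=str(path))


# ---------------------------------------------------------------------------
# Entrez retrieval (optional; never exercised by the offline test suite)


def _default_esearch(query: str, contact: dict) -> list[str]:
    from Bio import Entrez  # imported lazily: network-only path

    Entrez.email = contact.get("email", "")
    Entrez.tool = contact.get("tool", "meshnet")
    with Entrez.esearch(db="pubmed", term=query, retmax=100_000) as handle:
        result = Entrez.read(handle)
    return list(result["IdList"])


def _default_efetch(ids: Sequence[str], contact: dict) -> bytes:
    from Bio import Entrez

    Entrez.email = contact.get("email", "")
    Entrez.tool = contact.get("tool", "meshnet")
    with Entrez.efetch(db="pubmed", id=",".join(ids), retmode="xml") as handle:
        return handle.read()


def fetch_entrez(
    query: str,
    contact: dict,
    *,
    page_size: int = 100,
    max_attempts: int = 3,
    esearch: Callable[[str, dict], list[str]] | None = None,
    efetch: Callable[[Sequence[str], dict], bytes] | None = None,
) -> Corpus:
    """Retrieve all records matching a PubMed query, paged politely.

    ``esearch``/``efetch`` are injectable so the retrieval logic (paging,
    retries, never-partial results) is testable against a local mock.
    Each page is retried up to ``max_attempts`` times; any page failing
    all attempts aborts the whole fetch — no silent partial corpus.
    """
    if not query:
        raise ValueError("query must be non-empty")
    esearch = esearch or _default_esearch
    efetch = efetch or _default_efetch

    ids = esearch(query, contact)
    records: list[PublicationRecord] = []
    for start in range(0, len(ids), page_size):
        page = ids[start : start + page_size]
        last_exc: Exception | None = None
        for attempt in range(1, max_attempts + 1):
            try:
                xml = efetch(page, contact)
                records.extend(parse_pubmed_xml(xml).records)
                break
            except (OSError, ParseError) as exc:  # retryable service failures
                last_exc = exc
        else:
            raise EntrezError(
                f"page at offset {start} failed after {max_attempts} attempts: {last_exc}"
            ) from last_exc
    return Corpus(records, provenance=f"entrez:{query}")
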