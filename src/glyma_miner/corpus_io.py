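"""Reading, writing and validating PubMed-style corpora.

A corpus is an ordered collection of :class:`PubMedRecord` objects, one per
PubMed citation, carrying the four fields the downstream text-mining stages
need: PMID, publication year, title and abstract.  Two on-disk dialects are
supported: NCBI's ``PubmedArticleSet`` XML (the format EFetch returns) and a
flat CSV with header ``pmid,year,title,abstract``.

Records without an abstract are retained — they still carry countable
metadata — and their ``abstract`` attribute is ``None``, never the empty
string.  Duplicate PMIDs are a hard error: a corpus whose provenance is
ambiguous is not silently deduplicated.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

logger = logging.getLogger(__name__)

__all__ = [
    "PubMedRecord",
    "Corpus",
    "CorpusFormatError",
    "DuplicatePmidError",
    "build_query",
    "parse_pubmed_xml",
    "read_csv_corpus",
    "write_csv_corpus",
    "write_pubmed_xml",
]

CSV_COLUMNS = ("pmid", "year", "title", "abstract")

_MONTHS = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)


class CorpusFormatError(ValueError):
    """Malformed or schema-violating corpus input."""


class DuplicatePmidError(CorpusFormatError):
    """The same PMID occurs more than once in one corpus."""

    def __init__(self, pmid: str):
        super().__init__(f"duplicate PMID in corpus: {pmid}")
        self.pmid = pmid


@dataclass(frozen=True)
class PubMedRecord:
    """One PubMed citation reduced to the fields the pipeline consumes.

    Parameters
    ----------
    pmid
        PubMed identifier, a nonempty digit string.
    year
        Publication year, or ``None`` when no year could be parsed.
    title
        Article title (may be empty).
    abstract
        Abstract text, or ``None`` for records that have no abstract.
    """

    pmid: str
    year: int | None = None
    title: str = ""
    abstract: str | None = None

    def __post_init__(self) -> None:
        if not self.pmid or not self.pmid.isdigit():
            raise CorpusFormatError(f"pmid must be a nonempty digit string, got {self.pmid!r}")
        if self.year is not None and not (1900 <= self.year <= 2100):
            raise CorpusFormatError(f"implausible publication year {self.year} for PMID {self.pmid}")
        if self.abstract == "":
            # canonical representation of "no abstract" is None
            object.__setattr__(self, "abstract", None)

    @property
    def text(self) -> str:
        """Concatenated title and abstract, the unit of text mining."""
        if self.abstract is None:
            return self.title
        return f"{self.title} {self.abstract}"


@dataclass
class Corpus:
    """Ordered, PMID-unique collection of records plus a provenance note."""

    records: list[PubMedRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.pmid in seen:
                raise DuplicatePmidError(rec.pmid)
            seen.add(rec.pmid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PubMedRecord]:
        return iter(self.records)

    def __getitem__(self, idx: int) -> PubMedRecord:
        return self.records[idx]


def build_query(term: str, date_start: _dt.date, date_end: _dt.date) -> str:
    """Render a PubMed query for *term* in Title/Abstract within a date window.

    The query uses PubMed's bracketed field syntax, with the publication-date
    range written as day-month-year (no leading zero on the day), e.g.::

        ("Glyma" [Title/Abstract]) AND ("1 December 2006" [Date-Publication]
        : "31 December 2025" [Date-Publication])

    Raises
    ------
    ValueError
        If ``date_start`` is after ``date_end``.
    """
    if isinstance(date_start, str):
        date_start = _dt.date.fromisoformat(date_start)
    if isinstance(date_end, str):
        date_end = _dt.date.fromisoformat(date_end)
    if date_start > date_end:
        raise ValueError(f"date_start {date_start} is after date_end {date_end}")

    def fmt(d: _dt.date) -> str:
        return f"{d.day} {_MONTHS[d.month - 1]} {d.year}"

    return (
        f'("{term}" [Title/Abstract]) AND '
        f'("{fmt(date_start)}" [Date-Publication]: "{fmt(date_end)}" [Date-Publication])'
    )


_WS_RUN = re.compile(r"\s+")


def _clean_text(element: ET.Element | None) -> str:
    """Flatten an element to plain text: strip markup, collapse whitespace.

    Inline markup (``<i>Glyma</i>``...) must not split identifier tokens, so
    all descendant text is joined with no separator before whitespace runs
    are collapsed.
    """
    if element is None:
        return ""
    return _WS_RUN.sub(" ", "".join(element.itertext())).strip()


_YEAR_IN_TEXT = re.compile(r"(?<!\d)(\d{4})(?!\d)")


def _parse_year(article: ET.Element) -> int | None:
    """Publication year: PubDate/Year preferred, MedlineDate fallback."""
    pubdate = article.find(".//Journal/JournalIssue/PubDate")
    if pubdate is None:
        pubdate = article.find(".//PubDate")
    if pubdate is None:
        return None
    year_el = pubdate.find("Year")
    if year_el is not None and year_el.text and year_el.text.strip().isdigit():
        return int(year_el.text.strip())
    medline = pubdate.find("MedlineDate")
    if medline is not None and medline.text:
        m = _YEAR_IN_TEXT.search(medline.text)
        if m:
            return int(m.group(1))
    return None


def parse_pubmed_xml(source: Union[str, Path, IO[bytes], IO[str]],
                     provenance: str | None = None) -> Corpus:
    """Parse a ``PubmedArticleSet`` XML document into a :class:`Corpus`.

    One record is produced per ``PubmedArticle`` element carrying a PMID;
    articles without a PMID are skipped with a logged warning.  Records
    lacking an ``AbstractText`` are retained with ``abstract = None``; a
    structured abstract's sections are concatenated with single spaces.

    Parameters
    ----------
    source
        Path to an XML file, or an open file-like object.
    provenance
        Free-text provenance note; defaults to the file path.

    Raises
    ------
    CorpusFormatError
        On malformed XML (the message names the line/column position) or
        duplicate PMIDs.
    """
    if provenance is None:
        provenance = str(source) if isinstance(source, (str, Path)) else "<stream>"
    try:
        tree = ET.parse(source)
    except ET.ParseError as exc:
        raise CorpusFormatError(
            f"malformed PubMed XML at line {exc.position[0]}, column {exc.position[1]}: {exc}"
        ) from exc

    root = tree.getroot()
    records: list[PubMedRecord] = []
    for article in root.iter("PubmedArticle"):
        pmid_el = article.find(".//MedlineCitation/PMID")
        if pmid_el is None:
            pmid_el = article.find(".//PMID")
        pmid = (pmid_el.text or "").strip() if pmid_el is not None else ""
        if not pmid:
            logger.warning("skipping PubmedArticle without a PMID")
            continue
        title = _clean_text(article.find(".//ArticleTitle"))
        sections = [_clean_text(el) for el in article.findall(".//Abstract/AbstractText")]
        sections = [s for s in sections if s]
        abstract = " ".join(sections) if sections else None
        records.append(PubMedRecord(pmid=pmid, year=_parse_year(article),
                                    title=title, abstract=abstract))
    return Corpus(records=records, provenance=provenance)


def read_csv_corpus(path: Union[str, Path], provenance: str | None = None) -> Corpus:
    """Read the flat CSV corpus dialect (``pmid,year,title,abstract``).

    Empty ``year``/``abstract`` cells become ``None``; the write/read cycle
    is the identity on records.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise CorpusFormatError(
                f"corpus CSV {path} is missing required column(s): {', '.join(missing)}"
            )
        records = []
        for row in reader:
            year = row["year"].strip() if row["year"] else ""
            records.append(PubMedRecord(
                pmid=(row["pmid"] or "").strip(),
                year=int(year) if year else None,
                title=row["title"] or "",
                abstract=row["abstract"] or None,
            ))
    return Corpus(records=records, provenance=provenance or str(path))


def write_csv_corpus(corpus: Corpus | Iterable[PubMedRecord], path: Union[str, Path]) -> None:
    """Write records to the CSV corpus dialect; absent fields as empty cells."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in corpus:
            writer.writerow([
                rec.pmid,
                "" if rec.year is None else rec.year,
                rec.title,
                "" if rec.abstract is None else rec.abstract,
            ])


def write_pubmed_xml(corpus: Corpus | Iterable[PubMedRecord], path: Union[str, Path]) -> None:
    """Serialize records as a minimal ``PubmedArticleSet`` document.

    Emits only the elements :func:`parse_pubmed_xml` consumes (PMID,
    PubDate/Year, ArticleTitle, AbstractText), which is enough to round-trip
    a corpus through the XML reader.
    """
    root = ET.Element("PubmedArticleSet")
    for rec in corpus:
        art = ET.SubElement(root, "PubmedArticle")
        cit = ET.SubElement(art, "MedlineCitation")
        ET.SubElement(cit, "PMID").text = rec.pmid
        article = ET.SubElement(cit, "Article")
        journal = ET.SubElement(article, "Journal")
        issue = ET.SubElement(journal, "JournalIssue")
        pubdate = ET.SubElement(issue, "PubDate")
        if rec.year is not None:
            ET.SubElement(pubdate, "Year").text = str(rec.year)
        ET.SubElement(article, "ArticleTitle").text = rec.title
        if rec.abstract is not None:
            abstract = ET.SubElement(article, "Abstract")
            ET.SubElement(abstract, "AbstractText").text = rec.abstract
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)
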