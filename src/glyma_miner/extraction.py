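"""Rule-based recognition of standardized *Glyma* gene identifiers.

Soybean (Glycine max) genes in the Wm82.a2 assembly are named
``Glyma.<cc>G<nnnnnn>`` where ``<cc>`` is the two-digit chromosome number
(01-20) and ``<nnnnnn>`` the gene number, optionally followed by a
transcript/version suffix such as ``.1``.  Because the nomenclature is this
rigid, a small regular-expression grammar extracts mentions with essentially
no ambiguity — no trained model is needed.

Grammar decisions
-----------------
* ``Glyma`` and the ``G`` separator match case-insensitively; the canonical
  rendering fixes casing so case variants collapse to one gene.
* Gene numbers of 5 or 6 digits are accepted (published identifiers carry 6,
  but the 5-digit reading also occurs in the wild).
* Matches must be bounded by non-alphanumeric context on both sides, so
  identifiers embedded in longer tokens (``xGlyma.03G227300``) do not match.
* A match whose chromosome field falls outside 01-20 (scaffolds, typos) is
  rejected and reported in the rejection log rather than silently dropped.
* Version suffixes are captured but stripped from the canonical form:
  ``Glyma.06G095100.1`` and ``Glyma.06G095100`` are the same gene.
* Legacy Wm82.a1 identifiers (dot-free, e.g. ``Glyma13g12340``) are outside
  the grammar; an opt-in flag matches them and tags them distinctly.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from .corpus_io import Corpus, PubMedRecord

__all__ = [
    "GeneMention",
    "RejectedToken",
    "ExtractionResult",
    "AbstractProfile",
    "GrammarError",
    "GENE_PATTERN",
    "LEGACY_PATTERN",
    "extract_mentions",
    "scan_text",
    "canonicalize",
    "chromosome_of",
    "profile_record",
    "profile_corpus",
    "write_mention_table",
]

N_CHROMOSOMES = 20

# Wm82.a2 grammar: Glyma . <2-digit chromosome> G <5-6 digit gene number>
# [. <1-2 digit version>], bounded by non-alphanumeric context.
GENE_PATTERN = re.compile(
    r"(?<![A-Za-z0-9])"
    r"(?P<prefix>[Gg][Ll][Yy][Mm][Aa])\.(?P<chrom>\d{2})(?P<sep>[Gg])(?P<gene>\d{5,6})"
    r"(?:\.(?P<version>\d{1,2}))?"
    r"(?![A-Za-z0-9])"
)

# Wm82.a1 legacy grammar: dot-free, 2-digit chromosome + lowercase g + 5 digits.
LEGACY_PATTERN = re.compile(
    r"(?<![A-Za-z0-9])"
    r"(?P<prefix>[Gg][Ll][Yy][Mm][Aa])(?P<chrom>\d{2})(?P<sep>[Gg])(?P<gene>\d{5})"
    r"(?![A-Za-z0-9])"
)


class GrammarError(ValueError):
    """Input does not match the Glyma identifier grammar."""


@dataclass(frozen=True)
class GeneMention:
    """One matched identifier occurrence in a piece of text.

    ``start``/``end`` are 0-based, half-open character offsets into the
    source text, so ``text[start:end] == raw``.
    """

    raw: str
    canonical: str
    chromosome: int
    gene_number: str
    version: str | None
    start: int
    end: int
    legacy: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.chromosome <= N_CHROMOSOMES):
            raise GrammarError(f"chromosome {self.chromosome} outside 1..{N_CHROMOSOMES}")
        if self.end <= self.start:
            raise ValueError("empty mention span")


@dataclass(frozen=True)
class RejectedToken:
    """A grammar-shaped token refused by a validity rule (with the reason)."""

    raw: str
    reason: str
    start: int
    end: int


@dataclass
class ExtractionResult:
    """Mentions plus the audit trail of rejected tokens."""

    mentions: list[GeneMention] = field(default_factory=list)
    rejections: list[RejectedToken] = field(default_factory=list)


def _canonical_from(chrom: str, gene: str, legacy: bool = False) -> str:
    if legacy:
        return f"Glyma{chrom}g{gene}"
    return f"Glyma.{chrom}G{gene}"


def scan_text(text: str, include_legacy: bool = False) -> ExtractionResult:
    """Scan *text* for identifier-grammar matches, left to right.

    Returns every non-overlapping match in order of appearance.  Matches
    whose chromosome field is outside 01-20 are diverted to the rejection
    log.  With ``include_legacy`` the dot-free Wm82.a1 grammar is also
    applied and its matches are tagged ``legacy=True``.
    """
    result = ExtractionResult()
    matches: list[tuple[re.Match, bool]] = [(m, False) for m in GENE_PATTERN.finditer(text)]
    if include_legacy:
        matches += [(m, True) for m in LEGACY_PATTERN.finditer(text)]
        matches.sort(key=lambda pair: pair[0].start())
    for m, legacy in matches:
        chrom = int(m.group("chrom"))
        if not (1 <= chrom <= N_CHROMOSOMES):
            result.rejections.append(RejectedToken(
                raw=m.group(0),
                reason=f"chromosome field {m.group('chrom')} outside 01-{N_CHROMOSOMES}",
                start=m.start(), end=m.end(),
            ))
            continue
        result.mentions.append(GeneMention(
            raw=m.group(0),
            canonical=_canonical_from(m.group("chrom"), m.group("gene"), legacy),
            chromosome=chrom,
            gene_number=m.group("gene"),
            version=m.group("version") if not legacy else None,
            start=m.start(), end=m.end(),
            legacy=legacy,
        ))
    return result


def extract_mentions(text: str, include_legacy: bool = False) -> list[GeneMention]:
    """All accepted identifier mentions in *text*, in order of appearance."""
    return scan_text(text, include_legacy=include_legacy).mentions


def canonicalize(raw: str) -> str:
    """Normalize one identifier: fixed casing, version suffix removed.

    >>> canonicalize("glyma.18g022500")
    'Glyma.18G022500'
    >>> canonicalize("Glyma.14G194300.2")
    'Glyma.14G194300'
    """
    m = GENE_PATTERN.fullmatch(raw.strip())
    if m is None:
        raise GrammarError(f"not a Glyma identifier: {raw!r}")
    chrom = int(m.group("chrom"))
    if not (1 <= chrom <= N_CHROMOSOMES):
        raise GrammarError(f"chromosome field {m.group('chrom')} outside 01-{N_CHROMOSOMES}")
    return _canonical_from(m.group("chrom"), m.group("gene"))


def chromosome_of(canonical: str) -> int:
    """Chromosome number (1..20) embedded in a canonical identifier."""
    m = GENE_PATTERN.fullmatch(canonical)
    if m is None:
        raise GrammarError(f"not a Glyma identifier: {canonical!r}")
    chrom = int(m.group("chrom"))
    if not (1 <= chrom <= N_CHROMOSOMES):
        raise GrammarError(f"chromosome field {m.group('chrom')} outside 01-{N_CHROMOSOMES}")
    return chrom


@dataclass
class AbstractProfile:
    """Per-record mention accounting: raw totals and the unique gene set."""

    pmid: str
    year: int | None
    total_mentions: int
    unique_genes: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.unique_genes) > self.total_mentions:
            raise ValueError("unique gene count cannot exceed total mentions")

    @property
    def n_unique(self) -> int:
        return len(self.unique_genes)


def profile_record(record: PubMedRecord, include_legacy: bool = False) -> AbstractProfile:
    """Extract mentions from a record's concatenated title and abstract.

    The unit of extraction is ``title + " " + abstract`` (absent abstract
    treated as empty), so identifiers appearing only in the title are still
    found.  Uniqueness is on suffix-stripped canonical forms.
    """
    mentions = extract_mentions(record.text, include_legacy=include_legacy)
    return AbstractProfile(
        pmid=record.pmid,
        year=record.year,
        total_mentions=len(mentions),
        unique_genes=frozenset(m.canonical for m in mentions),
    )


def profile_corpus(corpus: Corpus | Iterable[PubMedRecord],
                   include_legacy: bool = False,
                   ) -> tuple[list[AbstractProfile], list[RejectedToken]]:
    """Profile every record; also collect corpus-wide token rejections."""
    profiles: list[AbstractProfile] = []
    rejections: list[RejectedToken] = []
    for rec in corpus:
        res = scan_text(rec.text, include_legacy=include_legacy)
        profiles.append(AbstractProfile(
            pmid=rec.pmid,
            year=rec.year,
            total_mentions=len(res.mentions),
            unique_genes=frozenset(m.canonical for m in res.mentions),
        ))
        rejections.extend(res.rejections)
    return profiles, rejections


def write_mention_table(corpus: Corpus | Iterable[PubMedRecord],
                        path: Union[str, Path],
                        include_legacy: bool = False) -> int:
    """Export per-record mentions as CSV; returns the number of rows written.

    Columns: ``pmid,raw,canonical,chromosome,version,start,end``.
    """
    n = 0
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pmid", "raw", "canonical", "chromosome", "version", "start", "end"])
        for rec in corpus:
            for m in extract_mentions(rec.text, include_legacy=include_legacy):
                writer.writerow([rec.pmid, m.raw, m.canonical, m.chromosome,
                                 m.version or "", m.start, m.end])
                n += 1
    return n
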