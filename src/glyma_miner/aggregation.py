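"""Corpus-level accounting of gene mentions.

All aggregates consume :class:`~glyma_miner.extraction.AbstractProfile`
objects, i.e. they operate on per-abstract *unique* gene sets.  The default
counting convention is gene x abstract pairs: a gene contributes once per
abstract containing it, and abstracts are counted independently, so the same
gene appearing in k abstracts adds k to its chromosome's total.  The
alternative convention — corpus-distinct genes per chromosome — is exposed
via a flag, because bar-chart summaries of "distinct identifiers per
chromosome" are ambiguous between the two readings.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .extraction import AbstractProfile, N_CHROMOSOMES, chromosome_of

__all__ = [
    "GenesPerAbstract",
    "ChromYearMatrix",
    "GeneRanking",
    "TailSummary",
    "EmptyAnalysisError",
    "genes_per_abstract",
    "chromosome_totals",
    "year_chromosome_matrix",
    "rank_genes",
    "tail_summary",
]


class EmptyAnalysisError(ValueError):
    """No identifier-bearing abstracts: nothing to aggregate."""


class GenesPerAbstract(NamedTuple):
    """Distribution of unique-gene counts over identifier-bearing abstracts."""

    histogram: dict[int, int]
    median: int
    maximum: int


def _lower_median(values: Sequence[int]) -> int:
    """Median with the lower-median convention for even-sized sets.

    Keeps the statistic integer-valued on integer data.
    """
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def genes_per_abstract(profiles: Iterable[AbstractProfile]) -> GenesPerAbstract:
    """Histogram, median and maximum of unique genes per abstract.

    Restricted to the analysis set: profiles with at least one gene.
    Abstracts without identifiers carry no information about how many genes
    identifier-using studies report, so they are excluded here (they remain
    part of corpus-level prevalence summaries).
    """
    counts = [p.n_unique for p in profiles if p.n_unique > 0]
    if not counts:
        raise EmptyAnalysisError("no identifier-bearing abstracts in the corpus")
    hist = dict(sorted(Counter(counts).items()))
    return GenesPerAbstract(histogram=hist, median=_lower_median(counts), maximum=max(counts))


def chromosome_totals(profiles: Iterable[AbstractProfile],
                      distinct_genes: bool = False) -> np.ndarray:
    """Unique-mention counts per chromosome as a length-20 integer vector.

    Index 0 is chromosome 1.  By default counts gene x abstract pairs; with
    ``distinct_genes=True`` each corpus-distinct gene counts once regardless
    of how many abstracts mention it.
    """
    totals = np.zeros(N_CHROMOSOMES, dtype=np.int64)
    if distinct_genes:
        genes: set[str] = set()
        for p in profiles:
            genes.update(p.unique_genes)
        for g in genes:
            totals[chromosome_of(g) - 1] += 1
    else:
        for p in profiles:
            for g in p.unique_genes:
                totals[chromosome_of(g) - 1] += 1
    return totals


@dataclass
class ChromYearMatrix:
    """20 x Y chromosome-by-year counts with per-year percentage columns.

    ``percent[:, j]`` rescales column j to sum to 100; columns with a zero
    total stay all-zero.  ``n_year_absent`` records how many profiles were
    excluded for lacking a publication year.
    """

    years: list[int]
    counts: np.ndarray
    percent: np.ndarray = field(init=False)
    n_year_absent: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CHROMOSOMES, len(self.years)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({N_CHROMOSOMES}, {len(self.years)})"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        col_totals = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / col_totals
        pct[:, col_totals == 0] = 0.0
        self.percent = pct

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.chromosome_index(), columns=self.years)

    def percent_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.percent, index=self.chromosome_index(), columns=self.years)

    @staticmethod
    def chromosome_index() -> pd.Index:
        return pd.Index(range(1, N_CHROMOSOMES + 1), name="chromosome")

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (chromosome, year) with count and percent."""
        rows = [
            (c + 1, y, int(self.counts[c, j]), float(self.percent[c, j]))
            for j, y in enumerate(self.years)
            for c in range(N_CHROMOSOMES)
        ]
        return pd.DataFrame(rows, columns=["chromosome", "year", "count", "percent"])


def year_chromosome_matrix(profiles: Iterable[AbstractProfile]) -> ChromYearMatrix:
    """Chromosome totals partitioned by publication year.

    Profiles with no year are excluded (and tallied in ``n_year_absent``);
    they still count in whole-corpus totals elsewhere.
    """
    profiles = list(profiles)
    dated = [p for p in profiles if p.year is not None]
    n_absent = len(profiles) - len(dated)
    years = sorted({p.year for p in dated})
    counts = np.zeros((N_CHROMOSOMES, len(years)), dtype=np.int64)
    col = {y: j for j, y in enumerate(years)}
    for p in dated:
        for g in p.unique_genes:
            counts[chromosome_of(g) - 1, col[p.year]] += 1
    return ChromYearMatrix(years=years, counts=counts, n_year_absent=n_absent)


@dataclass
class GeneRanking:
    """Genes ordered by the number of abstracts mentioning them.

    Descending by abstract count, ties broken by identifier ascending.
    """

    entries: list[tuple[str, int]]

    def __post_init__(self) -> None:
        for _, n in self.entries:
            if n < 1:
                raise ValueError("abstract counts in a ranking must be >= 1")
        expected = sorted(self.entries, key=lambda e: (-e[1], e[0]))
        if self.entries != expected:
            raise ValueError("ranking entries are not in ranking order")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene", "n_abstracts"])


def rank_genes(profiles: Iterable[AbstractProfile], k: int | None = None) -> GeneRanking:
    """Top-k genes by number of abstracts mentioning them.

    A gene's score is the number of profiles whose unique set contains it —
    repeat mentions within one abstract do not inflate it.  ``k=None`` (or k
    exceeding the number of distinct genes) returns the full ranking.
    """
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    counter: Counter[str] = Counter()
    for p in profiles:
        counter.update(p.unique_genes)
    ordered = sorted(counter.items(), key=lambda e: (-e[1], e[0]))
    return GeneRanking(entries=ordered[:k] if k is not None else ordered)


class TailSummary(NamedTuple):
    """How much of the ranking lives in the sparsely-mentioned tail."""

    n_genes_total: int
    n_genes_low: int     # mentioned in at most two abstracts
    fraction: float


def tail_summary(ranking: GeneRanking) -> TailSummary:
    """Count genes mentioned in only one or two abstracts and their share."""
    if not ranking.entries:
        raise EmptyAnalysisError("cannot summarize an empty ranking")
    total = len(ranking.entries)
    low = sum(1 for _, n in ranking.entries if n <= 2)
    return TailSummary(total, low, low / total)
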