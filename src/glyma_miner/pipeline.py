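"""End-to-end pipeline orchestration and reporting.

``run_pipeline`` drives one full analysis: read a corpus, extract mentions,
aggregate, test chromosome uniformity, and write a run directory containing
tabular outputs, their figure twins, a chi-square record, a run log and a
manifest.  Every figure has a CSV twin holding exactly the plotted numbers;
figures themselves are content-checked only through those twins.

``summarize`` produces the headline corpus metrics (record counts,
identifier prevalence as a half-up-rounded percentage, median and maximum
unique genes per identifier-bearing abstract).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import seaborn as sns

from . import aggregation, stats
from .corpus_io import Corpus, parse_pubmed_xml, read_csv_corpus
from .extraction import AbstractProfile, profile_corpus

__all__ = ["RunConfig", "SummaryMetrics", "summarize", "run_pipeline", "load_corpus"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 90.15 -> 90.2, not banker's 90.1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SummaryMetrics:
    """Headline corpus metrics."""

    n_records: int
    n_with_identifier: int
    percent_with_identifier: float  # half-up, 1 decimal
    median_unique_genes: int | None
    max_unique_genes: int | None

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_with_identifier": self.n_with_identifier,
            "percent_with_identifier": self.percent_with_identifier,
            "median_unique_genes": self.median_unique_genes,
            "max_unique_genes": self.max_unique_genes,
        }


def _summary_from_profiles(profiles: list[AbstractProfile]) -> SummaryMetrics:
    n = len(profiles)
    bearing = [p for p in profiles if p.n_unique > 0]
    pct = round_half_up(100.0 * len(bearing) / n, 1) if n else 0.0
    if bearing:
        dist = aggregation.genes_per_abstract(bearing)
        med, mx = dist.median, dist.maximum
    else:
        med = mx = None
    return SummaryMetrics(
        n_records=n,
        n_with_identifier=len(bearing),
        percent_with_identifier=pct,
        median_unique_genes=med,
        max_unique_genes=mx,
    )


def summarize(corpus: Corpus, include_legacy: bool = False) -> SummaryMetrics:
    """Headline metrics for a corpus: size, identifier prevalence, per-
    abstract unique-gene median and maximum."""
    profiles, _ = profile_corpus(corpus, include_legacy=include_legacy)
    return _summary_from_profiles(profiles)


def load_corpus(path: Union[str, Path], fmt: str = "auto") -> Corpus:
    """Read a corpus from XML or CSV, sniffing the format by suffix."""
    path = Path(path)
    if fmt == "auto":
        fmt = "xml" if path.suffix.lower() in {".xml", ".nxml"} else "csv"
    if fmt == "xml":
        return parse_pubmed_xml(path)
    if fmt == "csv":
        return read_csv_corpus(path)
    raise ValueError(f"unknown corpus format {fmt!r}")


@dataclass
class RunConfig:
    """One pipeline run: input, output directory, extraction flags."""

    input_path: Union[str, Path]
    out_dir: Union[str, Path]
    input_format: str = "auto"          # "xml" | "csv" | "auto"
    include_legacy: bool = False
    distinct_genes: bool = False        # chromosome counting convention
    top_k: int = 20
    figures: bool = True


def _write_csv(path: Path, header: list[str], rows: Iterable[Iterable]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


def _fig_genes_per_abstract(dist: aggregation.GenesPerAbstract, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(list(dist.histogram), list(dist.histogram.values()), color="#4c72b0")
    ax.set_xlabel("Unique Glyma genes per abstract")
    ax.set_ylabel("Number of abstracts")
    ax.set_title("Distribution of unique gene identifiers per abstract")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _fig_chromosome_totals(totals, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(range(1, 21), totals, color="#55a868")
    ax.set_xticks(range(1, 21))
    ax.set_xlabel("Chromosome")
    ax.set_ylabel("Unique gene mentions")
    ax.set_title("Chromosome-level distribution of gene mentions")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _fig_heatmaps(matrix: aggregation.ChromYearMatrix, path: Path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(14, 6))
    sns.heatmap(matrix.counts_frame(), ax=axes[0], cmap="viridis",
                cbar_kws={"label": "count"})
    axes[0].set_title("Gene mentions per chromosome per year (raw)")
    sns.heatmap(matrix.percent_frame(), ax=axes[1], cmap="viridis",
                cbar_kws={"label": "% of year total"})
    axes[1].set_title("Percent of each year's mentions")
    for ax in axes:
        ax.set_xlabel("Year")
        ax.set_ylabel("Chromosome")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _fig_top_genes(ranking: aggregation.GeneRanking, path: Path) -> None:
    frame = ranking.to_frame()
    fig, ax = plt.subplots(figsize=(7, max(3, 0.3 * len(frame))))
    ax.barh(frame["gene"][::-1], frame["n_abstracts"][::-1], color="#c44e52")
    ax.set_xlabel("Number of abstracts")
    ax.set_title("Most frequently mentioned genes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the output bundle.

    Outputs (all under ``config.out_dir``):

    * ``genes_per_abstract.csv`` (+ ``fig1_genes_per_abstract.png``)
    * ``chromosome_totals.csv`` (+ ``fig2_chromosome_totals.png``)
    * ``year_chromosome.csv`` (+ ``fig3_temporal_heatmaps.png``)
    * ``top_genes.csv`` (+ ``fig4_top_genes.png``)
    * ``chi_square.json`` — uniformity test record
    * ``run_log.json`` — provenance, flags, rejection/exclusion tallies
    * ``manifest.json`` — list of files written

    Returns the manifest as a dict.  Raises on unreadable input or on a
    corpus with no identifier-bearing abstract.
    """
    corpus = load_corpus(config.input_path, config.input_format)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    profiles, rejections = profile_corpus(corpus, include_legacy=config.include_legacy)
    summary = _summary_from_profiles(profiles)
    if summary.n_with_identifier == 0:
        raise aggregation.EmptyAnalysisError(
            "corpus contains no identifier-bearing abstract; nothing to analyze")

    dist = aggregation.genes_per_abstract(profiles)
    totals = aggregation.chromosome_totals(profiles, distinct_genes=config.distinct_genes)
    matrix = aggregation.year_chromosome_matrix(profiles)
    ranking = aggregation.rank_genes(profiles, k=config.top_k)
    full_ranking = aggregation.rank_genes(profiles)
    tail = aggregation.tail_summary(full_ranking)
    chi = stats.chi_square_uniform(totals)

    files: list[str] = []

    def emit_csv(name: str, header: list[str], rows) -> None:
        _write_csv(out / name, header, rows)
        files.append(name)

    emit_csv("genes_per_abstract.csv",
             ["n_unique_genes", "n_abstracts_with_that_count"],
             sorted(dist.histogram.items()))
    emit_csv("chromosome_totals.csv",
             ["chromosome", "total_unique_mentions"],
             [(c + 1, int(totals[c])) for c in range(len(totals))])
    long = matrix.to_long_frame()
    emit_csv("year_chromosome.csv",
             ["chromosome", "year", "count", "percent"],
             long.itertuples(index=False, name=None))
    emit_csv("top_genes.csv", ["gene", "n_abstracts"], ranking.entries)

    (out / "chi_square.json").write_text(
        json.dumps(chi.to_dict(), indent=1), encoding="utf-8")
    files.append("chi_square.json")

    run_log = {
        "provenance": corpus.provenance,
        "flags": {
            "include_legacy": config.include_legacy,
            "distinct_genes": config.distinct_genes,
            "top_k": config.top_k,
        },
        "summary": summary.to_dict(),
        "n_without_identifier": summary.n_records - summary.n_with_identifier,
        "n_rejected_tokens": len(rejections),
        "rejected_tokens": [
            {"raw": r.raw, "reason": r.reason} for r in rejections],
        "n_year_absent_excluded": matrix.n_year_absent,
        "tail": {
            "n_genes_total": tail.n_genes_total,
            "n_genes_in_at_most_two_abstracts": tail.n_genes_low,
            "fraction": tail.fraction,
        },
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1), encoding="utf-8")
    files.append("run_log.json")

    if config.figures:
        _fig_genes_per_abstract(dist, out / "fig1_genes_per_abstract.png")
        _fig_chromosome_totals(totals, out / "fig2_chromosome_totals.png")
        _fig_heatmaps(matrix, out / "fig3_temporal_heatmaps.png")
        _fig_top_genes(ranking, out / "fig4_top_genes.png")
        files += ["fig1_genes_per_abstract.png", "fig2_chromosome_totals.png",
                  "fig3_temporal_heatmaps.png", "fig4_top_genes.png"]

    manifest = {"out_dir": str(out), "files": files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest
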