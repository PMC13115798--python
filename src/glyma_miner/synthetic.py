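"""Synthetic PubMed-like corpora with fully known planted gene mentions.

The generator emulates the shape of the real *Glyma* abstract corpus — a few
hundred records spanning 2006-2025 with a post-2018 publication surge, ~90%
of records carrying at least one identifier, a right-skewed number of unique
genes per abstract (median 1, tail to ~14), non-uniform chromosome usage,
occasional missing abstracts, and noise tokens that probe each grammar
boundary (out-of-range chromosome fields, legacy dot-free identifiers, and
identifiers embedded in longer tokens).

Every planted mention is recorded in a :class:`GroundTruth` with its exact
canonical form and character span, so the extraction and aggregation stages
can be tested for exact recovery: decoys must never leak into counts, and
planted mentions must never be missed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence, Union

import numpy as np

from .corpus_io import Corpus, PubMedRecord
from .extraction import N_CHROMOSOMES

__all__ = [
    "CorpusConfig",
    "PlantedMention",
    "PlantedRecord",
    "GroundTruth",
    "default_paper_config",
    "generate",
]

# Chromosome sampling weights: usage elevated on chromosomes 2, 3, 6, 13, 16
# and 18, depressed on 1, 10, 11 and 20, mirroring the uneven literature
# representation of the soybean genome.
_ELEVATED = (2, 3, 6, 13, 16, 18)
_DEPRESSED = (1, 10, 11, 20)


def _default_chromosome_weights() -> tuple[float, ...]:
    w = np.ones(N_CHROMOSOMES)
    w[[c - 1 for c in _ELEVATED]] = 1.9
    w[[c - 1 for c in _DEPRESSED]] = 0.55
    return tuple(w / w.sum())


def _default_year_weights(year_start: int, year_end: int) -> tuple[float, ...]:
    """Publication volume rising steeply after 2018, sparse before 2015."""
    w = []
    for y in range(year_start, year_end + 1):
        if y < 2015:
            w.append(0.2)
        elif y < 2018:
            w.append(0.5)
        else:
            w.append(1.0 + 0.8 * (y - 2017))
    arr = np.asarray(w, dtype=float)
    return tuple(arr / arr.sum())


@dataclass(frozen=True)
class CorpusConfig:
    """Parameters of the synthetic corpus.

    Defaults approximate the real corpus: 377 records over 2006-2025, 90%
    identifier prevalence, zero-truncated geometric unique-genes-per-abstract
    counts (continuation probability 0.45 puts the median strictly at 1)
    capped at 14, and
    the elevated/depressed chromosome weights above.
    """

    n_records: int = 377
    year_start: int = 2006
    year_end: int = 2025
    year_weights: tuple[float, ...] | None = None
    p_has_identifier: float = 0.9
    gpa_continue: float = 0.45       # P(k+1 genes | >= k genes), zero-truncated geometric
    gpa_max: int = 14
    chromosome_weights: tuple[float, ...] = field(default_factory=_default_chromosome_weights)
    p_missing_abstract: float = 0.05
    p_gene_reuse: float = 0.15       # chance a planted gene is drawn from earlier records
    p_repeat_mention: float = 0.3    # chance a planted gene gets a second in-record mention
    p_version_suffix: float = 0.2    # chance a mention carries a ".N" transcript suffix
    noise_out_of_range: float = 0.10   # expected decoys per record, Poisson
    noise_legacy: float = 0.10
    noise_lookalike: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.year_start > self.year_end:
            raise ValueError("year_start after year_end")
        for name in ("p_has_identifier", "gpa_continue", "p_missing_abstract",
                     "p_gene_reuse", "p_repeat_mention", "p_version_suffix"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        w = np.asarray(self.chromosome_weights, dtype=float)
        if w.shape != (N_CHROMOSOMES,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("chromosome_weights must be 20 nonnegative values summing to 1")
        if self.year_weights is not None:
            yw = np.asarray(self.year_weights, dtype=float)
            n_years = self.year_end - self.year_start + 1
            if yw.shape != (n_years,) or (yw < 0).any() or abs(yw.sum() - 1.0) > 1e-9:
                raise ValueError(f"year_weights must be {n_years} nonnegative values summing to 1")
        if not (1 <= self.gpa_max):
            raise ValueError("gpa_max must be >= 1")
        for name in ("noise_out_of_range", "noise_legacy", "noise_lookalike"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def resolved_year_weights(self) -> tuple[float, ...]:
        if self.year_weights is not None:
            return self.year_weights
        return _default_year_weights(self.year_start, self.year_end)


def default_paper_config(seed: int = 0) -> CorpusConfig:
    """The documented default configuration emulating the real corpus shape."""
    return CorpusConfig(seed=seed)


class PlantedMention(NamedTuple):
    """One planted identifier occurrence, in title+abstract coordinates."""

    canonical: str
    raw: str
    chromosome: int
    start: int
    end: int


@dataclass(frozen=True)
class PlantedRecord:
    pmid: str
    year: int
    has_abstract: bool
    mentions: tuple[PlantedMention, ...]
    decoys: dict[str, int]

    @property
    def unique_genes(self) -> frozenset[str]:
        return frozenset(m.canonical for m in self.mentions)


@dataclass
class GroundTruth:
    """Per-record plants plus derived aggregates, all exactly recomputable."""

    records: list[PlantedRecord]

    def n_identifier_bearing(self) -> int:
        return sum(1 for r in self.records if r.mentions)

    def chromosome_totals(self) -> np.ndarray:
        """Gene x abstract pair counts per chromosome (length-20 vector)."""
        totals = np.zeros(N_CHROMOSOMES, dtype=np.int64)
        for r in self.records:
            for g in r.unique_genes:
                totals[int(g[6:8]) - 1] += 1
        return totals

    def year_chromosome_counts(self) -> tuple[list[int], np.ndarray]:
        """(sorted years, 20 x Y counts) over all records with a year."""
        years = sorted({r.year for r in self.records})
        col = {y: j for j, y in enumerate(years)}
        counts = np.zeros((N_CHROMOSOMES, len(years)), dtype=np.int64)
        for r in self.records:
            for g in r.unique_genes:
                counts[int(g[6:8]) - 1, col[r.year]] += 1
        return years, counts

    def genes_per_abstract_histogram(self) -> dict[int, int]:
        """Unique-gene count histogram over identifier-bearing records."""
        hist: dict[int, int] = {}
        for r in self.records:
            k = len(r.unique_genes)
            if k > 0:
                hist[k] = hist.get(k, 0) + 1
        return dict(sorted(hist.items()))

    def decoy_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for r in self.records:
            for cls, n in r.decoys.items():
                totals[cls] = totals.get(cls, 0) + n
        return totals

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "records": [
                {
                    "pmid": r.pmid,
                    "year": r.year,
                    "has_abstract": r.has_abstract,
                    "mentions": [m._asdict() for m in r.mentions],
                    "decoys": r.decoys,
                }
                for r in self.records
            ],
            "chromosome_totals": self.chromosome_totals().tolist(),
            "genes_per_abstract_histogram": self.genes_per_abstract_histogram(),
            "decoy_totals": self.decoy_totals(),
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# text assembly

_GENERIC_TITLES = (
    "Genetic dissection of agronomic traits in soybean (Glycine max)",
    "Transcriptome profiling of soybean roots under abiotic stress",
    "QTL mapping for seed composition traits in a soybean RIL population",
    "Genome-wide association analysis of disease resistance in soybean",
)

_INTRO_SENTENCES = (
    "Soybean (Glycine max) is a globally important legume crop.",
    "Improving stress resilience is a central goal of soybean breeding.",
    "Seed composition traits are controlled by multiple quantitative loci.",
)

_FILLER_SENTENCES = (
    "Phenotypic variation was assessed across multiple field environments.",
    "A recombinant inbred line population was genotyped at high density.",
    "Candidate regions were validated by expression profiling.",
)

# Gene-sentence templates exercising mention placement: mid-sentence,
# sentence-initial, parenthesized, and immediately followed by punctuation.
# "{g}" marks where the identifier goes.
_GENE_TEMPLATES = (
    "Expression of {g} increased markedly under drought stress.",
    "{g} encodes a putative transcription factor in this interval.",
    "A major-effect locus ({g}) was fine-mapped in this study.",
    "Resistance co-segregated with {g}, suggesting a causal role.",
)

_REPEAT_TEMPLATES = (
    "Overexpression of {g} confirmed its regulatory function.",
    "Knockdown of {g} reversed the observed phenotype.",
)

_DECOY_TEMPLATES = {
    "out_of_range": "An earlier report listed {g}, which maps to no assembled chromosome.",
    "legacy": "Under the previous assembly this locus was designated {g}.",
    "lookalike": "The array probe {g} showed strong hybridization signal.",
}


def _sentence_with(template: str, token: str) -> tuple[str, int]:
    """Fill a template; return (sentence, offset of token within sentence)."""
    pos = template.index("{g}")
    return template.replace("{g}", token), pos


def _draw_ztg(rng: np.random.Generator, cont: float, cap: int) -> int:
    """Zero-truncated geometric: k=1, then continue with probability *cont*."""
    k = 1
    while k < cap and rng.random() < cont:
        k += 1
    return k


def _new_gene(rng: np.random.Generator, weights: Sequence[float]) -> str:
    chrom = int(rng.choice(N_CHROMOSOMES, p=np.asarray(weights))) + 1
    number = int(rng.integers(0, 1_000_000))
    return f"Glyma.{chrom:02d}G{number:06d}"


def _decoy_token(rng: np.random.Generator, cls: str) -> str:
    number6 = f"{int(rng.integers(0, 1_000_000)):06d}"
    number5 = f"{int(rng.integers(0, 100_000)):05d}"
    chrom_ok = f"{int(rng.integers(1, N_CHROMOSOMES + 1)):02d}"
    if cls == "out_of_range":
        bad = "00" if rng.random() < 1 / 3 else f"{int(rng.integers(21, 100)):02d}"
        return f"Glyma.{bad}G{number6}"
    if cls == "legacy":
        return f"Glyma{chrom_ok}g{number5}"
    if cls == "lookalike":
        core = f"Glyma.{chrom_ok}G{number6}"
        # letter fused before or after the identifier
        return f"x{core}" if rng.random() < 0.5 else f"{core}A"
    raise ValueError(f"unknown decoy class {cls}")


def generate(config: CorpusConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus and its exact ground truth, deterministically.

    The same config (including seed) always produces byte-identical records
    and plants.  Each record's mentions are tracked with character offsets
    in the concatenated ``title + " " + abstract`` text, the same string the
    extraction stage scans.
    """
    rng = np.random.default_rng(config.seed)
    chrom_w = np.asarray(config.chromosome_weights)
    years = np.arange(config.year_start, config.year_end + 1)
    year_w = np.asarray(config.resolved_year_weights())

    records: list[PubMedRecord] = []
    planted: list[PlantedRecord] = []
    gene_history: list[str] = []  # one entry per past gene-abstract assignment

    for i in range(config.n_records):
        pmid = str(30_000_000 + i)
        year = int(rng.choice(years, p=year_w))
        has_id = bool(rng.random() < config.p_has_identifier)
        missing_abstract = bool(rng.random() < config.p_missing_abstract)

        # --- choose this record's genes -----------------------------------
        genes: list[str] = []
        if has_id:
            k = 1 if missing_abstract else _draw_ztg(rng, config.gpa_continue, config.gpa_max)
            while len(genes) < k:
                if gene_history and rng.random() < config.p_gene_reuse:
                    # preferential reuse: sample past assignments, so often-
                    # used genes accumulate abstracts (long-tailed ranking)
                    g = gene_history[int(rng.integers(len(gene_history)))]
                else:
                    g = _new_gene(rng, chrom_w)
                if g not in genes:
                    genes.append(g)
            gene_history.extend(genes)

        def render(gene: str) -> str:
            if rng.random() < config.p_version_suffix:
                return f"{gene}.{int(rng.integers(1, 4))}"
            return gene

        # --- assemble text, tracking token offsets ------------------------
        # each entry: (sentence, token offset in sentence, canonical or None,
        #              raw token or None)
        mentions: list[PlantedMention] = []
        decoys = {cls: 0 for cls in _DECOY_TEMPLATES}

        if missing_abstract:
            if has_id:
                raw = genes[0]
                prefix = "Functional characterization of "
                title = f"{prefix}{raw} in soybean"
                mentions.append(PlantedMention(genes[0], raw, int(genes[0][6:8]),
                                               len(prefix), len(prefix) + len(raw)))
            else:
                title = _GENERIC_TITLES[int(rng.integers(len(_GENERIC_TITLES)))]
            records.append(PubMedRecord(pmid=pmid, year=year, title=title, abstract=None))
            planted.append(PlantedRecord(pmid=pmid, year=year, has_abstract=False,
                                         mentions=tuple(mentions), decoys=decoys))
            continue

        title = _GENERIC_TITLES[int(rng.integers(len(_GENERIC_TITLES)))]
        sentences: list[tuple[str, int | None, str | None, str | None]] = []
        intro = _INTRO_SENTENCES[int(rng.integers(len(_INTRO_SENTENCES)))]
        sentences.append((intro, None, None, None))

        for gene in genes:
            raw = render(gene)
            tmpl = _GENE_TEMPLATES[int(rng.integers(len(_GENE_TEMPLATES)))]
            sent, pos = _sentence_with(tmpl, raw)
            sentences.append((sent, pos, gene, raw))
            if rng.random() < config.p_repeat_mention:
                raw2 = render(gene)
                tmpl2 = _REPEAT_TEMPLATES[int(rng.integers(len(_REPEAT_TEMPLATES)))]
                sent2, pos2 = _sentence_with(tmpl2, raw2)
                sentences.append((sent2, pos2, gene, raw2))

        if not genes:
            filler = _FILLER_SENTENCES[int(rng.integers(len(_FILLER_SENTENCES)))]
            sentences.append((filler, None, None, None))

        for cls, rate in (("out_of_range", config.noise_out_of_range),
                          ("legacy", config.noise_legacy),
                          ("lookalike", config.noise_lookalike)):
            for _ in range(int(rng.poisson(rate))):
                token = _decoy_token(rng, cls)
                sent, pos = _sentence_with(_DECOY_TEMPLATES[cls], token)
                # decoy spans are not tracked: they must not be recovered
                sentences.append((sent, None, None, None))
                decoys[cls] += 1

        # interleave decoys/genes deterministically: shuffle all but the intro
        body = sentences[1:]
        order = rng.permutation(len(body))
        sentences = [sentences[0]] + [body[j] for j in order]

        abstract_parts: list[str] = []
        cursor = len(title) + 1  # mentions are located in title+" "+abstract
        for sent, pos, canonical, raw in sentences:
            if canonical is not None:
                start = cursor + pos
                mentions.append(PlantedMention(canonical, raw, int(canonical[6:8]),
                                               start, start + len(raw)))
            abstract_parts.append(sent)
            cursor += len(sent) + 1  # joined with single spaces

        abstract = " ".join(abstract_parts)
        records.append(PubMedRecord(pmid=pmid, year=year, title=title, abstract=abstract))
        planted.append(PlantedRecord(pmid=pmid, year=year, has_abstract=True,
                                     mentions=tuple(mentions), decoys=decoys))

    provenance = (f"synthetic corpus (n={config.n_records}, seed={config.seed}, "
                  f"years {config.year_start}-{config.year_end})")
    return Corpus(records=records, provenance=provenance), GroundTruth(records=planted)
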