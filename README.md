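# glyma-miner

Rule-based text mining of soybean (*Glycine max*) gene mentions in PubMed
abstracts, resolved to chromosomes and publication years.

Soybean genes in the Wm82.a2 reference annotation carry standardized
identifiers of the form `Glyma.<cc>G<nnnnnn>` — `<cc>` is the two-digit
chromosome number (01–20), `<nnnnnn>` the gene number, optionally suffixed
with a transcript version such as `.1`. Because the nomenclature is this
rigid, a regular-expression grammar extracts mentions from abstracts with
essentially no ambiguity, and each mention resolves to its chromosome
directly from the identifier. `glyma-miner` turns that observation into a
reproducible bibliometric pipeline for anyone studying how research
attention is distributed across a crop genome: plant-genomics researchers,
bibliometricians, and database curators.

## What it computes

Given a corpus of PubMed records (PMID, year, title, abstract), the
pipeline produces:

* **Genes per abstract** — the distribution of unique identifiers per
  identifier-bearing abstract (histogram, lower median, maximum).
* **Chromosome totals** — unique gene mentions per chromosome, counting a
  gene once per abstract containing it (O₁…O₂₀).
* **Uniformity test** — Pearson chi-square goodness-of-fit of the
  chromosome totals against equal expectation E = N/20:
  X² = Σᵢ (Oᵢ − E)²/E with df = 19, p-value from the chi-square upper
  tail Q(df/2, x/2), implemented from first principles.
* **Temporal matrices** — 20 × years raw counts and per-year percentage
  heatmap tables.
* **Gene ranking** — genes ordered by the number of abstracts mentioning
  them, plus the long-tail share (genes in ≤ 2 abstracts).

A synthetic corpus generator emulates the shape of the real *Glyma*
abstract corpus (377 records over 2006–2025, ~90% identifier-bearing,
median 1 gene per abstract, non-uniform chromosome usage, planted decoy
tokens) with exact ground truth, so the whole pipeline is testable without
network access.

## Worked example

Generate a synthetic corpus and run the full report:

```console
$ glyma-miner query
("Glyma" [Title/Abstract]) AND ("1 December 2006" [Date-Publication]: "31 December 2025" [Date-Publication])

$ glyma-miner simulate --seed 7 -o sim/
wrote synthetic corpus of 377 records to sim/

$ glyma-miner report sim/corpus.xml -o run/ --no-figures
{
 "n_records": 377,
 "n_with_identifier": 344,
 "percent_with_identifier": 91.2,
 "median_unique_genes": 1,
 "max_unique_genes": 9
}
wrote 6 files to run/

$ glyma-miner test-uniformity sim/corpus.csv
chi-square = 187.66, df = 19, p = < 1e-15
```

Reading the output: 344 of 377 records (91.2%) contain at least one
standardized identifier; the typical abstract mentions a single gene
(median 1) while one study mentions 9. The chi-square statistic of 187.66
on 19 degrees of freedom is far beyond the p = 0.001 critical value
(43.82), so the per-chromosome mention counts are decisively non-uniform —
exactly the structure the generator plants (elevated usage on chromosomes
2, 3, 6, 13, 16 and 18). The run directory contains each figure's CSV twin
with the plotted numbers, e.g.:

```console
$ head -4 run/top_genes.csv
gene,n_abstracts
Glyma.02G322163,5
Glyma.02G937955,4
Glyma.12G652140,4
```

The same `report` command accepts a real EFetch download
(`PubmedArticleSet` XML) or a `pmid,year,title,abstract` CSV.

## Library use

```python
from glyma_miner import (default_paper_config, generate, profile_corpus,
                         chromosome_totals, chi_square_uniform)

corpus, truth = generate(default_paper_config(seed=7))
profiles, rejected = profile_corpus(corpus)
totals = chromosome_totals(profiles)
print(chi_square_uniform(totals).p_display)
```

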