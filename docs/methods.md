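# Methods

## Problem and scope

`glyma-miner` quantifies how soybean (*Glycine max*) genes are represented
in the biomedical literature, using the standardized Wm82.a2 *Glyma*
identifier system as the recognizable entity class. The pipeline has four
stages: (1) read a corpus of PubMed records (PMID, year, title, abstract);
(2) recognize *Glyma* identifiers in each record's concatenated title and
abstract with a rule-based grammar; (3) aggregate per-abstract unique gene
sets into chromosome-level, temporal and per-gene summaries; (4) test the
chromosome-level totals against a uniform distribution with a Pearson
chi-square goodness-of-fit test.

The package analyzes corpora it is given (XML or CSV); constructing the
PubMed query string is in scope, but live NCBI retrieval is not part of the
tested surface. Gene aliases and symbolic names (e.g. *E1*, *GmFT2a*) are
out of scope by design: the method captures only the standardized
nomenclature, and its outputs must be read as describing that subset of the
literature.

## Identifier grammar

A mention is any maximal token of the form

```
Glyma . <cc> G <nnnnn[n]> [. <v>]
```

where `<cc>` is a two-digit chromosome field, `<nnnnn[n]>` a 5- or 6-digit
gene number, and `<v>` an optional 1–2 digit transcript/version suffix.
Decisions that required judgment:

* **Case.** `Glyma` and the `G` separator match case-insensitively; the
  canonical rendering is `Glyma.NNGnnnnnn`, so case variants cannot inflate
  unique-gene counts. Whether real-world pipelines match case-insensitively
  varies; the flag-free default here is the permissive reading, which is
  safe because the canonical form collapses the variants.
* **Gene-number width.** The nomenclature is nominally 5 digits in some
  descriptions but every published identifier in current annotation carries
  6; the grammar accepts 5–6 to cover both readings.
* **Token boundaries.** Matches must be bounded by non-alphanumeric context
  on both sides. This rejects identifiers fused into longer tokens (probe
  names like `xGlyma.03G227300`) while accepting mentions adjacent to
  punctuation, parentheses and sentence boundaries.
* **Chromosome range.** The two-digit field must be 01–20. Grammar-shaped
  tokens outside that range (scaffold-style or corrupted identifiers) are
  diverted to a rejection log rather than dropped silently, so corpus
  accounting stays auditable.
* **Version suffixes.** `Glyma.06G095100.1` and `Glyma.06G095100` denote
  the same gene; uniqueness is defined on the suffix-stripped canonical
  form, and the suffix is retained on the mention record only.
* **Legacy identifiers.** Dot-free Wm82.a1 names (`Glyma13g12340`) are not
  matched by default; an opt-in flag matches them and tags them `legacy`
  so the two nomenclatures are never silently merged.

## Counting conventions

* **Per abstract:** both the raw mention count and the set of unique
  canonical identifiers are recorded.
* **Genes-per-abstract distribution:** restricted to identifier-bearing
  abstracts; the median uses the lower-median convention on even-sized
  sets, keeping the statistic integer-valued.
* **Chromosome totals:** the default counts gene × abstract pairs — a gene
  contributes once per abstract containing it, and a gene present in *k*
  abstracts adds *k*. The alternative (each corpus-distinct gene counted
  once) is exposed as a flag; the two coincide when no gene recurs across
  abstracts. The pair convention is the default because per-abstract
  unique counts are what the aggregation sums.
* **Temporal matrix:** 20 × Y counts, with per-year percentage columns
  (each nonzero column rescaled to sum to 100; all-zero columns stay
  zero). Records without a parseable year are excluded from the temporal
  matrix only, and tallied; they still count in whole-corpus totals.
* **Gene ranking:** genes ordered by number of abstracts mentioning them,
  descending, ties broken by identifier ascending (deterministic output).
* **Prevalence percentage:** half-up rounding to one decimal.

## Chi-square test

With observed per-chromosome counts `O_1..O_20` and total `N`, the uniform
expectation is `E = N/20`, the statistic `X² = Σ (O_i − E)²/E`, `df = 19`,
and the p-value is the chi-square upper tail `Q(df/2, x/2)` (regularized
upper incomplete gamma). No continuity correction is applied and expected
counts may be non-integer. `Q` is implemented from first principles: the
lower-tail series expansion for `x < a + 1` (where `Q` is bounded away
from 0, so `1 − P` loses no precision) and a modified-Lentz continued
fraction otherwise, with convergence tolerance 1e-16 and an iteration cap
of 1000. The test suite checks agreement with an independent
survival-function oracle to 1e-10 relative error over `x ∈ [0, 500]`,
`df ∈ 1..50`; observed agreement is ~3e-14. p-values are displayed to 3
significant digits and reported as "< 1e-15" below that floor, where
further digits are numerical noise.

The test uses all 20 chromosome cells; no pooling or exclusion is applied.
No alternative nulls (chromosome-length- or gene-density-weighted
expectations) are implemented; the uniformity null is a descriptive
baseline, not a biological model.

## Corpus parsing decisions

* **Year:** `PubDate/Year` preferred; if only `MedlineDate` is present the
  first 4-digit substring is used; otherwise the year is absent. When
  electronic and print dates differ, whichever populates these fields wins
  — both conventions are defensible and the choice is recorded here.
* **Markup and whitespace:** inline markup (e.g. italics around *Glyma*)
  is flattened with no separator and whitespace runs are collapsed, so
  markup can never split an identifier token.
* **Structured abstracts:** multiple `AbstractText` sections are joined
  with single spaces.
* **Missing abstracts:** retained with `abstract = None` (never the empty
  string), so prevalence denominators use the full record count.
* **Duplicate PMIDs:** a hard error naming the PMID, in both CSV and
  corpus construction.

## Synthetic corpus generator

Because the real corpus is a live PubMed query with no deposited archive,
the generator produces corpora with the same shape and a fully known
ground truth. Defaults (all overridable):

| parameter | default | what it emulates |
|---|---|---|
| `n_records` | 377 | corpus size |
| years | 2006–2025, weights rising steeply after 2018 | publication surge |
| `p_has_identifier` | 0.90 | ~90% identifier-bearing records |
| `gpa_continue` | 0.45 | zero-truncated geometric unique-genes-per-abstract; 0.45 keeps the lower median strictly at 1 (at 0.5 the median sits exactly on the boundary and flips by sampling noise) |
| `gpa_max` | 14 | observed single-study maximum |
| chromosome weights | 1.9× on chrs 2, 3, 6, 13, 16, 18; 0.55× on 1, 10, 11, 20; normalized | uneven chromosome representation; at ~650 total mentions the implied noncentrality puts the expected chi-square near the low-hundreds, the regime the method operates in |
| `p_missing_abstract` | 0.05 | records lacking abstracts |
| `p_gene_reuse` | 0.15 | preferential reuse of earlier genes, yielding a long-tailed per-gene ranking (top genes in ~4–7 abstracts, >90% of genes in ≤2) |
| `p_repeat_mention` | 0.30 | within-abstract repeat mentions (total > unique) |
| `p_version_suffix` | 0.20 | `.N` transcript suffixes |
| noise rates | 0.10 / 0.10 / 0.05 per record (Poisson) | out-of-range, legacy, and letter-fused decoy tokens |

Prose templates place identifiers mid-sentence, sentence-initial,
parenthesized and punctuation-adjacent, each probing one boundary rule.
Records selected to lack an abstract but carry an identifier plant it in
the title, exercising title-only extraction. Every planted mention is
recorded with its exact character span in the `title + " " + abstract`
coordinate system — the same string extraction scans — so recovery can be
asserted with zero tolerance.

What the generator does **not** model: real linguistic context, aliases
and symbolic gene names, abstract semantics, or correlations between year
and gene choice. Passing the recovery tests therefore demonstrates that
the grammar and accounting are exact on in-grammar text with adversarial
decoys; it does not bound recall on free text that references genes
without standardized identifiers.

## Problem sizes in the test suite

End-to-end recovery runs 25 seeds of the full default corpus (377
records each). Type-I calibration draws 2000 multinomial replicates at
n = 800 over 20 cells; power uses 500 replicates at n = 680 under the
default chromosome weights. The survival-function oracle comparison grids
251 statistic values × 50 df. These sizes give stable checks while the
whole suite runs in well under a minute.

## Known limitations

* Abstract-level mining only; full-text mentions are invisible, so all
  frequencies are conservative.
* No normalization by chromosome length or annotated gene count; observed
  disparities mix biological relevance with research attention.
* No context classification: a mention counts the same whether the gene
  is the study's subject or a passing reference.
* The HTTP retrieval adapter is intentionally thin and untested; the
  tested surface starts at the XML/CSV readers.
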