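import pytest

from glyma_miner.corpus_io import Corpus, PubMedRecord
from glyma_miner.extraction import AbstractProfile


@pytest.fixture
def small_corpus() -> Corpus:
    """Three hand-built records with known mention structure."""
    return Corpus(records=[
        PubMedRecord(pmid="111", year=2020,
                     title="Fine-mapping of a flowering locus",
                     abstract="We mapped Glyma.19G194300 and Glyma.19G194300.1 near "
                              "Glyma.19G193400 on chromosome 19."),
        PubMedRecord(pmid="222", year=2021,
                     title="Glyma.03G227300 encodes a phytochrome",
                     abstract=None),
        PubMedRecord(pmid="333", year=2021,
                     title="A study without gene identifiers",
                     abstract="No standardized identifiers appear here."),
    ], provenance="unit-test fixture")


def profile(pmid: str, genes: list[str], year: int | None = 2020,
            total: int | None = None) -> AbstractProfile:
    """Shorthand for building AbstractProfile objects in tests."""
    return AbstractProfile(pmid=pmid, year=year,
                           total_mentions=total if total is not None else len(genes),
                           unique_genes=frozenset(genes))


@pytest.fixture
def make_profile():
    return profile
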