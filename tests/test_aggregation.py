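"""Corpus-level aggregation: histograms, chromosome totals, temporal
matrices, rankings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glyma_miner.aggregation import (
    EmptyAnalysisError,
    GeneRanking,
    chromosome_totals,
    genes_per_abstract,
    rank_genes,
    tail_summary,
    year_chromosome_matrix,
)
from tests.conftest import profile


class TestGenesPerAbstract:
    def test_median_and_max(self):
        profiles = [
            profile("1", ["Glyma.01G000100"]),
            profile("2", ["Glyma.02G000100"]),
            profile("3", [f"Glyma.0{c}G000100" for c in (1, 2)]),
            profile("4", [f"Glyma.{c:02d}G000100" for c in range(1, 15)]),
        ]
        dist = genes_per_abstract(profiles)
        assert dist.median == 1 and dist.maximum == 14
        assert dist.histogram == {1: 2, 2: 1, 14: 1}

    def test_single_profile(self):
        dist = genes_per_abstract([profile("1", ["Glyma.01G000100"])])
        assert dist.histogram == {1: 1} and dist.median == 1 and dist.maximum == 1

    def test_lower_median_convention(self):
        profiles = [profile("1", [f"Glyma.{c:02d}G000100" for c in (1, 2)]),
                    profile("2", [f"Glyma.{c:02d}G000100" for c in (1, 2, 3)])]
        assert genes_per_abstract(profiles).median == 2

    def test_gene_free_profiles_excluded_from_analysis_set(self):
        profiles = [profile("1", []), profile("2", ["Glyma.05G000100"])]
        assert genes_per_abstract(profiles).histogram == {1: 1}

    def test_all_empty_is_an_error(self):
        with pytest.raises(EmptyAnalysisError):
            genes_per_abstract([profile("1", []), profile("2", [])])


class TestChromosomeTotals:
    def test_same_gene_counts_once_per_abstract(self):
        profiles = [profile("1", ["Glyma.03G227300"]),
                    profile("2", ["Glyma.03G227300"])]
        totals = chromosome_totals(profiles)
        assert totals[2] == 2 and totals.sum() == 2

    def test_empty_profile_list(self):
        assert chromosome_totals([]).tolist() == [0] * 20

    def test_multiple_genes_same_chromosome(self):
        p = profile("1", ["Glyma.19G193400", "Glyma.19G194300", "Glyma.19G195400"])
        assert chromosome_totals([p])[18] == 3

    def test_distinct_genes_convention(self):
        profiles = [profile("1", ["Glyma.03G227300"]),
                    profile("2", ["Glyma.03G227300", "Glyma.16G149300"])]
        pairs = chromosome_totals(profiles)
        distinct = chromosome_totals(profiles, distinct_genes=True)
        assert pairs[2] == 2 and distinct[2] == 1
        assert pairs[15] == distinct[15] == 1


class TestYearChromosomeMatrix:
    def test_percent_column_arithmetic(self):
        profiles = [profile("1", ["Glyma.03G000100", "Glyma.03G000200",
                                  "Glyma.16G000100", "Glyma.16G000200"], year=2020)]
        m = year_chromosome_matrix(profiles)
        assert m.years == [2020]
        assert m.percent[2, 0] == pytest.approx(50.0)
        assert m.percent[15, 0] == pytest.approx(50.0)

    def test_zero_mention_year_column_zero_filled(self):
        profiles = [profile("1", ["Glyma.05G000100"], year=2020),
                    profile("2", [], year=2021)]
        m = year_chromosome_matrix(profiles)
        assert m.years == [2020, 2021]
        assert m.counts[:, 1].sum() == 0
        assert (m.percent[:, 1] == 0.0).all()

    def test_identical_count_columns_give_identical_percent_columns(self):
        profiles = [profile("1", ["Glyma.07G000100"], year=2020),
                    profile("2", ["Glyma.07G000200"], year=2021)]
        m = year_chromosome_matrix(profiles)
        np.testing.assert_array_equal(m.percent[:, 0], m.percent[:, 1])

    def test_year_absent_profiles_excluded_and_counted(self):
        profiles = [profile("1", ["Glyma.05G000100"], year=2020),
                    profile("2", ["Glyma.06G000100"], year=None)]
        m = year_chromosome_matrix(profiles)
        assert m.n_year_absent == 1
        assert m.counts.sum() == 1

    def test_conservation_against_chromosome_totals(self):
        profiles = [profile("1", ["Glyma.05G000100", "Glyma.06G000100"], year=2020),
                    profile("2", ["Glyma.05G000100"], year=2021),
                    profile("3", ["Glyma.08G000100"], year=None)]
        m = year_chromosome_matrix(profiles)
        totals = chromosome_totals(profiles)
        assert m.counts.sum() + 1 == totals.sum()  # the year-absent mention

    def test_nonzero_percent_columns_sum_to_100(self):
        rng = np.random.default_rng(42)
        profiles = [
            profile(str(i), [f"Glyma.{rng.integers(1, 21):02d}G{rng.integers(0, 10**6):06d}"],
                    year=int(rng.integers(2006, 2026)))
            for i in range(60)
        ]
        m = year_chromosome_matrix(profiles)
        col_sums = m.percent.sum(axis=0)
        nonzero = m.counts.sum(axis=0) > 0
        np.testing.assert_allclose(col_sums[nonzero], 100.0, atol=1e-9)


class TestRankGenes:
    def test_abstract_level_counting(self):
        g = "Glyma.20G085100"
        profiles = [profile(str(i), [g], total=2 if i == 0 else 1) for i in range(4)]
        ranking = rank_genes(profiles, k=5)
        assert ranking.entries == [(g, 4)]

    def test_k_larger_than_distinct_genes(self):
        profiles = [profile("1", ["Glyma.01G000100", "Glyma.02G000100"])]
        assert len(rank_genes(profiles, k=100).entries) == 2

    def test_ties_broken_alphabetically(self):
        profiles = [profile("1", ["Glyma.09G284700", "Glyma.03G227300"]),
                    profile("2", ["Glyma.09G284700", "Glyma.03G227300"])]
        ranking = rank_genes(profiles, k=2)
        assert ranking.entries == [("Glyma.03G227300", 2), ("Glyma.09G284700", 2)]

    def test_ranking_order_enforced(self):
        with pytest.raises(ValueError):
            GeneRanking(entries=[("a", 1), ("b", 3)])


class TestTailSummary:
    def test_counts_and_fraction(self):
        ranking = GeneRanking(entries=[("a", 4), ("b", 4), ("c", 2), ("d", 2), ("e", 1)])
        assert tail_summary(ranking) == (5, 3, 0.6)

    def test_all_singletons(self):
        ranking = GeneRanking(entries=[("a", 1), ("b", 1)])
        assert tail_summary(ranking).fraction == 1.0

    def test_no_tail(self):
        assert tail_summary(GeneRanking(entries=[("a", 10)])).fraction == 0.0


# --- property tests ---------------------------------------------------------

_profile_lists = st.lists(
    st.builds(
        lambda pmid, genes, year: profile(str(pmid), genes, year=year),
        st.integers(0, 10**6),
        st.lists(st.builds(lambda c, n: f"Glyma.{c:02d}G{n:06d}",
                           st.integers(1, 20), st.integers(0, 999)),
                 min_size=0, max_size=6, unique=True),
        st.one_of(st.none(), st.integers(2006, 2025)),
    ),
    min_size=0, max_size=15,
    unique_by=lambda p: p.pmid,
)


@settings(max_examples=100, derandomize=True)
@given(_profile_lists)
def test_count_conservation_and_permutation_invariance(profiles):
    """Total mentions are conserved across aggregation routes, and no
    aggregate depends on profile order."""
    totals = chromosome_totals(profiles)
    n_unique_sum = sum(p.n_unique for p in profiles)
    assert totals.sum() == n_unique_sum

    m = year_chromosome_matrix(profiles)
    n_year_absent_mentions = sum(p.n_unique for p in profiles if p.year is None)
    assert m.counts.sum() + n_year_absent_mentions == totals.sum()

    reversed_profiles = list(reversed(profiles))
    np.testing.assert_array_equal(totals, chromosome_totals(reversed_profiles))
    m2 = year_chromosome_matrix(reversed_profiles)
    assert m2.years == m.years
    np.testing.assert_array_equal(m.counts, m2.counts)
    assert rank_genes(profiles).entries == rank_genes(reversed_profiles).entries


@settings(max_examples=100, derandomize=True)
@given(_profile_lists, st.data())
def test_adding_a_profile_never_decreases_counts(profiles, data):
    extra = data.draw(st.builds(
        lambda genes: profile("9999999", genes, year=2020),
        st.lists(st.builds(lambda c, n: f"Glyma.{c:02d}G{n:06d}",
                           st.integers(1, 20), st.integers(0, 999)),
                 min_size=0, max_size=4, unique=True)))
    before = chromosome_totals(profiles)
    after = chromosome_totals(profiles + [extra])
    assert (after >= before).all()
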