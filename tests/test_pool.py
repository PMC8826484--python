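"""Pool-seq sampling theory: lineage occupancy, Kish sizes, pooling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tempopool.pool import (
    LineageTable,
    combine_pools,
    expected_lineages,
    kish_neff,
    lineage_pmf,
    pseudo_pool,
)
from tempopool.synthetic import default_world, generate_isofemale_panel

from conftest import make_pool


def enumeration_pmf(n_r, n_c):
    """Brute-force occupancy pmf: every read->chromosome assignment equally likely."""
    counts = {}
    for assign in itertools.product(range(n_c), repeat=n_r):
        j = len(set(assign))
        counts[j] = counts.get(j, 0) + 1
    total = n_c**n_r
    return np.array([counts.get(j, 0) / total for j in range(1, min(n_r, n_c) + 1)])


class TestLineagePmf:
    @pytest.mark.parametrize("n_r,n_c", [(2, 4), (3, 3), (4, 2), (5, 6), (1, 9)])
    def test_matches_enumeration(self, n_r, n_c):
        np.testing.assert_allclose(lineage_pmf(n_r, n_c), enumeration_pmf(n_r, n_c),
                                   atol=1e-12)

    def test_single_read_samples_one_lineage(self):
        for n_c in (1, 2, 50):
            pmf = lineage_pmf(1, n_c)
            assert pmf[0] == 1.0 and len(pmf) == 1

    def test_two_chromosome_saturation(self):
        # all 50 reads on one chromosome has probability 2^-49
        pmf = lineage_pmf(50, 2)
        assert pmf[1] == pytest.approx(1 - 2.0**-49, rel=1e-15)

    @pytest.mark.parametrize("n_r,n_c", [(50, 40), (200, 82), (350, 60), (500, 120)])
    def test_normalization_including_log_space_branch(self, n_r, n_c):
        pmf = lineage_pmf(n_r, n_c)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert (pmf >= 0).all()

    def test_matches_sympy_stirling_route(self):
        # independent route through sympy's Stirling numbers
        from sympy.functions.combinatorial.numbers import stirling

        n_r, n_c = 7, 5
        expected = []
        for j in range(1, 6):
            falling = 1
            for i in range(j):
                falling *= n_c - i
            expected.append(falling * int(stirling(n_r, j, kind=2)) / n_c**n_r)
        np.testing.assert_allclose(lineage_pmf(n_r, n_c), expected, atol=1e-14)

    @pytest.mark.parametrize("n_r,n_c", [(5, 10), (30, 20), (100, 82)])
    def test_expectation_matches_monte_carlo(self, n_r, n_c):
        rng = np.random.default_rng(0)
        draws = 100_000
        distinct = np.array(
            [len(np.unique(rng.integers(0, n_c, size=n_r))) for _ in range(draws)]
        )
        se = distinct.std(ddof=1) / np.sqrt(draws)
        assert expected_lineages(n_r, n_c) == pytest.approx(distinct.mean(), abs=3 * se)


class TestExpectedLineages:
    def test_worked_value(self):
        assert expected_lineages(2, 4) == pytest.approx(1.75)

    def test_saturates_at_chromosome_count(self):
        assert expected_lineages(2000, 10) == pytest.approx(10.0, abs=1e-3)
        assert expected_lineages(1, 10) == 1.0

    def test_monotone_in_reads_and_chromosomes(self):
        values = [expected_lineages(r, 20) for r in (1, 5, 20, 80)]
        assert values == sorted(values)
        values = [expected_lineages(30, c) for c in (2, 10, 40)]
        assert values == sorted(values)

    def test_table_roundtrip(self, tmp_path):
        table = LineageTable()
        table.lookup(5, 8)
        table.lookup(12, 20)
        path = tmp_path / "lineages.tsv"
        table.to_tsv(path)
        again = LineageTable.from_tsv(path)
        assert again.table == table.table


class TestKish:
    def test_worked_values(self):
        assert kish_neff([1.0] * 10) == pytest.approx(10.0)
        assert kish_neff([2.0, 1.0, 1.0]) == pytest.approx(16.0 / 6.0)
        assert kish_neff([3.5]) == pytest.approx(1.0)

    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=200)
    def test_bounded_by_count_with_equality_iff_uniform(self, weights):
        n = kish_neff(weights)
        assert n <= len(weights) + 1e-9
        if len(set(weights)) == 1:
            assert n == pytest.approx(len(weights))

    def test_rejects_degenerate_weights(self):
        with pytest.raises(ValueError):
            kish_neff([0.0, 0.0])
        with pytest.raises(ValueError):
            kish_neff([])


class TestCombinePools:
    def test_effective_size_weighting(self):
        p1 = make_pool("a", n_eff=10, ref_counts=(80,), alt_counts=(20,), positions=(100,))
        p2 = make_pool("b", n_eff=30, ref_counts=(60,), alt_counts=(40,), positions=(100,))
        assert combine_pools([p1, p2], 0) == pytest.approx(0.35)

    def test_equal_sizes_give_plain_mean(self):
        p1 = make_pool("a", n_eff=20, ref_counts=(90,), alt_counts=(10,), positions=(1,))
        p2 = make_pool("b", n_eff=20, ref_counts=(50,), alt_counts=(50,), positions=(1,))
        assert combine_pools([p1, p2], 0) == pytest.approx(0.3)

    def test_zero_coverage_is_missing_not_zero(self):
        p1 = make_pool("a", ref_counts=(0,), alt_counts=(0,), positions=(1,))
        assert np.isnan(combine_pools([p1], 0))
        p2 = make_pool("b", ref_counts=(3,), alt_counts=(1,), positions=(1,))
        # the empty pool drops out of the weighting entirely
        assert combine_pools([p1, p2], 0) == pytest.approx(0.25)


class TestPseudoPool:
    def test_equal_depth_is_plain_sum(self):
        world = default_world(seed=3, n_snps=300)
        panel = generate_isofemale_panel(world, n_strains=6)
        panel.read_depth = np.full_like(panel.read_depth, 20)
        rng = np.random.default_rng(0)
        panel.alt_reads = rng.binomial(20, panel.genotypes / panel.ploidy)
        pool = pseudo_pool(panel, seed=1)
        np.testing.assert_array_equal(
            pool.sites["alt_count"].to_numpy(), panel.alt_reads.sum(axis=0)
        )
        np.testing.assert_array_equal(
            (pool.sites["ref_count"] + pool.sites["alt_count"]).to_numpy(),
            panel.read_depth.sum(axis=0),
        )

    def test_thinning_equalizes_strain_contributions(self):
        world = default_world(seed=4, n_snps=400)
        panel = generate_isofemale_panel(world, n_strains=4)
        # force very unequal depths: strain 0 at 10x, others at 30x
        panel.read_depth = np.full((4, panel.n_sites), 30)
        panel.read_depth[0] = 10
        rng = np.random.default_rng(5)
        panel.alt_reads = rng.binomial(panel.read_depth, panel.genotypes / panel.ploidy)
        totals = []
        for seed in range(30):
            pool = pseudo_pool(panel, seed=seed)
            totals.append((pool.sites["ref_count"] + pool.sites["alt_count"]).sum())
        # every strain thinned to the shallowest total: expect ~4x strain-0 reads
        target = 4 * panel.read_depth[0].sum()
        assert np.mean(totals) == pytest.approx(target, rel=0.02)

    def test_requires_read_counts(self, small_dataset):
        panel = small_dataset.panel
        saved = panel.read_depth
        panel.read_depth = None
        try:
            with pytest.raises(ValueError):
                pseudo_pool(panel)
        finally:
            panel.read_depth = saved
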