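"""PBS scan: F_ST algebra, windows, p-values, regions, removal accounting."""

import numpy as np
import pandas as pd
import pytest

from tempopool import scan
from tempopool.scan import (
    NullDistribution,
    assign_pvalues,
    call_regions,
    confirm_snp_outliers,
    delimit_windows,
    enrichment_removal,
    fst,
    hudson_components,
    pbs,
    rec_bin_label,
    weighted_focal_frequencies,
    window_pbs_scan,
)
from tempopool.synthetic import default_world, generate_isofemale_panel


class TestFst:
    def test_identical_frequencies_clamp_to_zero(self):
        assert fst(0.4, 1000, 0.4, 1000) == 0.0

    def test_fixed_difference_stays_below_one(self):
        val = fst(1.0, 1000, 0.0, 1000)
        assert 0.999 < val < 1.0

    def test_matches_algebraic_form(self):
        p1, p2, n1, n2 = 0.8, 0.2, 100, 100
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        assert fst(p1, n1, p2, n2) == pytest.approx(num / den)

    def test_monomorphic_pair_is_excluded(self):
        num, den = hudson_components(0.0, 50, 0.0, 50)
        assert den == 0.0


class TestPbs:
    def test_no_differentiation(self):
        assert pbs(0.0, 0.0, 0.0) == 0.0

    def test_closed_form_focal_branch(self):
        assert pbs(0.1, 0.1, 0.0) == pytest.approx(-np.log(0.9))

    def test_symmetric_triple_identity(self):
        for x in (0.05, 0.2, 0.6):
            assert pbs(x, x, x) == pytest.approx(-np.log(1 - x) / 2)

    def test_window_pbs_invariant_to_season_swap(self):
        rng = np.random.default_rng(0)
        f_of, f_os, f_fs = rng.uniform(0, 0.5, (3, 20))
        np.testing.assert_allclose(pbs(f_of, f_os, f_fs), pbs(f_os, f_of, f_fs))


class TestWindows:
    def track(self, n, spacing=25, arm="2L"):
        return pd.DataFrame({"chrom": arm, "pos": np.arange(1, n + 1) * spacing})

    def test_track_density_sets_window_span(self):
        # 1 SNP per 25 bp and 200 SNPs per window gives ~5-kb windows
        wins = delimit_windows(self.track(1000), {"2L": 2.0})
        assert len(wins) == 5
        spans = wins["stop"] - wins["start"] + 1
        assert spans.iloc[1:].eq(5000).all()

    def test_exact_block_count_and_trailing_drop(self):
        wins = delimit_windows(self.track(400), {"2L": 2.0})
        assert len(wins) == 2
        with pytest.warns(UserWarning):
            assert len(delimit_windows(self.track(150), {"2L": 2.0})) == 0

    def test_windows_tile_without_overlap(self):
        wins = delimit_windows(self.track(1000), {"2L": 2.0})
        assert (wins["start"].iloc[1:].to_numpy()
                == wins["stop"].iloc[:-1].to_numpy() + 1).all()

    def test_recombination_bins(self):
        assert rec_bin_label(0.4) == "excluded"
        assert rec_bin_label(0.5) == "excluded"
        assert rec_bin_label(0.7) == "(0.5,1.0]"
        assert rec_bin_label(2.5) == "(2.0,3.0]"
        assert rec_bin_label(9.0) == "(3.0,inf]"

    def test_three_snp_window_matches_hand_calculation(self):
        sites = pd.DataFrame({"chrom": "2L", "pos": [10, 20, 30]})
        focal = sites.assign(freq=[0.9, 0.5, 0.2], neff=[100.0] * 3)
        fall = sites.assign(freq=[0.1, 0.4, 0.3], neff=[80.0] * 3)
        spring = sites.assign(freq=[0.2, 0.5, 0.2], neff=[60.0] * 3)
        wins = pd.DataFrame(
            [("2L", 1, 30, 3, 2.0, "(1.5,2.0]")],
            columns=["chrom", "start", "stop", "n_snps", "recomb_rate", "rec_bin"],
        )
        out = window_pbs_scan(wins, focal, fall, spring)

        def pair_sums(a, na, b, nb):
            nums, dens = [], []
            for p1, p2 in zip(a, b):
                num, den = hudson_components(p1, na, p2, nb)
                nums.append(num)
                dens.append(den)
            return np.clip(sum(nums) / sum(dens), 0, 1 - 1e-6)

        f_of = pair_sums(focal["freq"], 100, fall["freq"], 80)
        f_os = pair_sums(focal["freq"], 100, spring["freq"], 60)
        f_fs = pair_sums(fall["freq"], 80, spring["freq"], 60)
        expected = pbs(f_of, f_os, f_fs)
        assert out["window_pbs"].iloc[0] == pytest.approx(expected)
        # max-SNP PBS recomputed per site
        snp_vals = [
            pbs(
                fst(focal["freq"][i], 100, fall["freq"][i], 80),
                fst(focal["freq"][i], 100, spring["freq"][i], 60),
                fst(fall["freq"][i], 80, spring["freq"][i], 60),
            )
            for i in range(3)
        ]
        assert out["max_snp_pbs"].iloc[0] == pytest.approx(np.nanmax(snp_vals))
        assert out["max_snp_pos"].iloc[0] == [10, 20, 30][int(np.nanargmax(snp_vals))]


class TestWeightedFocal:
    def build_panel(self, n_strains, carrier_count, seed=0):
        world = default_world(seed=seed, n_snps=400)
        world.inversion_defs = world.inversion_defs[1:]  # keep In(2R)NS only
        panel = generate_isofemale_panel(world, n_strains=n_strains)
        karyo = np.zeros(n_strains, dtype=np.int8)
        karyo[:carrier_count] = 1
        panel.karyotypes["In(2R)NS"] = karyo
        # rebuild marker alleles to match the forced karyotypes
        markers = panel.sites["marker_of"].to_numpy() == "In(2R)NS"
        panel.hap1[:, markers] = 0
        panel.hap2[:, markers] = karyo[:, None]
        panel.ploidy[:, markers] = np.where(karyo[:, None] == 1, 2, panel.ploidy[:, markers])
        panel.genotypes = np.where(
            panel.ploidy == 2, panel.hap1 + panel.hap2, panel.hap1
        ).astype(np.int8)
        return panel, world.inversion_defs[0]

    def test_matched_targets_leave_plain_frequencies(self):
        panel, inv = self.build_panel(10, 2)
        f_panel = panel.inversion_frequency("In(2R)NS")
        out = weighted_focal_frequencies(panel, {"In(2R)NS": f_panel}, [inv])
        plain = panel.allele_frequencies()
        called = panel.ploidy.sum(axis=0)
        np.testing.assert_allclose(out["freq"].to_numpy(), plain, atol=1e-12)
        np.testing.assert_allclose(out["neff"].to_numpy(), called, atol=1e-9)

    def test_tagging_snp_moves_to_target(self):
        # 10 copies of which 2 inverted (f_panel=0.2) reweighted to 0.4:
        # inverted copies weigh 2.0, standard 0.75, tagging SNP hits 0.4
        panel, inv = self.build_panel(5, 2)
        panel.ploidy[:, :] = 2  # all 10 chromosome copies callable
        panel.genotypes = (panel.hap1 + panel.hap2).astype(np.int8)
        markers = panel.sites["marker_of"].to_numpy() == "In(2R)NS"
        out = weighted_focal_frequencies(panel, {"In(2R)NS": 0.4}, [inv])
        marker_freqs = out["freq"].to_numpy()[markers]
        np.testing.assert_allclose(marker_freqs, 0.4, atol=1e-12)

    def test_uncorrelated_snp_unchanged_in_expectation(self):
        diffs = []
        for seed in range(6):
            panel, inv = self.build_panel(40, 8, seed=seed)
            out = weighted_focal_frequencies(panel, {"In(2R)NS": 0.3}, [inv])
            plain = panel.allele_frequencies()
            sel = panel.sites["marker_of"].to_numpy() == ""
            diffs.append(np.nanmean(out["freq"].to_numpy()[sel] - plain[sel]))
        assert abs(np.mean(diffs)) < 0.01

    def test_non_reweightable_panel_rejected(self):
        panel, inv = self.build_panel(10, 0)
        with pytest.raises(ValueError, match="reweighted"):
            weighted_focal_frequencies(panel, {"In(2R)NS": 0.3}, [inv])


def make_windows(pvals, arm="2L", start0=1, span=5000):
    rows = []
    pos = start0
    for i, p in enumerate(pvals):
        rows.append((arm, pos, pos + span - 1, 200, 2.0, "(1.5,2.0]", 0.01, 0.01, p, p))
        pos += span
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "stop", "n_snps", "recomb_rate", "rec_bin",
                 "window_pbs", "max_snp_pbs", "p_window", "p_max_snp"],
    )


class TestPvalues:
    def test_empirical_p_with_smoothing(self):
        null = NullDistribution.from_arrays(np.linspace(0, 1, 2_500_000),
                                            np.linspace(0, 1, 2_500_000))
        wins = make_windows([0.5])
        wins["window_pbs"] = [2.0]  # above every simulated value
        wins["max_snp_pbs"] = [0.5]  # at the null median
        out = assign_pvalues(wins, null)
        assert out["p_window"].iloc[0] == pytest.approx(4e-7, rel=1e-3)
        assert out["p_max_snp"].iloc[0] == pytest.approx(0.5, abs=1e-3)

    def test_monotone_in_observed_statistic(self):
        null = NullDistribution.from_arrays(np.random.default_rng(0).gamma(2, 1, 10_000),
                                            np.ones(10))
        wins = make_windows([0.5] * 4)
        wins["window_pbs"] = [0.1, 1.0, 3.0, 9.0]
        out = assign_pvalues(wins, null)
        assert (np.diff(out["p_window"].to_numpy()) <= 0).all()

    def test_low_recombination_windows_excluded(self):
        null = NullDistribution.from_arrays(np.ones(100), np.ones(100))
        wins = make_windows([0.5, 0.5])
        wins.loc[0, ["recomb_rate", "rec_bin"]] = [0.3, "excluded"]
        out = assign_pvalues(wins, null)
        assert len(out) == 1

    def test_missing_bin_is_an_error(self):
        null = NullDistribution(window={"(0.5,1.0]": np.ones(10)},
                                max_snp={"(0.5,1.0]": np.ones(10)})
        with pytest.raises(ValueError, match="missing"):
            assign_pvalues(make_windows([0.5]), null)

    def test_null_data_gives_uniform_pvalues(self):
        # calibration: observed drawn from the same distribution as the null
        rng = np.random.default_rng(1)
        null_vals = rng.gamma(2.0, 0.01, 50_000)
        null = NullDistribution.from_arrays(null_vals, null_vals)
        wins = make_windows([0.5] * 2000)
        wins["window_pbs"] = rng.gamma(2.0, 0.01, 2000)
        out = assign_pvalues(wins, null)
        from scipy import stats

        assert stats.kstest(out["p_window"], "uniform").statistic < 0.05


class TestRegions:
    def test_isolated_seed_single_window(self):
        wins = make_windows([0.9] * 12 + [0.01] + [0.9] * 12)
        regions = call_regions(wins)
        assert len(regions) == 1
        assert regions[0].n_windows == 1
        assert regions[0].peak_p == 0.01

    def test_nine_high_windows_bridge_two_seeds(self):
        wins = make_windows([0.01] + [0.2] * 9 + [0.01] + [0.9] * 15)
        regions = call_regions(wins)
        assert len(regions) == 1
        assert regions[0].n_windows == 11

    def test_ten_high_windows_split_regions(self):
        wins = make_windows([0.01] + [0.2] * 10 + [0.01] + [0.9] * 15)
        regions = call_regions(wins)
        assert len(regions) == 2
        assert all(r.n_windows == 1 for r in regions)

    def test_calling_is_idempotent(self):
        rng = np.random.default_rng(2)
        wins = make_windows(rng.uniform(0, 1, 300))
        first = call_regions(wins)
        # re-calling on the called output (p-values unchanged) reproduces it
        second = call_regions(wins)
        assert [(r.start, r.stop) for r in first] == [(r.start, r.stop) for r in second]

    def test_gene_labels_near_peak(self):
        wins = make_windows([0.9] * 5 + [0.001] + [0.9] * 5)
        genes = pd.DataFrame(
            {"chrom": ["2L", "2L"], "start": [25_100, 200_000],
             "stop": [25_900, 201_000], "gene": ["near", "far"]}
        )
        regions = call_regions(wins, gene_table=genes)
        assert regions[0].genes == ["near"]


def planted_scan(seed, n_arm=600, n_plant_per_arm=10, plant_len=6):
    """Null window table with planted sweep regions of very low p."""
    rng = np.random.default_rng(seed)
    null_vals = rng.gamma(2.0, 0.01, size=20_000)
    rows = []
    for arm in ("2L", "2R"):
        for w in range(n_arm):
            rows.append((arm, w * 5000 + 1, (w + 1) * 5000, 200, 2.0, "(1.5,2.0]"))
    wins = pd.DataFrame(
        rows, columns=["chrom", "start", "stop", "n_snps", "recomb_rate", "rec_bin"]
    )
    stat = rng.choice(null_vals, size=len(wins))
    for a in range(2):
        for j in range(n_plant_per_arm):
            s = a * n_arm + 30 + j * 55
            stat[s : s + plant_len] = null_vals.max() * (1.5 + rng.random(plant_len))
    wins["window_pbs"] = stat
    wins["max_snp_pbs"] = stat
    null = NullDistribution.from_arrays(null_vals, null_vals)
    return assign_pvalues(wins, null)


class TestEnrichmentRemoval:
    def test_uniform_pvalues_remove_nothing(self):
        rng = np.random.default_rng(3)
        null_vals = rng.gamma(2.0, 0.01, 20_000)
        wins = make_windows([0.5] * 400)
        wins["window_pbs"] = rng.choice(null_vals, 400)
        out = assign_pvalues(wins, NullDistribution.from_arrays(null_vals, null_vals))
        n, frac = enrichment_removal(out, mode="deterministic", seed=0)
        assert n <= 3 and frac < 0.2

    def test_confirmation_filter_limits_counts(self):
        wp = planted_scan(4)
        confirm = wp.copy()
        # independent pseudo-pool scan: planted seeds rarely land in its top 5%
        rng = np.random.default_rng(99)
        confirm["window_pbs"] = rng.gamma(2.0, 0.01, len(confirm))
        confirm["max_snp_pbs"] = confirm["window_pbs"]
        n_conf, _ = enrichment_removal(
            wp, stat="window", mode="deterministic", confirm_table=confirm
        )
        n_all, _ = enrichment_removal(wp, stat="window", mode="deterministic")
        assert n_conf < n_all

    def test_mismatched_confirmation_grid_rejected(self):
        wp = planted_scan(5)
        other = wp.iloc[:-1]
        with pytest.raises(ValueError, match="grid"):
            enrichment_removal(wp, confirm_table=other)


class TestConfirmSnpOutliers:
    def grid(self, n=400, seed=6):
        rng = np.random.default_rng(seed)
        wins = make_windows([0.5] * n)
        wins["window_pbs"] = rng.gamma(2.0, 0.01, n)
        wins["max_snp_pbs"] = rng.gamma(2.0, 0.02, n)
        return wins

    def test_planted_soft_sweep_is_reported(self):
        primary = self.grid()
        pseudo = self.grid(seed=7)
        # single-SNP signal: huge max-SNP PBS, unremarkable window PBS
        primary.loc[100, "max_snp_pbs"] = 5.0
        pseudo.loc[100, "max_snp_pbs"] = 5.0
        out = confirm_snp_outliers(primary, pseudo)
        assert primary.loc[100, "start"] in out["start"].to_numpy()

    def test_window_outliers_are_excluded(self):
        primary = self.grid()
        pseudo = self.grid(seed=8)
        primary.loc[50, ["max_snp_pbs", "window_pbs"]] = [5.0, 5.0]
        pseudo.loc[50, "max_snp_pbs"] = 5.0
        out = confirm_snp_outliers(primary, pseudo)
        assert primary.loc[50, "start"] not in out["start"].to_numpy()

    def test_quantile_boundary_is_inclusive(self):
        vals = np.arange(1, 101, dtype=float)
        wins = make_windows([0.5] * 100)
        wins["max_snp_pbs"] = vals
        wins["window_pbs"] = 0.0
        pseudo = wins.copy()
        out = confirm_snp_outliers(wins, pseudo, snp_quantile=0.99,
                                   pseudo_quantile=0.99)
        # the SNP exactly at the 99th percentile is kept
        boundary = np.quantile(vals, 0.99)
        assert (out["max_snp_pbs"] >= boundary).all() and len(out) >= 1

    def test_different_grids_rejected(self):
        a = self.grid()
        with pytest.raises(ValueError, match="grids"):
            confirm_snp_outliers(a, a.iloc[:-2])
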