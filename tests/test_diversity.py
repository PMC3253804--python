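import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import divmap as dm
from divmap.diversity import (
    expected_heterozygosity,
    fixation_index,
    genotypic_distance,
    locally_common_alleles,
    mean_alleles_per_locus,
    mean_distance_to_reference,
    multilocus_distance,
    observed_heterozygosity,
    rarefied_richness,
)

from conftest import tiny_table


class TestMeanAlleles:
    def test_homozygous_tree_gives_one(self):
        counts = {f"L{i}": {101: 2} for i in range(9)}
        assert mean_alleles_per_locus(counts) == 1.0

    def test_heterozygous_tree_gives_two(self):
        counts = {f"L{i}": {101: 1, 103: 1} for i in range(9)}
        assert mean_alleles_per_locus(counts) == 2.0

    def test_arithmetic_mean_over_loci(self):
        counts = {"L1": {1: 3, 2: 1}, "L2": {3: 4}}
        assert mean_alleles_per_locus(counts) == pytest.approx(1.5)

    def test_empty_locus_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            assert mean_alleles_per_locus({"L1": {1: 2}, "L2": {}}) == 1.0


def mc_rarefaction(counts, g, n_draws=100_000, seed=0):
    """Monte-Carlo oracle: mean distinct alleles in g genes drawn without
    replacement; returns (mean, standard error)."""
    pool = np.repeat(
        np.arange(len(counts)), np.fromiter(counts.values(), dtype=int)
    )
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_draws, pool.size)), axis=1)[:, :g]
    draws = pool[order]
    distinct = (np.sort(draws, axis=1)[:, 1:] != np.sort(draws, axis=1)[:, :-1]).sum(
        axis=1
    ) + 1
    return float(distinct.mean()), float(distinct.std(ddof=1) / math.sqrt(n_draws))


class TestRarefaction:
    def test_exact_combinatorial_value(self):
        # {a:30, b:10}, g=2: [1-C(10,2)/C(40,2)] + [1-C(30,2)/C(40,2)] = 1080/780
        val = rarefied_richness({1: 30, 2: 10}, g=2)
        expected = (1 - math.comb(10, 2) / math.comb(40, 2)) + (
            1 - math.comb(30, 2) / math.comb(40, 2)
        )
        assert val == pytest.approx(expected, abs=1e-12)
        assert val == pytest.approx(1080 / 780, abs=1e-9)

    def test_g_equal_n_returns_observed_count(self):
        assert rarefied_richness({1: 5, 2: 3, 3: 2}, g=10) == pytest.approx(3.0)

    def test_single_allele_always_one(self):
        for n, g in [(40, 2), (100, 40), (6, 6)]:
            assert rarefied_richness({1: n}, g=g) == pytest.approx(1.0)

    def test_insufficient_genes_returns_none(self):
        assert rarefied_richness({1: 10, 2: 10}, g=40) is None

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_monte_carlo_subsampling(self, seed):
        """Hypergeometric formula vs 1e5 subsampling draws on random small cells."""
        rng = np.random.default_rng(seed)
        n_trees = rng.integers(3, 9)
        n_alleles = rng.integers(2, 4)
        pool = rng.integers(0, n_alleles, size=2 * n_trees)
        counts = {int(a): int((pool == a).sum()) for a in np.unique(pool)}
        g = int(rng.integers(2, 2 * n_trees))
        exact = rarefied_richness(counts, g=g)
        mc, se = mc_rarefaction(counts, g, seed=seed)
        assert abs(exact - mc) < 3 * max(se, 1e-12)

    def test_monotone_in_g_and_bounded_by_observed(self):
        counts = {1: 12, 2: 5, 3: 2, 4: 1}
        values = [rarefied_richness(counts, g=g) for g in range(2, 21)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] <= len(counts)


class TestHeterozygosity:
    def test_two_equal_alleles(self):
        assert expected_heterozygosity({1: 10, 2: 10}) == pytest.approx(0.5)

    def test_monomorphic_is_zero(self):
        assert expected_heterozygosity({1: 20}) == 0.0

    def test_four_equal_alleles(self):
        assert expected_heterozygosity({1: 5, 2: 5, 3: 5, 4: 5}) == pytest.approx(0.75)

    def test_invariant_under_allele_relabeling(self):
        assert expected_heterozygosity({1: 7, 2: 3}) == pytest.approx(
            expected_heterozygosity({900: 7, 42: 3})
        )

    def test_observed_het_of_cumbe_like_genotype(self):
        """Heterozygous at 8 of 9 loci → Ho = 0.89 to 2 dp."""
        geno = [(101, 103)] * 8 + [(101, 101)]
        assert observed_heterozygosity([geno]) == pytest.approx(8 / 9)
        assert round(observed_heterozygosity([geno]), 2) == 0.89

    def test_observed_het_extremes(self):
        assert observed_heterozygosity([[(1, 1), (2, 2)]]) == 0.0
        assert observed_heterozygosity([[(1, 2), (3, 4)]]) == 1.0


class TestFixationIndex:
    def test_equilibrium_is_zero(self):
        assert fixation_index(0.5, 0.5) == 0.0

    def test_complete_inbreeding(self):
        assert fixation_index(0.5, 0.0) == 1.0

    def test_clonal_heterozygote_excess(self):
        assert fixation_index(0.5, 1.0) == -1.0

    def test_undefined_at_zero_he(self):
        with pytest.raises(ValueError):
            fixation_index(0.0, 0.0)


class TestGenotypicDistance:
    @pytest.mark.parametrize(
        "g1,g2,expected",
        [
            ((1, 1), (1, 1), 0),  # ii vs ii
            ((1, 2), (1, 2), 0),  # ij vs ij (either order)
            ((1, 2), (2, 1), 0),
            ((1, 1), (1, 2), 1),  # ii vs ij
            ((1, 2), (1, 3), 1),  # ij vs ik
            ((1, 2), (3, 4), 2),  # ij vs kl
            ((1, 1), (2, 3), 3),  # ii vs jk
            ((1, 1), (2, 2), 4),  # ii vs jj
        ],
    )
    def test_enumerated_values(self, g1, g2, expected):
        assert genotypic_distance(g1, g2) == expected
        assert genotypic_distance(g2, g1) == expected  # symmetry

    def test_multilocus_sums_and_skips_missing(self):
        a = [(1, 1), None, (2, 3)]
        b = [(2, 2), (1, 1), (2, 3)]
        assert multilocus_distance(a, b) == 4

    def test_multilocus_invariant_under_locus_permutation(self):
        a = [(1, 1), (1, 2), (3, 4)]
        b = [(2, 2), (1, 3), (3, 3)]
        perm = [2, 0, 1]
        assert multilocus_distance(a, b) == multilocus_distance(
            [a[i] for i in perm], [b[i] for i in perm]
        )

    def test_mean_distance_to_reference(self):
        ref = [(2, 2)] * 9
        clones = [[(2, 2)] * 9] * 3
        assert mean_distance_to_reference(clones, ref) == 0.0
        homs = [[(1, 1)] * 9] * 3
        assert mean_distance_to_reference(homs, ref) == 36.0
        assert mean_distance_to_reference(clones + homs, ref) == 18.0


class TestLocallyCommonAlleles:
    def test_boundary_conditions(self):
        # allele 9 at freq 0.10 in 1 of 4 occupied cells: occupancy 0.25 → counted
        freqs = {
            c: {"L1": {1: 0.9 if c == 0 else 1.0, 9: 0.10 if c == 0 else 0.0}}
            for c in range(4)
        }
        out = locally_common_alleles(freqs)
        assert out[0]["L1"] == 1
        assert out[1]["L1"] == 0

    def test_ubiquitous_allele_never_counted(self):
        freqs = {c: {"L1": {1: 0.5, 2: 0.5}} for c in range(4)}
        out = locally_common_alleles(freqs)
        assert all(v["L1"] == 0 for v in out.values())

    def test_frequency_threshold_is_strict(self):
        freqs = {
            0: {"L1": {1: 0.95, 9: 0.05}},
            1: {"L1": {1: 1.0, 9: 0.0}},
            2: {"L1": {1: 1.0, 9: 0.0}},
            3: {"L1": {1: 1.0, 9: 0.0}},
        }
        out = locally_common_alleles(freqs)
        assert out[0]["L1"] == 0  # exactly 5% is not "> 5%"


class TestComputeCellStats:
    def test_cell_below_min_n_reports_na_only_for_thresholded_stats(self):
        t = tiny_table(
            [[(101, 103), (105, 105)]] * 19, coords=[(-79.0, -4.0)] * 19
        )
        grid = dm.make_grid((-79.5, -4.5, -78.5, -3.5))
        a = dm.resample_trees(t, grid, dm.neighborhood_mask())
        stats = dm.compute_cell_stats(a, t, min_n=20)
        row = stats.data.iloc[0]
        assert row["n_trees"] == 19
        assert not np.isnan(row["na"]) and not np.isnan(row["lca"])
        for colname in ("na_rarefied", "he", "ho", "f"):
            assert np.isnan(row[colname])

    def test_homogeneous_landscape_gives_flat_surfaces(self):
        t = tiny_table(
            [[(101, 103), (105, 107)]] * 25,
            coords=[(-79.0 + 0.01 * i, -4.0) for i in range(25)],
        )
        grid = dm.make_grid((-79.5, -4.5, -78.5, -3.5))
        a = dm.resample_trees(t, grid, dm.neighborhood_mask())
        stats = dm.compute_cell_stats(a, t, min_n=20)
        valued = stats.data.dropna(subset=["he"])
        assert valued["he"].nunique() == 1
        assert valued["ho"].unique() == pytest.approx([1.0])
        assert valued["na"].unique() == pytest.approx([2.0])

    def test_duplicating_trees_leaves_frequency_stats_unchanged(self):
        genos = [
            [(101, 103), (105, 105)],
            [(101, 101), (105, 107)],
            [(103, 103), (107, 107)],
        ]
        coords = [(-79.0, -4.0)] * 3
        t1 = tiny_table(genos, coords=coords)
        t2 = tiny_table(genos * 2, coords=coords * 2)
        grid = dm.make_grid((-79.5, -4.5, -78.5, -3.5))
        mask = dm.neighborhood_mask()
        s1 = dm.compute_cell_stats(dm.resample_trees(t1, grid, mask), t1, min_n=1)
        s2 = dm.compute_cell_stats(dm.resample_trees(t2, grid, mask), t2, min_n=1)
        for colname in ("na", "he", "ho", "f"):
            assert np.allclose(
                s1.data[colname].to_numpy(dtype=float),
                s2.data[colname].to_numpy(dtype=float),
                equal_nan=True,
            )

    def test_reference_distance_smallest_in_clonal_patch(self, landscape, cell_stats):
        cfg, _, _ = landscape
        d = cell_stats.data.dropna(subset=["gd_ref"])
        cx, cy = cfg.clonal_center
        inside = (d.lon - cx) ** 2 + (d.lat - cy) ** 2 <= 0.1**2
        outside = (d.lon - cx) ** 2 + (d.lat - cy) ** 2 > 2.0**2
        assert d.loc[inside, "gd_ref"].mean() < d.loc[outside, "gd_ref"].mean() / 2

    def test_rarefied_never_exceeds_observed(self, cell_stats):
        d = cell_stats.data.dropna(subset=["na_rarefied"])
        assert len(d) > 100
        assert (d["na_rarefied"] <= d["na"] + 1e-9).all()

    def test_hotspot_has_maximal_rarefied_richness(self, landscape, cell_stats):
        cfg, _, _ = landscape
        d = cell_stats.data.dropna(subset=["na_rarefied"])
        cx, cy = cfg.hotspot_center
        inside = (d.lon - cx) ** 2 + (d.lat - cy) ** 2 <= cfg.hotspot_radius**2
        assert d.loc[inside, "na_rarefied"].mean() > d.loc[~inside, "na_rarefied"].mean()

    def test_statistics_bounds(self, cell_stats):
        d = cell_stats.data
        for colname, lo, hi in [("he", 0, 1), ("ho", 0, 1)]:
            vals = d[colname].dropna()
            assert ((vals >= lo) & (vals <= hi)).all()
        assert (d["gd_ref"].dropna() >= 0).all()
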