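import itertools

import numpy as np
import pytest

import divmap as dm
from divmap.conservation import evaluate_kappa, training_presence_threshold
from divmap.spatial_grid import GridSpec

from conftest import tiny_table


def brute_force_auc(pres, absn):
    wins = sum(
        1.0 if p > a else (0.5 if p == a else 0.0)
        for p, a in itertools.product(pres, absn)
    )
    return wins / (len(pres) * len(absn))


def confusion_kappa(tp, fn, fp, tn):
    n = tp + fn + fp + tn
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    return (po - pe) / (1 - pe)


class TestGapAlleles:
    def test_set_difference(self):
        t = tiny_table(
            [[(1, 2)], [(1, 3)]],
            loci=["L1"],
            status=["ex_situ", "in_situ"],
        )
        gaps = dm.exsitu_missing_alleles(t)
        assert gaps.missing == (("L1", 3),)
        assert gaps.n_total_alleles == 3
        assert gaps.fraction_missing == pytest.approx(1 / 3)

    def test_identical_allele_sets_give_empty(self):
        t = tiny_table(
            [[(1, 2)], [(1, 2)]], loci=["L1"], status=["ex_situ", "in_situ"]
        )
        assert dm.exsitu_missing_alleles(t).missing == ()

    def test_no_exsitu_warns_and_returns_everything(self):
        t = tiny_table([[(1, 2)]], loci=["L1"], status=["in_situ"])
        with pytest.warns(UserWarning):
            gaps = dm.exsitu_missing_alleles(t)
        assert gaps.n_missing == 2

    def test_planted_withheld_alleles_recovered_exactly(self):
        cfg = dm.LandscapeConfig(
            seed=7,
            dirichlet_alpha=2.0,
            alleles_per_locus=(6,) * 9,
            hotspot_allele_prob=0.0,
        )
        table, _ = dm.simulate_landscape(cfg)
        gaps = dm.exsitu_missing_alleles(table)
        assert set(gaps.missing) == set(dm.withheld_alleles(cfg))


class TestMissingAlleleMap:
    def _fixture(self):
        cfg = dm.LandscapeConfig(
            seed=7, dirichlet_alpha=2.0, alleles_per_locus=(6,) * 9,
            hotspot_allele_prob=0.0,
        )
        table, _ = dm.simulate_landscape(cfg)
        grid = dm.make_grid(
            (table.lon.min(), table.lat.min(), table.lon.max() + 1e-9, table.lat.max() + 1e-9)
        )
        assignment = dm.resample_trees(table, grid, dm.neighborhood_mask())
        return cfg, table, assignment

    def test_no_gaps_gives_zero_map(self):
        cfg, table, assignment = self._fixture()
        empty = dm.GapAlleleSet(missing=(), n_total_alleles=54)
        r = dm.missing_allele_richness_map(assignment, table, empty)
        assert (r.values[~r.is_nodata()] == 0).all()

    def test_richness_confined_to_planted_region(self):
        cfg, table, assignment = self._fixture()
        gaps = dm.exsitu_missing_alleles(table)
        r = dm.missing_allele_richness_map(assignment, table, gaps)
        grid = assignment.grid
        cols, rows = np.meshgrid(np.arange(grid.n_cols), np.arange(grid.n_rows))
        lon, lat = grid.cell_center(cols, rows)
        positive = (~r.is_nodata()) & (r.values > 0)
        assert positive.any()
        # carriers live in the gap circle; re-sampling smears ≤ 0.5° + cell diagonal
        reach = cfg.gap_radius + 0.5 + 0.24
        dist2 = (lon - cfg.gap_center[0]) ** 2 + (lat - cfg.gap_center[1]) ** 2
        assert (dist2[positive] <= reach**2).all()
        assert (r.values[positive] <= gaps.n_missing).all()


class TestEnvelope:
    def test_training_points_score_one_with_no_tails(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 19))
        model = dm.envelope_sdm(X, tail_pct=0)
        assert np.allclose(model.score(X), 1.0)

    def test_point_outside_every_envelope_scores_zero(self):
        X = np.zeros((5, 3)) + [[0], [1], [2], [3], [4]]
        model = dm.envelope_sdm(X)
        assert model.score(np.full((1, 3), 99.0))[0] == 0.0

    def test_partial_envelope_fraction(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 19))
        model = dm.envelope_sdm(X)
        probe = np.full((1, 19), 2.0)
        probe[0, :9] = 99.0  # outside 9 of 19 envelopes
        assert model.score(probe)[0] == pytest.approx(10 / 19)

    def test_constant_variable_envelope(self):
        X = np.column_stack([np.arange(4.0), np.full(4, 7.0)])
        model = dm.envelope_sdm(X)
        assert model.score(np.array([[2.0, 7.0]]))[0] == 1.0
        assert model.score(np.array([[2.0, 8.0]]))[0] == 0.5


class TestThreshold:
    def test_ten_percent_convention(self):
        scores = [0.1 * i for i in range(1, 11)]
        assert training_presence_threshold(scores, pct=10) == pytest.approx(0.2)

    def test_all_equal_scores(self):
        assert training_presence_threshold([0.7] * 8, pct=10) == 0.7

    def test_pct_zero_is_minimum(self):
        assert training_presence_threshold([0.4, 0.9, 0.2], pct=0) == 0.2


class TestPseudoAbsences:
    def test_count_and_bbox(self):
        rng = np.random.default_rng(1)
        pres = rng.uniform([-80, -10], [-70, 0], size=(20, 2))
        pts = dm.generate_pseudo_absences(pres, factor=5, expand=0.1, seed=3)
        assert pts.shape == (100, 2)
        w, h = 10.0, 10.0
        assert (pts[:, 0] >= pres[:, 0].min() - 0.1 * w - 1e-9).all()
        assert (pts[:, 0] <= pres[:, 0].max() + 0.1 * w + 1e-9).all()
        assert (pts[:, 1] >= pres[:, 1].min() - 0.1 * h - 1e-9).all()

    def test_seed_reproducibility(self):
        pres = np.array([[0.0, 0.0], [1.0, 1.0]])
        a = dm.generate_pseudo_absences(pres, seed=5)
        b = dm.generate_pseudo_absences(pres, seed=5)
        assert np.array_equal(a, b)

    def test_degenerate_bbox_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            dm.generate_pseudo_absences(np.array([[0.0, 0.0], [0.0, 1.0]]))


class TestAUC:
    def test_perfect_separation(self):
        assert dm.evaluate_auc([0.8, 0.9], [0.1, 0.2]) == 1.0

    def test_identical_distributions(self):
        assert dm.evaluate_auc([0.5, 0.7], [0.5, 0.7]) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_pairwise(self, seed):
        rng = np.random.default_rng(seed)
        pres = np.round(rng.uniform(size=rng.integers(5, 50)), 2)
        absn = np.round(rng.uniform(size=rng.integers(5, 50)), 2)
        assert dm.evaluate_auc(pres, absn) == pytest.approx(
            brute_force_auc(pres, absn), abs=1e-12
        )


class TestKappa:
    def test_perfect_classifier(self):
        k = evaluate_kappa([0.9] * 5, [0.1] * 5, threshold=0.5)
        assert k.kappa == pytest.approx(1.0)

    def test_chance_level_is_zero(self):
        k = evaluate_kappa([0.2, 0.8], [0.2, 0.8], threshold=0.5)
        assert k.kappa == pytest.approx(0.0)

    def test_confusion_matrix_worked_example(self):
        # TP=45, FN=5, FP=10, TN=40 → kappa = (0.85-0.5)/0.5 = 0.70
        pres = [1.0] * 45 + [0.0] * 5
        absn = [1.0] * 10 + [0.0] * 40
        k = evaluate_kappa(pres, absn, threshold=0.5)
        assert k.kappa == pytest.approx(0.70)
        assert k.kappa == pytest.approx(confusion_kappa(45, 5, 10, 40))

    def test_maximized_threshold_reported(self):
        pres = [0.9, 0.8, 0.6]
        absn = [0.5, 0.3, 0.1]
        k = evaluate_kappa(pres, absn)
        assert k.kappa == pytest.approx(1.0)
        assert 0.5 < k.threshold <= 0.6


class TestCoverage:
    def _rasters(self, counts_row):
        grid = GridSpec(xll=0, yll=0, cell_size=1.0, n_cols=len(counts_row), n_rows=1)
        binary = dm.Raster(grid=grid, values=np.ones((1, len(counts_row))))
        counts = dm.Raster(grid=grid, values=np.array([counts_row], dtype=float))
        return binary, counts

    def test_worked_percentages(self):
        binary, counts = self._rasters([25, 30, 40, 50, 20, 5, 1, 0, 0, 0])
        cov = dm.sampling_coverage(binary, counts, min_n=20)
        assert cov.pct_well_sampled == pytest.approx(50.0)
        assert cov.pct_under_sampled == pytest.approx(20.0)
        assert cov.pct_gap == pytest.approx(30.0)

    def test_all_well_sampled(self):
        binary, counts = self._rasters([20, 21, 22])
        cov = dm.sampling_coverage(binary, counts, min_n=20)
        assert (cov.pct_well_sampled, cov.pct_under_sampled, cov.pct_gap) == (100, 0, 0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(2)
        binary, counts = self._rasters(rng.integers(0, 40, size=30).tolist())
        cov = dm.sampling_coverage(binary, counts, min_n=20)
        assert cov.pct_well_sampled + cov.pct_under_sampled + cov.pct_gap == pytest.approx(100.0)

    def test_monotone_in_min_n(self):
        rng = np.random.default_rng(3)
        binary, counts = self._rasters(rng.integers(0, 40, size=30).tolist())
        pcts = [
            dm.sampling_coverage(binary, counts, min_n=m).pct_well_sampled
            for m in (5, 10, 20, 30)
        ]
        assert all(b <= a for a, b in zip(pcts, pcts[1:]))

    def test_grid_mismatch_rejected(self):
        binary, _ = self._rasters([1, 2, 3])
        other = dm.Raster(
            grid=GridSpec(xll=1, yll=0, cell_size=1.0, n_cols=3, n_rows=1),
            values=np.zeros((1, 3)),
        )
        with pytest.raises(ValueError, match="grids"):
            dm.sampling_coverage(binary, other, min_n=20)
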