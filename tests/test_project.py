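"""Monte Carlo ensembles, quota allocation, and dynamic forward projection."""

import numpy as np
import pytest

from lucfrontier import (
    CovariateStack,
    GeneratorConfig,
    GridGeometry,
    LandCoverMap,
    allocate_quota,
    fit_logistic,
    grid_sample,
    make_scene,
    project_step,
    simulate_ensemble,
    update_dynamic_layers,
)
from lucfrontier.covariates import EmptyTargetError, distance_to
from lucfrontier.project import ProbabilitySurface


def geom_of(n, cell=30.0):
    return GridGeometry(n, n, cell, origin_y=n * cell)


def prob_surface(p_grid, forest=None):
    p_grid = np.asarray(p_grid, float)
    geom = GridGeometry(*p_grid.shape, 30.0, origin_y=p_grid.shape[0] * 30.0)
    if forest is None:
        forest = np.ones(p_grid.shape, bool)
    vals = np.where(forest, p_grid, np.nan)
    return ProbabilitySurface(geom, vals, forest)


class TestSimulateEnsemble:
    def test_probability_zero_and_one_limits(self):
        z = simulate_ensemble(prob_surface(np.zeros((5, 5))), S=50, seed=0)
        assert (z.counts == 0).all() and z.mean_loss_area_ha == 0.0
        o = simulate_ensemble(prob_surface(np.ones((5, 5))), S=50, seed=0)
        assert (o.counts[o.forest_mask] == 50).all()

    def test_binomial_expectation_of_loss_area(self):
        # 100 cells at p = 0.5: loss ~ Binomial(100, .5) per landscape
        p = np.full((10, 10), 0.5)
        e = simulate_ensemble(prob_surface(p), S=1000, seed=3)
        per_sim_sd_ha = np.sqrt(100 * 0.25) * 0.09
        se = 3 * per_sim_sd_ha / np.sqrt(1000)
        assert abs(e.mean_loss_area_ha - 50 * 0.09) < se

    def test_deterministic_under_seed(self):
        p = np.random.default_rng(0).random((20, 20))
        a = simulate_ensemble(prob_surface(p), S=64, seed=9)
        b = simulate_ensemble(prob_surface(p), S=64, seed=9)
        assert np.array_equal(a.counts, b.counts)
        assert a.mean_loss_area_ha == b.mean_loss_area_ha

    def test_chunking_does_not_change_the_stream(self):
        p = np.random.default_rng(1).random((15, 15))
        a = simulate_ensemble(prob_surface(p), S=100, seed=4, chunk=7)
        b = simulate_ensemble(prob_surface(p), S=100, seed=4, chunk=100)
        assert np.array_equal(a.counts, b.counts)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            prob_surface(np.full((3, 3), 1.5))

    def test_expected_counts_match_probabilities(self):
        rng = np.random.default_rng(5)
        p = rng.random((20, 20)) * 0.3
        e = simulate_ensemble(prob_surface(p), S=2000, seed=6)
        freq = e.counts / 2000
        sd = np.sqrt(p * (1 - p) / 2000)
        assert (np.abs(freq - p) < 5 * sd + 1e-9).mean() > 0.99


class TestAllocateQuota:
    def _setup(self, counts_list, probs_list):
        n = len(counts_list)
        geom = GridGeometry(1, n, 30.0, origin_y=30.0)
        lc = LandCoverMap(geom, np.ones((1, n), int))
        forest = np.ones((1, n), bool)
        prob = ProbabilitySurface(geom, np.asarray([probs_list], float), forest)
        from lucfrontier.project import EnsembleCounts

        counts = EnsembleCounts(
            geometry=geom, counts=np.asarray([counts_list]), forest_mask=forest,
            S=1000, seed=0, mean_loss_area_ha=0.0, sd_loss_area_ha=0.0,
        )
        return counts, prob, lc

    def test_highest_counts_convert_first(self):
        counts, prob, lc = self._setup([900, 500, 100], [0.9, 0.5, 0.1])
        res = allocate_quota(counts, prob, lc, quota_area_ha=2 * 0.09)
        assert res.quota_cells == 2
        assert list(res.predicted.cells[0]) == [2, 2, 1]

    def test_quota_zero_is_identity(self):
        counts, prob, lc = self._setup([5, 3, 1], [0.5, 0.3, 0.1])
        res = allocate_quota(counts, prob, lc, quota_area_ha=0.0)
        assert np.array_equal(res.predicted.cells, lc.cells)

    def test_count_tie_broken_by_probability(self):
        counts, prob, lc = self._setup([800, 500, 500], [0.9, 0.3, 0.7])
        res = allocate_quota(counts, prob, lc, quota_area_ha=2 * 0.09)
        # tied cells at count 500: the one with p = .7 wins
        assert list(res.predicted.cells[0]) == [2, 1, 2]
        assert "tied" in res.tie_break_trace

    def test_remaining_tie_broken_by_row_major_index(self):
        counts, prob, lc = self._setup([7, 7, 7], [0.5, 0.5, 0.5])
        res = allocate_quota(counts, prob, lc, quota_area_ha=2 * 0.09)
        assert list(res.predicted.cells[0]) == [2, 2, 1]

    def test_quota_beyond_forest_area_rejected(self):
        counts, prob, lc = self._setup([1, 1, 1], [0.1, 0.1, 0.1])
        with pytest.raises(ValueError, match="exceeds"):
            allocate_quota(counts, prob, lc, quota_area_ha=4 * 0.09)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_quota_and_nonforest_persistence(self, seed):
        rng = np.random.default_rng(seed)
        geom = geom_of(30)
        cells = rng.choice([1, 2, 3, 5], size=(30, 30), p=[0.6, 0.3, 0.05, 0.05])
        lc = LandCoverMap(geom, cells)
        forest = lc.class_mask("forest")
        p = np.where(forest, rng.random((30, 30)), np.nan)
        prob = ProbabilitySurface(geom, p, forest)
        counts = simulate_ensemble(prob, S=20, seed=seed)
        quota_cells = int(rng.integers(0, forest.sum()))
        res = allocate_quota(counts, prob, lc, quota_cells * geom.cell_area_ha)
        changed = res.predicted.cells != lc.cells
        assert changed.sum() == quota_cells
        assert (res.predicted.cells[changed] == 2).all()
        assert forest[changed].all()
        assert np.array_equal(res.predicted.cells[~forest], lc.cells[~forest])

    def test_allocation_monotone_in_rank(self, rng):
        geom = geom_of(10)
        lc = LandCoverMap(geom, np.ones((10, 10), int))
        forest = np.ones((10, 10), bool)
        p = rng.random((10, 10))
        prob = ProbabilitySurface(geom, p, forest)
        counts = simulate_ensemble(prob, S=50, seed=0)
        res = allocate_quota(counts, prob, lc, 30 * geom.cell_area_ha)
        converted = (res.predicted.cells == 2)
        key = list(zip(-counts.counts.ravel(), -p.ravel(), range(p.size)))
        order = sorted(range(p.size), key=lambda i: key[i])
        ranks = {i: r for r, i in enumerate(order)}
        conv_ranks = [ranks[i] for i in np.flatnonzero(converted.ravel())]
        assert max(conv_ranks) == len(conv_ranks) - 1  # a perfect prefix of the ranking


class TestDynamicProjection:
    def test_missing_agriculture_surfaces_distance_error(self):
        geom = geom_of(10)
        lc = LandCoverMap(geom, np.ones((10, 10), int))  # all forest
        stack = CovariateStack(geom)
        stack.add("dist_agriculture", np.zeros((10, 10)), dynamic=True,
                  op="distance_to_class", target_class="agriculture",
                  transform={"mean": 0.0, "sd": 1.0})
        with pytest.raises(EmptyTargetError):
            update_dynamic_layers(stack, lc)

    def test_dynamic_update_tracks_the_map_and_freezes_scale(self):
        geom = geom_of(8)
        cells = np.ones((8, 8), int)
        cells[0, 0] = 2
        lc = LandCoverMap(geom, cells)
        raw0 = distance_to(lc.class_mask("agriculture"), geom).values
        mean, sd = raw0.mean(), raw0.std()
        stack = CovariateStack(geom)
        stack.add("dist_agriculture", (raw0 - mean) / sd, dynamic=True,
                  op="distance_to_class", target_class="agriculture",
                  transform={"mean": mean, "sd": sd})
        stack.add("static_layer", np.full((8, 8), 2.0))
        cells2 = cells.copy()
        cells2[7, 7] = 2
        lc2 = LandCoverMap(geom, cells2)
        updated = update_dynamic_layers(stack, lc2)
        raw2 = distance_to(lc2.class_mask("agriculture"), geom).values
        assert np.allclose(updated["dist_agriculture"], (raw2 - mean) / sd)
        assert np.array_equal(updated["static_layer"], stack["static_layer"])

    def test_quota_zero_projection_is_a_fixed_point(self, small_scene):
        t = grid_sample(small_scene.map_t0, small_scene.map_t1, small_scene.stack, 90.0)
        m = fit_logistic(t, ["dist_agriculture", "nonforest_neighborhood"], name="m")
        step1, _, _ = project_step(
            small_scene.map_t1, m, small_scene.stack, 0.0, S=8, seed=0
        )
        step2, _, _ = project_step(step1, m, small_scene.stack, 0.0, S=8, seed=1)
        assert np.array_equal(step2.cells, small_scene.map_t1.cells)

    def test_projected_conversion_concentrates_near_agriculture(self, small_scene):
        """Conversions cluster by existing farmland when adjacency dominates."""
        t = grid_sample(small_scene.map_t0, small_scene.map_t1, small_scene.stack, 90.0)
        m = fit_logistic(t, ["dist_agriculture", "nonforest_neighborhood"], name="adj")
        assert m.coef("dist_agriculture") < 0  # nearer farmland -> higher risk
        map_t1 = small_scene.map_t1
        forest1 = map_t1.class_mask("forest")
        quota = 0.05 * forest1.sum() * map_t1.geometry.cell_area_ha
        map_t2, _, _ = project_step(map_t1, m, small_scene.stack, quota, S=100, seed=2)
        converted = forest1 & (map_t2.cells == map_t1.code_of("agriculture"))
        still_forest = forest1 & ~converted
        d = distance_to(map_t1.class_mask("agriculture"), map_t1.geometry).values
        assert d[converted].mean() < d[still_forest].mean()
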