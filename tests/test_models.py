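"""Sampling, screening, logistic fitting and model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats
from scipy.special import expit

from lucfrontier import (
    CovariateStack,
    GeneratorConfig,
    GridGeometry,
    LandCoverMap,
    compare_models,
    correlation_screen,
    fit_logistic,
    grid_sample,
    make_scene,
    mcfadden_adjusted,
    predict_probability,
)
from lucfrontier.models import FittedModel, SampleTable


def geom_of(n, cell=30.0):
    return GridGeometry(n, n, cell, origin_y=n * cell)


def table_from_arrays(outcome, **cols):
    n = len(outcome)
    data = {"row": np.zeros(n, int), "col": np.zeros(n, int),
            "x": np.zeros(n), "y": np.zeros(n),
            "x_coord": np.zeros(n), "y_coord": np.zeros(n),
            "outcome": np.asarray(outcome, int)}
    data.update({k: np.asarray(v, float) for k, v in cols.items()})
    return SampleTable(pd.DataFrame(data), spacing_m=90.0, geometry=geom_of(10))


class TestGridSample:
    def test_candidate_count_all_forest(self):
        geom = geom_of(100)
        all_forest = LandCoverMap(geom, np.ones((100, 100), int))
        stack = CovariateStack(geom).add("z", np.zeros((100, 100)))
        t = grid_sample(all_forest, all_forest, stack, 300.0)
        assert len(t) == 100  # every 10th row/col from (0, 0)

    def test_no_forest_warns_and_returns_empty(self):
        geom = geom_of(10)
        ag = LandCoverMap(geom, np.full((10, 10), 2))
        stack = CovariateStack(geom).add("z", np.zeros((10, 10)))
        with pytest.warns(UserWarning, match="empty"):
            t = grid_sample(ag, ag, stack, 30.0)
        assert len(t) == 0

    def test_outcome_zero_for_forest_to_bare_soil(self):
        geom = geom_of(2)
        t0 = LandCoverMap(geom, np.array([[1, 1], [1, 1]]))
        t1 = LandCoverMap(geom, np.array([[3, 2], [1, 1]]))
        stack = CovariateStack(geom).add("z", np.zeros((2, 2)))
        t = grid_sample(t0, t1, stack, 30.0)
        by_cell = t.data.set_index(["row", "col"])["outcome"]
        assert by_cell.loc[(0, 0)] == 0  # became bare soil, not agriculture
        assert by_cell.loc[(0, 1)] == 1
        assert by_cell.loc[(1, 0)] == 0

    def test_non_multiple_spacing_rejected(self):
        geom = geom_of(10)
        m = LandCoverMap(geom, np.ones((10, 10), int))
        stack = CovariateStack(geom).add("z", np.zeros((10, 10)))
        with pytest.raises(ValueError, match="multiple"):
            grid_sample(m, m, stack, 45.0)


class TestCorrelationScreen:
    def test_identical_columns_drop_lower_priority(self, rng):
        v = rng.standard_normal(100)
        t = table_from_arrays(rng.integers(0, 2, 100), a=v, b=v.copy())
        rep = correlation_screen(t, ["a", "b"], priority=["a", "b"])
        assert rep.kept == ["a"]
        dropped, retained, r, p = rep.dropped[0]
        assert (dropped, retained) == ("b", "a")
        assert r == pytest.approx(1.0)

    def test_independent_columns_usually_all_kept(self):
        kept_all = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            cols = {f"c{i}": rng.standard_normal(1000) for i in range(4)}
            t = table_from_arrays(rng.integers(0, 2, 1000), **cols)
            rep = correlation_screen(t, list(cols))
            kept_all += len(rep.kept) == 4
        assert kept_all >= 38  # |r| > 0.66 between iid normals is essentially never

    def test_cattle_population_anticorrelation_drops_cattle(self, rng):
        pop = rng.standard_normal(500)
        noise = rng.standard_normal(500)
        # build cattle with corr(population, cattle) = -0.99 exactly in expectation
        cattle = -0.99 * pop + np.sqrt(1 - 0.99**2) * noise
        t = table_from_arrays(
            rng.integers(0, 2, 500), population_density=pop, cattle_density=cattle
        )
        rep = correlation_screen(
            t, ["population_density", "cattle_density"],
            priority=["population_density", "cattle_density"],
        )
        assert rep.kept == ["population_density"]
        assert rep.dropped[0][0] == "cattle_density"
        assert rep.dropped[0][2] == pytest.approx(-0.99, abs=0.02)

    def test_screening_is_idempotent(self, rng):
        base = rng.standard_normal(300)
        cols = {
            "a": base,
            "b": base + 0.1 * rng.standard_normal(300),
            "c": rng.standard_normal(300),
        }
        t = table_from_arrays(rng.integers(0, 2, 300), **cols)
        rep = correlation_screen(t, list(cols))
        rep2 = correlation_screen(t, rep.kept, priority=rep.kept)
        assert rep2.kept == rep.kept and rep2.dropped == []

    def test_priority_must_cover_names(self, rng):
        t = table_from_arrays(rng.integers(0, 2, 50), a=rng.standard_normal(50))
        with pytest.raises(ValueError, match="priority"):
            correlation_screen(t, ["a"], priority=[])


class TestFitLogistic:
    def test_intercept_only_balanced_outcomes(self):
        n = 100
        t = table_from_arrays(np.r_[np.ones(50), np.zeros(50)])
        m = fit_logistic(t, [], name="null")
        assert m.coef("intercept") == pytest.approx(0.0, abs=1e-8)
        assert m.loglik == pytest.approx(n * np.log(0.5))
        assert m.loglik_null == pytest.approx(m.loglik)

    def test_agreement_with_independent_maximizer(self):
        rng = np.random.default_rng(42)
        n = 200
        x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
        y = (rng.random(n) < expit(-1.0 + 0.8 * x1 - 0.5 * x2)).astype(int)
        t = table_from_arrays(y, x1=x1, x2=x2)
        m = fit_logistic(t, ["x1", "x2"])

        X = np.column_stack([np.ones(n), x1, x2])

        def nll(b):
            eta = X @ b
            return -(y * eta - np.logaddexp(0.0, eta)).sum()

        res = optimize.minimize(nll, np.zeros(3), method="BFGS", tol=1e-12)
        assert np.allclose(m.beta, res.x, atol=1e-6)
        assert m.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_degenerate_outcomes_rejected(self):
        t = table_from_arrays(np.ones(30), z=np.random.default_rng(0).standard_normal(30))
        with pytest.raises(ValueError, match="all 0 or all 1"):
            fit_logistic(t, ["z"])

    def test_fitted_probabilities_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(7)
        n = 400
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(-1 + x)).astype(int)
        t1 = table_from_arrays(y, z=x)
        t2 = table_from_arrays(y, z=5.0 * x + 3.0)
        m1, m2 = fit_logistic(t1, ["z"]), fit_logistic(t2, ["z"])
        eta1 = m1.beta[0] + m1.beta[1] * x
        eta2 = m2.beta[0] + m2.beta[1] * (5.0 * x + 3.0)
        assert np.allclose(expit(eta1), expit(eta2), atol=1e-8)

    def test_loglik_never_below_null(self, rng):
        y = rng.integers(0, 2, 300)
        t = table_from_arrays(y, z=rng.standard_normal(300))
        m = fit_logistic(t, ["z"])
        assert m.loglik >= m.loglik_null - 1e-9


class TestPseudoR2:
    def test_null_model_is_zero(self):
        m = FittedModel("null", [], np.zeros(1), np.ones(1), -100.0, -100.0, 100)
        assert mcfadden_adjusted(m) == 0.0

    def test_hand_value(self):
        m = FittedModel("m", list("abcde"), np.zeros(6), np.ones(6), -60.0, -100.0, 100)
        assert mcfadden_adjusted(m) == pytest.approx(0.35)

    def test_noise_covariate_cannot_beat_unadjusted_gain(self, rng):
        y = rng.integers(0, 2, 500)
        z = rng.standard_normal(500)
        noise = rng.standard_normal(500)
        t = table_from_arrays(y, z=z, noise=noise)
        m1 = fit_logistic(t, ["z"])
        m2 = fit_logistic(t, ["z", "noise"])
        unadjusted_gain = (m1.loglik - m2.loglik) / m1.loglik_null  # >= 0 shift
        assert mcfadden_adjusted(m2) - mcfadden_adjusted(m1) <= unadjusted_gain + 1e-12


class TestCompareModels:
    def _pair(self, rng, extra_is_noise=True, n=300):
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        y = (rng.random(n) < expit(-1 + 0.8 * x)).astype(int)
        t = table_from_arrays(y, x=x, e=e)
        return fit_logistic(t, ["x"], name="a"), fit_logistic(t, ["x", "e"], name="b")

    def test_identical_models_statistic_zero(self, rng):
        a, _ = self._pair(rng)
        cr = compare_models(a, a)
        assert cr.nested and cr.statistic == 0.0 and cr.p_value == 1.0

    def test_null_extra_term_p_uniform(self):
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            a, b = self._pair(rng, n=300)
            pvals.append(compare_models(a, b).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_disjoint_term_sets_not_tested(self, rng):
        n = 300
        x, z = rng.standard_normal(n), rng.standard_normal(n)
        y = rng.integers(0, 2, n)
        t = table_from_arrays(y, x=x, z=z)
        cr = compare_models(fit_logistic(t, ["x"]), fit_logistic(t, ["z"]))
        assert not cr.nested and cr.p_value is None and cr.statistic is None

    def test_different_sample_sizes_rejected(self, rng):
        a = fit_logistic(table_from_arrays(rng.integers(0, 2, 100)), [])
        b = fit_logistic(table_from_arrays(rng.integers(0, 2, 120)), [])
        with pytest.raises(ValueError, match="sample sizes"):
            compare_models(a, b)


class TestPredictProbability:
    def test_zero_covariates_give_half(self):
        geom = geom_of(2)
        stack = CovariateStack(geom).add("z", np.zeros((2, 2)))
        m = FittedModel("m", ["z"], np.array([0.0, 1.0]), np.ones(2), -1.0, -2.0, 10)
        forest = np.ones((2, 2), bool)
        prob = predict_probability(m, stack, forest)
        assert np.allclose(prob.values, 0.5)

    def test_hand_computed_three_cell_fixture(self):
        geom = GridGeometry(1, 3, 30.0, origin_y=30.0)
        stack = CovariateStack(geom).add("z", np.array([[-1.0, 0.0, 2.0]]))
        m = FittedModel("m", ["z"], np.array([-0.5, 1.2]), np.ones(2), -1.0, -2.0, 10)
        prob = predict_probability(m, stack, np.ones((1, 3), bool))
        assert np.allclose(prob.values[0], expit(-0.5 + 1.2 * np.array([-1.0, 0.0, 2.0])))

    def test_monotone_in_positive_coefficient(self):
        geom = geom_of(2)
        base = np.zeros((2, 2))
        m = FittedModel("m", ["z"], np.array([0.0, 2.0]), np.ones(2), -1.0, -2.0, 10)
        forest = np.ones((2, 2), bool)
        lo = predict_probability(m, CovariateStack(geom).add("z", base), forest)
        hi = predict_probability(m, CovariateStack(geom).add("z", base + 1.0), forest)
        assert (hi.values > lo.values).all()

    def test_missing_layer_named(self):
        geom = geom_of(2)
        stack = CovariateStack(geom).add("z", np.zeros((2, 2)))
        m = FittedModel("m", ["w"], np.array([0.0, 1.0]), np.ones(2), -1.0, -2.0, 10)
        with pytest.raises(KeyError, match="w"):
            predict_probability(m, stack, np.ones((2, 2), bool))

    def test_nodata_outside_forest_mask(self):
        geom = geom_of(2)
        stack = CovariateStack(geom).add("z", np.zeros((2, 2)))
        m = FittedModel("m", ["z"], np.array([0.0, 1.0]), np.ones(2), -1.0, -2.0, 10)
        forest = np.array([[True, False], [False, True]])
        prob = predict_probability(m, stack, forest)
        assert np.isnan(prob.values[0, 1]) and np.isnan(prob.values[1, 0])


class TestSceneRecovery:
    def test_combined_model_outperforms_single_groups(self):
        """With signal in both covariate groups, the union model explains most."""
        scene = make_scene(GeneratorConfig(seed=10))
        t = grid_sample(scene.map_t0, scene.map_t1, scene.stack, 90.0)
        luc = ["elevation", "slope", "soil_moisture", "dist_road",
               "nonforest_neighborhood", "buffer_10km"]
        da = ["dist_agriculture", "fire_density", "unallocated_land", "buffer_10km"]
        both = luc + [x for x in da if x not in luc]
        r2 = {
            name: mcfadden_adjusted(fit_logistic(t, terms, name=name))
            for name, terms in (("LUC", luc), ("DA", da), ("combined", both))
        }
        assert r2["combined"] > r2["LUC"]
        assert r2["combined"] > r2["DA"]
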