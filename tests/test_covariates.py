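import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import forestedge as fe
from forestedge.raster import SubRegion

PX = 0.465


class TestDrySeasonLength:
    def test_strict_inequality_at_threshold(self):
        months = [10, 20, 59, 60, 61] + [100] * 7
        stack = np.array(months, float)[:, None, None] * np.ones((1, 3, 3))
        assert (fe.dry_season_length(stack) == 3).all()  # 59 counts, 60 does not

    def test_extremes(self):
        wet = np.full((12, 2, 2), 100.0)
        dry = np.zeros((12, 2, 2))
        assert (fe.dry_season_length(wet) == 0).all()
        assert (fe.dry_season_length(dry) == 12).all()

    def test_invariant_to_layer_permutation(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(0, 200, (12, 6, 6))
        perm = stack[rng.permutation(12)]
        assert np.array_equal(fe.dry_season_length(stack), fe.dry_season_length(perm))

    def test_wrong_layer_count_rejected(self):
        with pytest.raises(ValueError, match="12 layers"):
            fe.dry_season_length(np.zeros((11, 4, 4)))


class TestAggregateCovariates:
    tiles = [SubRegion(0, 0, 10, 0, 10), SubRegion(1, 0, 10, 10, 20)]

    def test_constant_raster(self):
        mask = np.ones((10, 20), bool)
        agg = fe.aggregate_covariates(np.full((10, 20), 7.0), self.tiles, mask)
        assert agg.tolist() == [7.0, 7.0]

    def test_checkerboard_mean_is_half(self):
        mask = np.ones((10, 20), bool)
        board = np.indices((10, 20)).sum(axis=0) % 2
        agg = fe.aggregate_covariates(board.astype(float), self.tiles, mask, "proportion")
        assert agg.tolist() == [0.5, 0.5]

    def test_forest_only_and_missing_tile(self):
        mask = np.zeros((10, 20), bool)
        mask[:, :10] = True  # tile 1 has no forest
        raster = np.where(mask, 3.0, 99.0)
        agg = fe.aggregate_covariates(raster, self.tiles, mask)
        assert agg[0] == 3.0 and np.isnan(agg[1])

    def test_shape_mismatch_and_bad_statistic(self):
        mask = np.ones((10, 20), bool)
        with pytest.raises(ValueError, match="co-registered"):
            fe.aggregate_covariates(np.zeros((5, 5)), self.tiles, mask)
        with pytest.raises(ValueError, match="statistic"):
            fe.aggregate_covariates(np.zeros((10, 20)), self.tiles, mask, "max")


class TestFilterSparsePredictors:
    def test_ten_percent_rule(self):
        n = 100
        tab = pd.DataFrame(
            {
                "sparse": [1.0] * 5 + [0.0] * 95,    # 5% non-zero -> dropped
                "kept": [1.0] * 50 + [0.0] * 50,     # 50% non-zero -> kept
                "dense": np.arange(n, dtype=float) + 1,
            }
        )
        out = fe.filter_sparse_predictors(tab)
        assert list(out.columns) == ["kept", "dense"]

    def test_rule_applies_only_to_designated_columns(self):
        tab = pd.DataFrame({"anthrome_a": [0.0] * 99 + [1.0], "physical": [0.0] * 100})
        out = fe.filter_sparse_predictors(tab, columns=["anthrome_a"])
        assert list(out.columns) == ["physical"]

    def test_all_dense_unchanged_and_empty_rejected(self):
        tab = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        pd.testing.assert_frame_equal(fe.filter_sparse_predictors(tab), tab)
        with pytest.raises(ValueError):
            fe.filter_sparse_predictors(pd.DataFrame())


class TestRobustFit:
    def test_exact_linear_data_recovered_with_unit_weights(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({"x1": rng.normal(size=50), "x2": rng.normal(size=50)})
        y = 1.0 + 2.0 * tab["x1"] - 3.0 * tab["x2"]
        res = fe.robust_fit(y, tab)
        assert res.converged
        assert res.coefficients["intercept"] == pytest.approx(1.0, abs=1e-8)
        assert res.coefficients["x1"] == pytest.approx(2.0, abs=1e-8)
        assert res.coefficients["x2"] == pytest.approx(-3.0, abs=1e-8)
        assert np.allclose(res.weights, 1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_ols_on_clean_gaussian_data(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({"x1": rng.normal(size=200), "x2": rng.normal(size=200)})
        y = 0.5 + 1.5 * tab["x1"] + 0.7 * tab["x2"] + rng.normal(0, 0.01, 200)
        robust = fe.robust_fit(y, tab)
        ols = sm.OLS(y, sm.add_constant(tab)).fit()
        # Tukey weights are all near (not exactly) 1 on Gaussian residuals,
        # so agreement is close but not to machine precision
        for name, ols_val in zip(["intercept", "x1", "x2"], ols.params):
            assert abs(robust.coefficients[name] - ols_val) / abs(ols_val) < 1e-3

    def test_gross_outlier_downweighted(self):
        rng = np.random.default_rng(2)
        tab = pd.DataFrame({"x": rng.normal(size=100)})
        y = (2.0 * tab["x"] + rng.normal(0, 0.5, 100)).to_numpy()
        y_dirty = y.copy()
        y_dirty[0] += 100.0
        robust = fe.robust_fit(y_dirty, tab)
        assert robust.weights[0] < 0.05
        clean_slope = sm.OLS(y, sm.add_constant(tab)).fit().params["x"]
        dirty_slope = sm.OLS(y_dirty, sm.add_constant(tab)).fit().params["x"]
        assert abs(robust.coefficients["x"] - clean_slope) < abs(dirty_slope - clean_slope)

    def test_rank_deficient_design_named(self):
        tab = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 6, 8, 10]})
        with pytest.raises(ValueError, match="collinear"):
            fe.robust_fit(np.arange(5.0), tab)

    def test_too_few_rows(self):
        tab = pd.DataFrame({"a": [1.0, 2.0], "b": [5.0, 3.0]})
        with pytest.raises(ValueError, match="too few rows"):
            fe.robust_fit(np.array([1.0, 2.0]), tab)


class TestSelectModel:
    def test_single_strong_candidate_selected(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame({"x": rng.normal(size=100)})
        y = 3.0 * tab["x"] + rng.normal(0, 0.1, 100)
        sel = fe.select_model(y, tab, ["x"])
        assert sel.predictors == ("x",)

    def test_deterministic_across_runs(self):
        tab, _ = fe.generate_covariate_study(
            120, {"latitude": 1.0, "dry_season_length": -2.0}, noise_sd=3.0, seed=4
        )
        preds = [c for c in tab.columns if c != "response"]
        a = fe.select_model(tab["response"], tab, preds)
        b = fe.select_model(tab["response"], tab, preds)
        assert a.predictors == b.predictors
        assert a.bic == b.bic
        assert np.array_equal(a.weights, b.weights)

    def test_planted_predictors_recovered(self):
        tab, _ = fe.generate_covariate_study(
            300, {"latitude": 2.0, "dry_season_length": -3.0}, noise_sd=2.0, seed=5
        )
        preds = [c for c in tab.columns if c != "response"]
        sel = fe.select_model(tab["response"], tab, preds)
        assert {"latitude", "dry_season_length"} <= set(sel.predictors)

    def test_k_max_validation_and_cap(self):
        tab, _ = fe.generate_covariate_study(60, {"latitude": 2.0}, noise_sd=1.0, seed=6)
        preds = [c for c in tab.columns if c != "response"]
        with pytest.raises(ValueError, match="k_max"):
            fe.select_model(tab["response"], tab, preds, k_max=0)
        sel = fe.select_model(tab["response"], tab, preds, k_max=1)
        assert len(sel.predictors) <= 1
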