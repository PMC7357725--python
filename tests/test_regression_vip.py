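"""Standardized GLM, PLS-VIP importance, and the power-law fit."""

import numpy as np
import pandas as pd
import pytest

from fertmeta.regression_vip import (
    DEFAULT_LOG_VARS,
    RegressionError,
    fit_glm,
    fit_power_law,
    standardize,
    transform_predictors,
    vip_scores,
)


class TestTransform:
    def test_log_recipe(self):
        t = pd.DataFrame({"p_olsen": [10.0], "clay": [25.0]})
        out = transform_predictors(t)
        assert out["log_p_olsen"].iloc[0] == pytest.approx(np.log(10.0))
        assert out["clay"].iloc[0] == 25.0  # untransformed by design
        assert "p_olsen" not in out.columns

    def test_nonpositive_value_rejected_by_default(self):
        t = pd.DataFrame({"p_olsen": [0.0]})
        with pytest.raises(RegressionError):
            transform_predictors(t)

    def test_drop_mode_removes_offending_rows(self):
        t = pd.DataFrame({"p_olsen": [0.0, 5.0], "clay": [10.0, 20.0]})
        out = transform_predictors(t, on_nonpositive="drop")
        assert len(out) == 1 and out["clay"].iloc[0] == 20.0

    def test_default_recipe_contents(self):
        assert set(DEFAULT_LOG_VARS) == {
            "total_c", "p_olsen", "n_rate", "exch_k", "silt", "rainfall"}


class TestStandardize:
    def test_unit_sd_column_unchanged(self, rng):
        col = rng.normal(size=200)
        col = col / col.std(ddof=1)
        t = pd.DataFrame({"x": col})
        out, scales = standardize(t)
        assert np.allclose(out["x"], t["x"])
        assert scales["x"] == pytest.approx(1.0)

    def test_result_has_unit_sd_no_centering(self, rng):
        t = pd.DataFrame({"a": rng.uniform(5, 9, 100),
                          "b": rng.normal(100, 30, 100)})
        out, scales = standardize(t)
        assert np.allclose(out.std(ddof=1), 1.0)
        # scale-only: the mean shifts by the same factor, sign preserved
        assert np.allclose(out["a"] * scales["a"], t["a"])
        assert (out["a"] > 0).all()

    def test_constant_column_rejected(self):
        with pytest.raises(RegressionError, match="constant"):
            standardize(pd.DataFrame({"x": [3.0, 3.0, 3.0]}))


class TestGlm:
    def test_perfect_fit(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = 2.0 * X["a"] - 1.0 * X["b"] + 0.5
        fit = fit_glm(y, X)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.pvalues[["a", "b"]].max() < 1e-10

    def test_null_simulation(self, rng):
        X = pd.DataFrame(rng.normal(size=(1000, 3)), columns=list("abc"))
        y = rng.normal(size=1000)
        fit = fit_glm(y, X)
        assert fit.r2 < 0.02
        assert fit.params[["a", "b", "c"]].abs().max() < 0.12
        assert fit.adjusted_r2 <= fit.r2

    def test_matches_normal_equations_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = X["a"] - 0.5 * X["c"] + rng.normal(0, 0.3, 40)
        fit = fit_glm(y.to_numpy(), X)
        A = np.column_stack([np.ones(40), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y.to_numpy())
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_scale_only_standardization_preserves_inference(self, rng):
        X = pd.DataFrame({"a": rng.uniform(1, 9, 60),
                          "b": rng.normal(50, 12, 60)})
        y = 0.3 * X["a"] + 0.01 * X["b"] + rng.normal(0, 0.5, 60)
        raw = fit_glm(y.to_numpy(), X)
        Xs, scales = standardize(X)
        std = fit_glm(y.to_numpy(), Xs)
        assert np.allclose(std.pvalues[["a", "b"]], raw.pvalues[["a", "b"]])
        assert np.allclose(std.params[["a", "b"]] / scales[["a", "b"]],
                           raw.params[["a", "b"]])

    def test_too_few_rows_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 3)), columns=list("abc"))
        with pytest.raises(RegressionError):
            fit_glm(rng.normal(size=4), X)

    def test_significance_codes(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
        y = 1.5 * X["a"] + rng.normal(0, 0.5, 200)
        table = fit_glm(y.to_numpy(), X).coefficient_table()
        assert table.set_index("predictor").loc["a", "signif"] == "***"


class TestVip:
    def test_single_predictor_scores_one(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=30)})
        y = 2 * X["a"] + rng.normal(0, 0.1, 30)
        res = vip_scores(y.to_numpy(), X, n_components=1)
        assert res.scores["a"] == pytest.approx(1.0)

    def test_sum_of_squares_identity(self, rng):
        p = 6
        X = pd.DataFrame(rng.normal(size=(80, p)),
                         columns=[f"x{i}" for i in range(p)])
        y = X.iloc[:, 0] - X.iloc[:, 3] + rng.normal(0, 0.5, 80)
        for a in (1, 2, 4):
            res = vip_scores(y.to_numpy(), X, n_components=a)
            assert np.sum(res.scores**2) == pytest.approx(p, rel=1e-9)

    def test_orthonormal_single_signal_closed_form(self, rng):
        p, n = 5, 64
        M = rng.normal(size=(n, p))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        X = pd.DataFrame(Q, columns=[f"x{i}" for i in range(p)])
        y = 3.0 * X["x0"].to_numpy()
        res = vip_scores(y, X, n_components=1)
        assert res.scores["x0"] == pytest.approx(np.sqrt(p), rel=1e-9)
        assert np.allclose(res.scores.drop("x0"), 0.0, atol=1e-9)
        assert res.important == {"x0"}

    def test_ranking_invariant_to_column_order(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        y = (2 * X["a"] + X["c"] + rng.normal(0, 0.3, 60)).to_numpy()
        res1 = vip_scores(y, X, n_components=2)
        res2 = vip_scores(y, X[["d", "c", "b", "a"]], n_components=2)
        assert np.allclose(res1.scores.sort_index(), res2.scores.sort_index())

    def test_loo_component_selection_runs(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        y = (X["a"] - X["b"] + rng.normal(0, 0.4, 40)).to_numpy()
        res = vip_scores(y, X)
        assert 1 <= res.n_components <= 4
        assert len(res.press) == 4

    def test_signal_carriers_rank_highest(self, rng):
        """Two informative predictors out of six get the top-2 VIP scores."""
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(500 + rep)
            X = pd.DataFrame(r.normal(size=(150, 6)),
                             columns=[f"x{i}" for i in range(6)])
            y = (0.8 * X["x1"] - 0.6 * X["x4"]
                 + r.normal(0, 0.7, 150)).to_numpy()
            res = vip_scores(y, X, n_components=2)
            top2 = set(res.scores.nlargest(2).index)
            hits += top2 == {"x1", "x4"}
        assert hits >= 18

    def test_zero_variance_response_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        with pytest.raises(RegressionError):
            vip_scores(np.ones(20), X, n_components=1)


class TestPowerLaw:
    def test_exact_recovery(self):
        yc = np.linspace(200.0, 5000.0, 50)
        fr = 2.0 * yc**-0.5
        fit = fit_power_law(fr, yc)
        assert fit.a == pytest.approx(2.0, rel=1e-9)
        assert fit.b == pytest.approx(-0.5, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_flat_relation_gives_large_p(self, rng):
        yc = rng.uniform(300, 4000, 100)
        fr = np.exp(rng.normal(np.log(1.8), 0.3, 100))  # independent of yc
        fit = fit_power_law(fr, yc)
        assert abs(fit.b) < 0.2
        assert fit.p > 0.05

    def test_slope_coverage_under_noise(self):
        """|b_hat - b| < 2 se(b_hat) in >= 90% of replicates."""
        b_true, covered = -0.6, 0
        for rep in range(200):
            r = np.random.default_rng(900 + rep)
            yc = r.uniform(300, 4000, 200)
            fr = 30.0 * yc**b_true * np.exp(r.normal(0, 0.4, 200))
            fit = fit_power_law(fr, yc)
            covered += abs(fit.b - b_true) < 2 * fit.se_b
        assert covered >= 180

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(RegressionError):
            fit_power_law([1.0, 2.0, 3.0], [500.0, 500.0, 500.0])
        with pytest.raises(RegressionError):
            fit_power_law([1.0, -2.0, 3.0], [500.0, 600.0, 700.0])
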