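"""Missing-data cascade: sd recovery, the 1.5x rule, correlation-gated
linear imputation, and predictive mean matching."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fertmeta import imputation
from fertmeta.imputation import (
    ImputationError,
    PmmConfig,
    apply_linear_imputation,
    impute_cascade,
    impute_missing_sds,
    pairwise_correlations,
    plan_linear_imputation,
    pmm_impute,
    recover_sd,
    recover_sds,
)


class TestRecoverSd:
    @pytest.mark.parametrize(
        "sd, se, cv, mean, n, expected",
        [
            (np.nan, 100.0, np.nan, 2000.0, 4, 200.0),   # sd = se * sqrt(n)
            (np.nan, np.nan, 10.0, 2000.0, 3, 200.0),    # sd = cv * mean / 100
            (150.0, 100.0, 10.0, 2000.0, 4, 150.0),      # reported sd wins
        ],
    )
    def test_recovery_rules(self, sd, se, cv, mean, n, expected):
        assert recover_sd(sd, se, cv, mean, n) == pytest.approx(expected)

    def test_nothing_reported_gives_missing(self):
        assert np.isnan(recover_sd(np.nan, np.nan, np.nan, 2000.0, 3))

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            recover_sd(np.nan, -1.0, np.nan, 2000.0, 3)

    def test_frame_level_recovery(self, tiny_trials):
        df = tiny_trials.copy()
        df.loc[0, "yield_t_sd"] = np.nan
        df["yield_t_se"] = [100.0, np.nan, np.nan]
        out = recover_sds(df)
        assert out.loc[0, "yield_t_sd"] == pytest.approx(100.0 * np.sqrt(3))
        assert out.loc[1, "yield_t_sd"] == 250.0  # untouched


class TestSdImputationRule:
    def test_mean_times_multiplier(self):
        df = pd.DataFrame({
            "yield_t_sd": [100.0, np.nan], "yield_c_sd": [200.0, np.nan]})
        out = impute_missing_sds(df)
        assert out.loc[1, "yield_t_sd"] == pytest.approx(225.0)
        assert out.loc[1, "yield_c_sd"] == pytest.approx(225.0)
        assert bool(out.loc[1, "sd_t_imputed"]) and not bool(out.loc[0, "sd_t_imputed"])

    def test_single_reported_sd(self):
        df = pd.DataFrame({
            "yield_t_sd": [80.0, np.nan], "yield_c_sd": [np.nan, np.nan]})
        out = impute_missing_sds(df)
        filled = out[["yield_t_sd", "yield_c_sd"]].to_numpy()
        assert filled[0, 0] == 80.0
        assert np.allclose(filled[[0, 1], [1, 0]], 120.0)

    def test_complete_data_unchanged(self, tiny_trials):
        out = impute_missing_sds(tiny_trials)
        pd.testing.assert_frame_equal(out[["yield_t_sd", "yield_c_sd"]],
                                      tiny_trials[["yield_t_sd", "yield_c_sd"]])
        assert not out["sd_t_imputed"].any()

    def test_no_reported_sds_is_hard_error(self):
        df = pd.DataFrame({"yield_t_sd": [np.nan], "yield_c_sd": [np.nan]})
        with pytest.raises(ImputationError):
            impute_missing_sds(df)


class TestPairwiseCorrelations:
    def test_diagonal_and_perfect_pair(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        df["y"] = 2.0 * df["x"]
        corr = pairwise_correlations(df, ["x", "y"])
        assert corr.loc["x", "x"] == 1.0
        assert corr.loc["x", "y"] == pytest.approx(1.0)

    def test_independent_variables_near_zero(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10_000),
                           "b": rng.normal(size=10_000)})
        corr = pairwise_correlations(df, ["a", "b"])
        assert abs(corr.loc["a", "b"]) < 0.05

    def test_insufficient_pairs_missing(self):
        df = pd.DataFrame({"x": [1.0, 2.0, np.nan, np.nan],
                           "y": [1.0, np.nan, 3.0, np.nan]})
        corr = pairwise_correlations(df, ["x", "y"])
        assert np.isnan(corr.loc["x", "y"])
        assert corr.loc["x", "x"] == 1.0


def _correlated_frame(rng, n=60):
    """x and y strongly correlated, z independent; y has the most gaps."""
    x = rng.normal(10, 2, n)
    y = 2.0 * x + 1.0 + rng.normal(0, 0.3, n)
    z = rng.normal(0, 1, n)
    df = pd.DataFrame({"x": x, "y": y, "z": z})
    df.loc[df.index[:12], "y"] = np.nan
    df.loc[df.index[:5], "x"] = np.nan
    return df


class TestLinearImputationPlan:
    def test_gate_includes_strong_excludes_weak(self, rng):
        df = _correlated_frame(rng)
        plan = plan_linear_imputation(df, ["x", "y", "z"])
        assert {(p.kept, p.dropped) for p in plan.pairs} == {("x", "y")}
        assert plan.dropped_vars == {"y"}  # y has more missing values

    def test_below_threshold_pair_excluded(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)  # r ~ 0.45
        df = pd.DataFrame({"x": x, "y": y})
        plan = plan_linear_imputation(df, ["x", "y"])
        assert plan.pairs == []

    def test_greedy_keeps_only_top_pair_of_triplet(self, rng):
        n = 100
        a = rng.normal(size=n)
        b = a + rng.normal(0, 0.05, n)   # |r| ~ 0.999
        c = a + rng.normal(0, 0.3, n)    # still > 0.8 with both
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        plan = plan_linear_imputation(df, ["a", "b", "c"])
        assert len(plan.pairs) == 1
        assert {plan.pairs[0].kept, plan.pairs[0].dropped} == {"a", "b"}

    def test_tie_drops_later_variable(self, rng):
        n = 50
        a = rng.normal(size=n)
        df = pd.DataFrame({"a": a, "b": a + rng.normal(0, 0.05, n)})
        plan = plan_linear_imputation(df, ["a", "b"])  # zero missing each
        assert plan.pairs[0].kept == "a"
        assert plan.pairs[0].dropped == "b"

    def test_line_evaluation_and_gaps(self):
        plan = imputation.ImputationPlan(
            pairs=[imputation.LinearPair("y", "x", 2.0, 1.0, 0.95, 10)],
            dropped_vars={"x"})
        df = pd.DataFrame({"x": [10.0, np.nan, 3.0],
                           "y": [np.nan, np.nan, 99.0]})
        out = apply_linear_imputation(df, plan)
        assert out.loc[0, "y"] == pytest.approx(21.0)  # 2*10 + 1
        assert np.isnan(out.loc[1, "y"])               # both missing -> PMM
        assert out.loc[2, "y"] == 99.0                 # observed untouched
        assert list(out["y_imputed"]) == [True, False, False]


class TestPmm:
    def _frame(self, rng, n=500, miss=0.18):
        x1 = rng.normal(0, 1, n)
        x2 = rng.normal(0, 1, n)
        target = 0.8 * x1 - 0.5 * x2 + rng.normal(0, 0.6, n)
        df = pd.DataFrame({"target": target, "x1": x1, "x2": x2})
        mask = rng.random(n) < miss
        removed = df.loc[mask, "target"].copy()
        df.loc[mask, "target"] = np.nan
        return df, removed

    def test_no_missing_is_identity(self, tiny_trials):
        cfg = PmmConfig(variables=("soil_ph", "total_c"), seed=1)
        out = pmm_impute(tiny_trials, cfg)
        pd.testing.assert_frame_equal(out, tiny_trials)

    def test_imputations_live_in_observed_support(self, rng):
        df, _ = self._frame(rng)
        observed = set(df["target"].dropna())
        cfg = PmmConfig(variables=("target", "x1", "x2"), seed=7)
        out = pmm_impute(df, cfg)
        assert out["target"].notna().all()
        assert set(out["target"]) <= observed | set(df["target"].dropna())
        assert out["target"].min() >= df["target"].min()
        assert out["target"].max() <= df["target"].max()

    def test_mcar_mean_recovery(self, rng):
        df, removed = self._frame(rng)
        cfg = PmmConfig(variables=("target", "x1", "x2"), seed=11)
        out = pmm_impute(df, cfg)
        imputed = out.loc[removed.index, "target"]
        sd = np.concatenate([df["target"].dropna(), removed]).std(ddof=1)
        assert abs(imputed.mean() - removed.mean()) < 0.15 * sd

    def test_marginal_distribution_preserved(self, rng):
        df, removed = self._frame(rng)
        full = np.concatenate([df["target"].dropna(), removed])
        cfg = PmmConfig(variables=("target", "x1", "x2"), seed=3)
        out = pmm_impute(df, cfg)
        ks = stats.ks_2samp(full, out["target"])
        assert ks.pvalue > 0.01

    def test_deterministic_under_seed(self, rng):
        df, _ = self._frame(rng)
        cfg = PmmConfig(variables=("target", "x1", "x2"), seed=5)
        out1 = pmm_impute(df, cfg)
        out2 = pmm_impute(df, cfg)
        pd.testing.assert_frame_equal(out1, out2)

    def test_too_few_observed_values_raise(self):
        df = pd.DataFrame({"a": [1.0, np.nan, np.nan, np.nan, np.nan, np.nan],
                           "b": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        with pytest.raises(ImputationError, match="'a'"):
            pmm_impute(df, PmmConfig(variables=("a", "b"), k=5))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PmmConfig(variables=("a",), k=0)
        with pytest.raises(ValueError):
            PmmConfig(variables=("a",), iterations=0)


class TestCascade:
    def test_rerun_is_noop(self, rng):
        n = 80
        x = rng.normal(10, 2, n)
        df = pd.DataFrame({
            "yield_t_mean": rng.uniform(1000, 4000, n),
            "yield_c_mean": rng.uniform(500, 2000, n),
            "yield_t_sd": np.where(rng.random(n) < 0.7, rng.uniform(50, 400, n),
                                   np.nan),
            "yield_c_sd": np.where(rng.random(n) < 0.7, rng.uniform(50, 400, n),
                                   np.nan),
            "n_t": 3.0, "n_c": 3.0,
            "x": np.where(rng.random(n) < 0.9, x, np.nan),
            "y": np.where(rng.random(n) < 0.8, 2 * x + rng.normal(0, 0.2, n),
                          np.nan),
            "z": np.where(rng.random(n) < 0.85, rng.normal(size=n), np.nan),
        })
        once, _ = impute_cascade(df, ["x", "y", "z"], seed=4)
        twice, _ = impute_cascade(once, ["x", "y", "z"], seed=4)
        pd.testing.assert_frame_equal(once, twice)
        assert once[["x", "z"]].notna().all().all()
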