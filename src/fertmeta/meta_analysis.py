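"""Random-effects meta-analysis of the log response ratio.

Model: y_i ~ Normal(μ, v_i + τ²) with known sampling variances v_i and
between-observation variance τ² estimated by restricted maximum
likelihood (REML).  The intercept-only model makes the restricted
likelihood a one-dimensional function of τ², so the fit is a bounded
scalar optimization rather than a general solver.

Also provided: Cochran's heterogeneity statistic Q_T with its chi-square
test, fixed-effect weighted subgroup means with normal 95% CIs and the
CI-overlap decision rules, a weighted regression (Egger-type) funnel
asymmetry test, the Duval–Tweedie trim-and-fill procedure with the L0
estimator, and plot-ready funnel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Normal 97.5% quantile used for all 95% confidence intervals.
Z_975 = 1.959964


class MetaAnalysisError(ValueError):
    pass


def _check_yv(y, v, min_k: int = 1):
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if y.shape != v.shape or y.ndim != 1:
        raise MetaAnalysisError("y and v must be 1-d arrays of equal length")
    if len(y) < min_k:
        raise MetaAnalysisError(f"need at least {min_k} records, got {len(y)}")
    if np.any(v <= 0):
        raise MetaAnalysisError("all sampling variances must be > 0")
    return y, v


# ---------------------------------------------------------------------------
# heterogeneity


def q_statistic(y, v) -> tuple[float, int, float]:
    """Cochran's Q_T with df = k−1 and the chi-square upper-tail p-value."""
    y, v = _check_yv(y, v, min_k=1)
    k = len(y)
    w = 1.0 / v
    ybar = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - ybar) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return q, df, p


# ---------------------------------------------------------------------------
# REML random-effects fit


@dataclass(frozen=True)
class REFit:
    """Pooled random-effects estimate with heterogeneity diagnostics."""

    mu: float
    se_mu: float
    tau2: float
    q_t: float
    df: int
    p_q: float
    k: int

    @property
    def ci(self) -> tuple[float, float]:
        return self.mu - Z_975 * self.se_mu, self.mu + Z_975 * self.se_mu


def _reml_nll(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """Negative restricted log-likelihood of the intercept-only RE model."""
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return 0.5 * (np.sum(np.log(v + tau2)) + np.log(np.sum(w))
                  + np.sum(w * (y - mu) ** 2))


def fit_random_effects(y, v, tol: float = 1e-8) -> REFit:
    """REML fit of y_i ~ Normal(μ, v_i + τ²) over τ² ≥ 0.

    τ² is found by bounded scalar minimization of the restricted negative
    log-likelihood on [0, 10·var(y)]; the boundary τ² = 0 is checked
    explicitly so homogeneous data give exactly zero.
    """
    y, v = _check_yv(y, v, min_k=2)
    var_y = float(np.var(y, ddof=1))
    if var_y == 0.0:
        tau2 = 0.0
    else:
        upper = 10.0 * var_y
        res = optimize.minimize_scalar(
            _reml_nll, bounds=(0.0, upper), args=(y, v),
            method="bounded", options={"xatol": tol, "maxiter": 500},
        )
        if not res.success:
            raise MetaAnalysisError(f"REML optimization failed: {res.message}")
        tau2 = float(res.x)
        if _reml_nll(0.0, y, v) <= res.fun:
            tau2 = 0.0
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se_mu = float(np.sum(w) ** -0.5)
    q, df, p = q_statistic(y, v)
    return REFit(mu=mu, se_mu=se_mu, tau2=tau2, q_t=q, df=df, p_q=p, k=len(y))


# ---------------------------------------------------------------------------
# subgroup comparison


def subgroup_weighted_means(
    effects: pd.DataFrame,
    variable: str,
    value_col: str = "ln_fr",
    var_col: str = "fr_var",
    weighting: str = "fixed",
    tau2: float = 0.0,
) -> pd.DataFrame:
    """Inverse-variance weighted mean of ln FR per level of a categorical.

    Weights are w_i = 1/v_i (``weighting="fixed"``, the default) or
    1/(v_i + τ²) (``weighting="random"``, with ``tau2`` supplied).  CIs
    use the normal 97.5% quantile; the back-transformed FR and its CI are
    reported alongside.  Rows with a missing level are excluded; their
    count is stored in ``result.attrs["n_missing_level"]``.
    """
    if weighting not in ("fixed", "random"):
        raise ValueError("weighting must be 'fixed' or 'random'")
    data = effects[[variable, value_col, var_col]]
    n_missing = int(data[variable].isna().sum())
    data = data.dropna(subset=[variable])
    rows = []
    for level, grp in data.groupby(variable, observed=True, sort=True):
        y = grp[value_col].to_numpy(dtype=float)
        v = grp[var_col].to_numpy(dtype=float)
        if np.any(v <= 0):
            raise MetaAnalysisError(f"non-positive variance in level {level!r}")
        w = 1.0 / (v + (tau2 if weighting == "random" else 0.0))
        mean = float(np.sum(w * y) / np.sum(w))
        se = float(np.sum(w) ** -0.5)
        lo, hi = mean - Z_975 * se, mean + Z_975 * se
        rows.append({
            "variable": variable, "level": level, "k": len(y),
            "ln_fr_w": mean, "se_w": se, "ci_low": lo, "ci_high": hi,
            "fr_w": float(np.exp(mean)),
            "fr_ci_low": float(np.exp(lo)), "fr_ci_high": float(np.exp(hi)),
            "differs_from_no_effect": bool(lo > 0 or hi < 0),
        })
    if not rows:
        raise MetaAnalysisError(f"no records with a level for {variable!r}")
    out = pd.DataFrame(rows)
    out.attrs["n_missing_level"] = n_missing
    return out


def compare_subgroups(summaries: pd.DataFrame) -> pd.DataFrame:
    """Pairwise CI-disjointness flags between levels of one variable.

    Two levels are declared different iff their 95% CIs do not overlap.
    """
    rows = []
    recs = summaries.to_dict("records")
    for i, a in enumerate(recs):
        for b in recs[i + 1:]:
            disjoint = a["ci_high"] < b["ci_low"] or b["ci_high"] < a["ci_low"]
            rows.append({"level_a": a["level"], "level_b": b["level"],
                         "differ": bool(disjoint)})
    return pd.DataFrame(rows, columns=["level_a", "level_b", "differ"])


# ---------------------------------------------------------------------------
# publication bias


@dataclass(frozen=True)
class EggerResult:
    slope: float
    se_slope: float
    z: float
    p: float
    intercept: float


def egger_regression_test(y, v) -> EggerResult:
    """Funnel-asymmetry regression test: effect on its standard error.

    Weighted least squares of y_i on √v_i with weights 1/v_i; the test
    statistic is z = slope/se(slope) against the standard normal.
    """
    y, v = _check_yv(y, v, min_k=3)
    se = np.sqrt(v)
    if np.ptp(se) == 0:
        raise MetaAnalysisError("all standard errors equal; regression test "
                                "design is degenerate")
    import statsmodels.api as sm

    X = sm.add_constant(se)
    fit = sm.WLS(y, X, weights=1.0 / v).fit()
    slope = float(fit.params[1])
    se_slope = float(fit.bse[1])
    z = slope / se_slope
    p = float(2.0 * stats.norm.sf(abs(z)))
    return EggerResult(slope=slope, se_slope=se_slope, z=z, p=p,
                       intercept=float(fit.params[0]))


@dataclass
class TrimFillResult:
    k0: int
    side: str
    center: float
    adjusted_mu: float
    filled_y: np.ndarray = field(default_factory=lambda: np.empty(0))
    filled_v: np.ndarray = field(default_factory=lambda: np.empty(0))
    iterations: int = 0


def _fixed_effect_mean(y, v):
    w = 1.0 / v
    return float(np.sum(w * y) / np.sum(w))


def trim_and_fill(y, v, side: str = "auto", max_iter: int = 100) -> TrimFillResult:
    """Duval–Tweedie trim-and-fill with the L0 estimator.

    ``side`` names the side of the funnel where studies are presumed
    missing; ``"auto"`` picks it from the skewness of effects about the
    fixed-effect center (positive skew → long right tail → missing left).
    The k0 most extreme effects on the opposite side are trimmed, the
    center re-estimated, and the L0 count recomputed until it stabilizes;
    filled pseudo-records are mirror images of the extremes about the
    final center, and ``adjusted_mu`` is the fixed-effect pooled mean of
    observed + filled records.
    """
    y, v = _check_yv(y, v, min_k=3)
    if side not in ("left", "right", "auto"):
        raise ValueError("side must be 'left', 'right' or 'auto'")
    if side == "auto":
        center0 = _fixed_effect_mean(y, v)
        skew = float(stats.skew(y - center0))
        side = "left" if skew >= 0 else "right"
    # Work on a flipped axis so suppression is always on the left and the
    # candidate extremes to trim are the largest values.
    sign = 1.0 if side == "left" else -1.0
    z = sign * y
    order = np.argsort(z)          # ascending; extremes at the end
    z_sorted = z[order]
    v_sorted = v[order]
    n = len(z)

    k0 = 0
    iterations = 0
    for iterations in range(1, max_iter + 1):
        trimmed = z_sorted[: n - k0] if k0 else z_sorted
        trimmed_v = v_sorted[: n - k0] if k0 else v_sorted
        center = _fixed_effect_mean(trimmed, trimmed_v)
        d = z_sorted - center
        ranks = stats.rankdata(np.abs(d))
        t_sum = float(ranks[d > 0].sum())
        l0 = (4.0 * t_sum - n * (n + 1.0)) / (2.0 * n - 1.0)
        k0_new = max(0, int(round(l0)))
        k0_new = min(k0_new, n - 2)  # keep at least two records after trimming
        if k0_new == k0:
            break
        k0 = k0_new
    else:
        raise MetaAnalysisError(f"trim-and-fill did not stabilize in {max_iter} "
                                "iterations")

    if k0 > 0:
        extremes = z_sorted[n - k0:]
        filled_z = 2.0 * center - extremes
        filled_v = v_sorted[n - k0:]
        all_z = np.concatenate([z_sorted, filled_z])
        all_v = np.concatenate([v_sorted, filled_v])
    else:
        filled_z = np.empty(0)
        filled_v = np.empty(0)
        all_z, all_v = z_sorted, v_sorted
    adjusted = _fixed_effect_mean(all_z, all_v)
    return TrimFillResult(
        k0=k0, side=side, center=sign * center, adjusted_mu=sign * adjusted,
        filled_y=sign * filled_z, filled_v=filled_v, iterations=iterations,
    )


def funnel_data(effects: pd.DataFrame,
                value_col: str = "ln_fr", var_col: str = "fr_var") -> pd.DataFrame:
    """(effect, standard error) pairs for funnel plotting, one per record."""
    out = pd.DataFrame({
        "effect": effects[value_col].to_numpy(dtype=float),
        "se": np.sqrt(effects[var_col].to_numpy(dtype=float)),
    })
    return out
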