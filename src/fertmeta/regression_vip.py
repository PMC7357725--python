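"""Standardized regression on continuous moderators and PLS-based
variable importance.

The response (ln FR or N-AE) is modelled by ordinary least squares on
predictors that are first log-transformed where their marginal
distribution is skewed (default recipe: total C, P-Olsen, N rate,
exchangeable K, silt and rainfall logged; soil pH and clay left on their
original scale) and then scaled to unit sample standard deviation
*without centering*, so every factor enters the model on an equal
footing.  Scale-only standardization leaves slope t-statistics and
p-values identical to the unstandardized fit.

Predictor importance is ranked by VIP (variable importance in
projection) scores from a partial-least-squares decomposition of the
same (X, y):

    VIP_j = sqrt( p · Σ_a SS_a (w_aj / ‖w_a‖)² / Σ_a SS_a )

where SS_a is the response variance captured by component a and w_a its
X-weight vector.  Σ_j VIP_j² = p always; predictors with VIP > 1 are
conventionally called important.

The empirical fertilizer-response decline with control-plot yield is
summarized by the power law FR = a·(control yield)^b, fit as OLS on the
log-log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cross_decomposition import PLSRegression

#: Predictors log-transformed by default before standardization.
DEFAULT_LOG_VARS = ("total_c", "p_olsen", "n_rate", "exch_k", "silt", "rainfall")

#: Conventional importance threshold for VIP scores.
VIP_THRESHOLD = 1.0


class RegressionError(ValueError):
    pass


def transform_predictors(
    table: pd.DataFrame,
    log_vars: tuple[str, ...] = DEFAULT_LOG_VARS,
    on_nonpositive: str = "raise",
) -> pd.DataFrame:
    """Natural-log transform the configured predictors; rename ``log_<var>``.

    ``on_nonpositive`` is ``"raise"`` (default) or ``"drop"`` (rows with a
    non-positive value in any logged column are removed).
    """
    if on_nonpositive not in ("raise", "drop"):
        raise ValueError("on_nonpositive must be 'raise' or 'drop'")
    out = table.copy()
    present = [v for v in log_vars if v in out.columns]
    if on_nonpositive == "drop" and present:
        keep = np.ones(len(out), dtype=bool)
        for var in present:
            vals = out[var].to_numpy(dtype=float)
            keep &= ~(vals <= 0)  # NaN stays (not our concern here)
        out = out.loc[keep].reset_index(drop=True)
    for var in present:
        vals = out[var].to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise RegressionError(f"non-positive value in {var!r} under log "
                                  "transform")
        out[f"log_{var}"] = np.log(vals)
        out = out.drop(columns=var)
    return out


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each column by its sample sd (no centering); return scales.

    The returned ``scales`` Series maps column name to the divisor, so
    coefficients can be mapped back to the original units.
    """
    scales = table.std(ddof=1)
    bad = scales[(scales == 0) | scales.isna()]
    if len(bad):
        raise RegressionError(f"constant column(s): {', '.join(bad.index)}")
    return table / scales, scales


@dataclass(frozen=True)
class GlmFit:
    """OLS fit summary for one response / one region."""

    response: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r2: float
    adjusted_r2: float
    n: int

    def coefficient_table(self) -> pd.DataFrame:
        codes = pd.cut(
            self.pvalues, bins=[-np.inf, 0.001, 0.01, 0.05, 0.1, np.inf],
            labels=["***", "**", "*", ".", ""],
        ).astype(str)
        return pd.DataFrame({
            "predictor": self.params.index,
            "estimate": self.params.to_numpy(),
            "std_error": self.bse.to_numpy(),
            "p_value": self.pvalues.to_numpy(),
            "signif": codes.to_numpy(),
        })


def fit_glm(y, X: pd.DataFrame, response: str = "ln_fr") -> GlmFit:
    """Ordinary least squares with intercept on standardized predictors."""
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise RegressionError(f"need n > p + 1 (n={n}, p={p})")
    design = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, design).fit()
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise RegressionError("rank-deficient design matrix")
    return GlmFit(
        response=response,
        params=fit.params.rename(index={"const": "intercept"}),
        bse=fit.bse.rename(index={"const": "intercept"}),
        pvalues=fit.pvalues.rename(index={"const": "intercept"}),
        r2=float(fit.rsquared),
        adjusted_r2=float(fit.rsquared_adj),
        n=n,
    )


@dataclass(frozen=True)
class VipResult:
    scores: pd.Series
    n_components: int
    threshold: float = VIP_THRESHOLD
    press: tuple[float, ...] = field(default=())

    @property
    def important(self) -> set[str]:
        return set(self.scores.index[self.scores > self.threshold])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "predictor": self.scores.index,
            "vip": self.scores.to_numpy(),
            "important": (self.scores > self.threshold).to_numpy(),
        })


def _vip_from_pls(pls: PLSRegression, p: int) -> np.ndarray:
    W = pls.x_weights_                     # (p, a)
    T = pls.x_scores_                      # (n, a)
    q = pls.y_loadings_.ravel()            # (a,)
    ss = q**2 * np.sum(T**2, axis=0)       # response variance per component
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wnorm2 @ ss) / ss.sum())


def _loo_press(y: np.ndarray, X: np.ndarray, n_components: int) -> float:
    press = 0.0
    n = len(y)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(X[keep], y[keep])
        pred = pls.predict(X[i: i + 1]).ravel()[0]
        press += (y[i] - pred) ** 2
    return press


def vip_scores(y, X: pd.DataFrame, n_components: int | None = None,
               max_components: int = 10) -> VipResult:
    """VIP scores from a PLS fit of (X, y).

    With ``n_components=None`` the component count minimizing leave-one-out
    cross-validated squared prediction error is used, capped at
    ``min(p, max_components)``.
    """
    y = np.asarray(y, dtype=float)
    if np.var(y) == 0:
        raise RegressionError("response has zero variance")
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    cap = min(p, max_components, n - 1)
    press: tuple[float, ...] = ()
    if n_components is None:
        press = tuple(_loo_press(y, Xv, a) for a in range(1, cap + 1))
        n_components = int(np.argmin(press)) + 1
    if not 1 <= n_components <= cap:
        raise RegressionError(f"n_components must be in [1, {cap}]")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xv, y)
    scores = pd.Series(_vip_from_pls(pls, p), index=X.columns, name="vip")
    return VipResult(scores=scores, n_components=n_components, press=press)


@dataclass(frozen=True)
class PowerLawFit:
    """FR = a · (control yield)^b, fit on the log-log scale."""

    a: float
    b: float
    se_b: float
    se_ln_a: float
    r2: float
    p: float
    n: int

    def predict(self, control_yield) -> np.ndarray:
        return self.a * np.asarray(control_yield, dtype=float) ** self.b


def fit_power_law(fr, control_yield) -> PowerLawFit:
    """OLS of ln FR on ln(control yield): a = exp(intercept), b = slope."""
    fr = np.asarray(fr, dtype=float)
    yc = np.asarray(control_yield, dtype=float)
    if np.any(fr <= 0) or np.any(yc <= 0):
        raise RegressionError("fr and control yield must be > 0")
    if len(fr) < 3:
        raise RegressionError("need at least 3 points")
    if np.ptp(yc) == 0:
        raise RegressionError("all control yields equal; slope undefined")
    X = sm.add_constant(np.log(yc))
    fit = sm.OLS(np.log(fr), X).fit()
    return PowerLawFit(
        a=float(np.exp(fit.params[0])), b=float(fit.params[1]),
        se_b=float(fit.bse[1]), se_ln_a=float(fit.bse[0]),
        r2=float(fit.rsquared), p=float(fit.pvalues[1]), n=len(fr),
    )
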