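"""Missing-data cascade for the trial database.

Order is fixed and matters::

    recover_sds -> impute_missing_sds -> plan/apply linear imputation -> pmm_impute

1. Variance recovery: a reported sd wins; otherwise sd = se·√n, otherwise
   sd = cv·mean/100.
2. Remaining missing sds are set to 1.5x the mean of all reported sds
   (treatment and control arms pooled).
3. Strongly correlated soil-property pairs (Pearson r above a gate,
   default 0.8) are collapsed: the member with more missing values is
   dropped from later analysis, after an OLS line fit on complete pairs
   fills gaps in the retained member wherever the dropped one is observed.
4. Predictive mean matching (chained equations) fills whatever is left:
   each missing value receives the observed value of a donor whose
   model-predicted mean is among the k nearest to the missing case's
   prediction, so imputations always live in the observed support.

Every imputed cell is flagged in a ``*_imputed`` boolean column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ImputationError(ValueError):
    pass


@dataclass(frozen=True)
class LinearPair:
    """One correlation-gated pair: ``kept`` is predicted from ``dropped``."""

    kept: str
    dropped: str
    slope: float
    intercept: float
    r: float
    n: int


@dataclass
class ImputationPlan:
    pairs: list[LinearPair] = field(default_factory=list)
    dropped_vars: set[str] = field(default_factory=set)
    threshold_r: float = 0.8


@dataclass
class PmmConfig:
    """Settings for predictive-mean-matching chained imputation."""

    variables: tuple[str, ...]
    k: int = 5
    iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("donor count k must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


# ---------------------------------------------------------------------------
# sd recovery and the 1.5x rule


def recover_sd(sd, se, cv, mean, n):
    """Best available sd for one arm: sd, else se·√n, else cv·mean/100."""
    if sd is not None and not np.isnan(sd):
        return float(sd)
    if se is not None and not np.isnan(se):
        if se < 0:
            raise ValueError("standard error must be >= 0")
        return float(se) * float(np.sqrt(n))
    if cv is not None and not np.isnan(cv):
        if cv < 0:
            raise ValueError("coefficient of variation must be >= 0")
        return float(cv) * float(mean) / 100.0
    return float("nan")


def recover_sds(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`recover_sd` over both arms of a trial table."""
    out = df.copy()
    for arm in ("t", "c"):
        sd_col, se_col, cv_col = f"yield_{arm}_sd", f"yield_{arm}_se", f"yield_{arm}_cv"
        mean_col, n_col = f"yield_{arm}_mean", f"n_{arm}"
        for c in (se_col, cv_col):
            if c in out and (out[c].dropna() < 0).any():
                raise ValueError(f"negative values in {c}")
        sd = out[sd_col] if sd_col in out else pd.Series(np.nan, index=out.index)
        if se_col in out:
            from_se = out[se_col] * np.sqrt(out[n_col])
            sd = sd.where(sd.notna(), from_se)
        if cv_col in out:
            from_cv = out[cv_col] * out[mean_col] / 100.0
            sd = sd.where(sd.notna(), from_cv)
        out[sd_col] = sd
    return out


def impute_missing_sds(df: pd.DataFrame, multiplier: float = 1.5) -> pd.DataFrame:
    """Fill remaining missing sds with ``multiplier`` x mean of reported sds.

    Treatment and control sds are pooled into one mean.  Raises if no sd
    was reported anywhere.  Flags land in ``sd_t_imputed``/``sd_c_imputed``.
    """
    out = df.copy()
    reported = pd.concat([out["yield_t_sd"], out["yield_c_sd"]]).dropna()
    if reported.empty:
        raise ImputationError("no reported sds anywhere; cannot apply the "
                              f"{multiplier}x-mean rule")
    fill = multiplier * float(reported.mean())
    for arm in ("t", "c"):
        col = f"yield_{arm}_sd"
        flag = f"sd_{arm}_imputed"
        missing = out[col].isna()
        if flag in out:  # keep provenance across repeated cascade runs
            out[flag] = out[flag].fillna(False).astype(bool) | missing
        else:
            out[flag] = missing
        out.loc[missing, col] = fill
    return out


# ---------------------------------------------------------------------------
# correlation-gated linear imputation


def pairwise_correlations(
    df: pd.DataFrame, variables: list[str], min_pairs: int = 3
) -> pd.DataFrame:
    """Pearson r on pairwise-complete observations; diagonal forced to 1.

    Entries backed by fewer than ``min_pairs`` complete pairs are missing.
    """
    corr = df[list(variables)].corr(method="pearson", min_periods=min_pairs)
    counts = df[list(variables)].notna().astype(int)
    npairs = counts.T @ counts
    corr = corr.where(npairs >= min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def plan_linear_imputation(
    df: pd.DataFrame,
    variables: list[str],
    threshold_r: float = 0.8,
    use_abs_r: bool = False,
    min_pairs: int = 3,
) -> ImputationPlan:
    """Select correlated pairs and fit the lines used to fill the kept member.

    Pairs with r > ``threshold_r`` (or |r| with ``use_abs_r``) are taken
    greedily by descending |r|; a variable joins at most one pair.  Within a
    pair the variable with more missing values is dropped (ties broken by
    dropping the one later in ``variables``), and an OLS line predicting
    the kept variable from the dropped one is fit on complete pairs.
    """
    corr = pairwise_correlations(df, variables, min_pairs=min_pairs)
    missing = df[list(variables)].isna().sum()
    order = {v: i for i, v in enumerate(variables)}

    candidates = []
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            r = corr.loc[a, b]
            if pd.isna(r):
                continue
            score = abs(r) if use_abs_r else r
            if score > threshold_r:
                candidates.append((abs(r), a, b, float(r)))
    candidates.sort(key=lambda t: (-t[0], order[t[1]], order[t[2]]))

    plan = ImputationPlan(threshold_r=threshold_r)
    used: set[str] = set()
    for _, a, b, r in candidates:
        if a in used or b in used:
            continue
        if missing[a] > missing[b] or (missing[a] == missing[b] and order[a] > order[b]):
            dropped, kept = a, b
        else:
            dropped, kept = b, a
        complete = df[[kept, dropped]].dropna()
        slope, intercept = np.polyfit(complete[dropped], complete[kept], 1)
        plan.pairs.append(LinearPair(kept, dropped, float(slope),
                                     float(intercept), r, len(complete)))
        plan.dropped_vars.add(dropped)
        used.update((a, b))
    return plan


def apply_linear_imputation(df: pd.DataFrame, plan: ImputationPlan) -> pd.DataFrame:
    """Fill kept-variable gaps from the paired line where the partner is observed.

    Rows where both members are missing stay missing (left for PMM).
    """
    out = df.copy()
    for pair in plan.pairs:
        flag = f"{pair.kept}_imputed"
        if flag not in out:
            out[flag] = False
        mask = out[pair.kept].isna() & out[pair.dropped].notna()
        out.loc[mask, pair.kept] = (
            pair.slope * out.loc[mask, pair.dropped] + pair.intercept
        )
        out.loc[mask, flag] = True
    return out


# ---------------------------------------------------------------------------
# predictive mean matching


def _draw_coefficients(rng, X, y):
    """OLS fit with a stochastic draw from the coefficient sampling distribution."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X, hermitian=True)
    beta_star = rng.multivariate_normal(beta, cov, method="eigh")
    return beta, beta_star


def pmm_impute(df: pd.DataFrame, config: PmmConfig) -> pd.DataFrame:
    """Chained predictive-mean-matching imputation over ``config.variables``.

    Each pass regresses the target on all other configured variables
    (current working values), perturbs the coefficients by a draw from
    their estimated sampling distribution, and matches every missing case
    to one of the ``k`` observed cases with nearest predicted mean,
    copying the donor's observed value.  Deterministic under a fixed seed;
    every imputed value is an observed value of the same variable.
    """
    variables = list(config.variables)
    rng = np.random.default_rng(config.seed)
    out = df.copy()
    X = out[variables].to_numpy(dtype=float)
    observed = ~np.isnan(X)

    if observed.all():
        return out

    for j, var in enumerate(variables):
        n_obs = int(observed[:, j].sum())
        if n_obs < config.k:
            raise ImputationError(
                f"variable {var!r} has {n_obs} observed values; "
                f"need at least k={config.k}")

    # initial fill: random draws from each variable's observed values
    work = X.copy()
    for j in range(len(variables)):
        miss = ~observed[:, j]
        if miss.any():
            pool = X[observed[:, j], j]
            work[miss, j] = rng.choice(pool, size=int(miss.sum()))

    for _ in range(config.iterations):
        for j, var in enumerate(variables):
            miss = ~observed[:, j]
            if not miss.any():
                continue
            obs = observed[:, j]
            others = [c for c in range(len(variables)) if c != j]
            A = np.column_stack([np.ones(len(work)), work[:, others]])
            y_obs = X[obs, j]
            beta, beta_star = _draw_coefficients(rng, A[obs], y_obs)
            pred_obs = A[obs] @ beta
            pred_mis = A[miss] @ beta_star
            # k nearest observed predictions; donor picked uniformly
            dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
            k = min(config.k, len(y_obs))
            nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
            pick = rng.integers(0, k, size=len(pred_mis))
            donors = nearest[np.arange(len(pred_mis)), pick]
            work[miss, j] = y_obs[donors]

    for j, var in enumerate(variables):
        miss = ~observed[:, j]
        flag = f"{var}_imputed"
        if flag not in out:
            out[flag] = False
        out.loc[miss, flag] = True
        out[var] = work[:, j]
    return out


def impute_cascade(
    df: pd.DataFrame,
    soil_variables: list[str],
    sd_multiplier: float = 1.5,
    threshold_r: float = 0.8,
    use_abs_r: bool = False,
    pmm_k: int = 5,
    pmm_iterations: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, ImputationPlan]:
    """Run the full cascade in its fixed order; re-running is a no-op."""
    out = recover_sds(df)
    out = impute_missing_sds(out, multiplier=sd_multiplier)
    plan = plan_linear_imputation(out, soil_variables, threshold_r=threshold_r,
                                  use_abs_r=use_abs_r)
    out = apply_linear_imputation(out, plan)
    pmm_vars = tuple(v for v in soil_variables if v not in plan.dropped_vars)
    config = PmmConfig(variables=pmm_vars, k=pmm_k,
                       iterations=pmm_iterations, seed=seed)
    out = pmm_impute(out, config)
    return out, plan
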