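"""Per-observation effect sizes: log response ratio, its sampling variance,
agronomic N use efficiency, and soil-responsiveness classification.

The fertilizer response FR is the ratio of the fertilized-plot mean yield
x̄_t to the control-plot mean yield x̄_c; analysis runs on ln FR (the log
response ratio).  Its delta-method sampling variance is

    v = sd_t² / (n_t · x̄_t²) + sd_c² / (n_c · x̄_c²)

Agronomic nitrogen use efficiency is the yield gain per kg applied N,
N-AE = (x̄_t − x̄_c)/FN in kg dry weight per kg N; it is not an effect
size (no sampling variance) and is summarized descriptively.

Responsiveness classes: FR > 1 is *responsive*; FR ≤ 1 is non-responsive
and split by control yield into *fertile* (control yield above a benchmark,
default 1125 kg ha⁻¹) and *poor* non-responsive soils.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RESPONSIVE = "responsive"
POOR_NONRESPONSIVE = "poor_nonresponsive"
FERTILE_NONRESPONSIVE = "fertile_nonresponsive"

#: Control-yield benchmark (kg ha⁻¹) separating fertile from poor
#: non-responsive soils on smallholder farms in SSA.
FERTILE_YIELD_THRESHOLD = 1125.0

#: Moderator columns carried from the trial table onto effect records.
MODERATOR_COLUMNS = (
    "study_id", "site_id", "region",
    "soil_order", "texture_class", "aez", "nutrient_type", "manager",
    "n_rate", "soil_ph", "total_c", "total_n", "p_olsen",
    "exch_k", "exch_ca", "exch_mg", "clay", "sand", "silt",
    "rainfall", "altitude", "yield_c_mean", "yield_t_mean",
)


def ln_fr(yield_t_mean, yield_c_mean):
    """Log response ratio ln(x̄_t / x̄_c); both means must be positive."""
    t = np.asarray(yield_t_mean, dtype=float)
    c = np.asarray(yield_c_mean, dtype=float)
    if np.any(t <= 0) or np.any(c <= 0):
        raise ValueError("yield means must be > 0")
    out = np.log(t / c)
    return float(out) if out.ndim == 0 else out


def fr_variance(sd_t, n_t, yield_t_mean, sd_c, n_c, yield_c_mean):
    """Delta-method sampling variance of the log response ratio."""
    sd_t = np.asarray(sd_t, dtype=float)
    sd_c = np.asarray(sd_c, dtype=float)
    n_t = np.asarray(n_t, dtype=float)
    n_c = np.asarray(n_c, dtype=float)
    mt = np.asarray(yield_t_mean, dtype=float)
    mc = np.asarray(yield_c_mean, dtype=float)
    if np.any(mt <= 0) or np.any(mc <= 0):
        raise ValueError("yield means must be > 0")
    if np.any(n_t < 1) or np.any(n_c < 1):
        raise ValueError("replicate counts must be >= 1")
    if np.any(sd_t < 0) or np.any(sd_c < 0):
        raise ValueError("sds must be >= 0")
    out = sd_t**2 / (n_t * mt**2) + sd_c**2 / (n_c * mc**2)
    return float(out) if out.ndim == 0 else out


def n_ae(yield_t_mean, yield_c_mean, n_rate):
    """Agronomic N use efficiency (x̄_t − x̄_c)/FN, kg dw per kg N.

    Requires FN > 0 (unfertilized controls are not efficiency-scored).
    Negative values are legitimate: fertilization can depress yield.
    """
    fn = np.asarray(n_rate, dtype=float)
    if np.any(fn <= 0):
        raise ValueError("N rate must be > 0 to compute N-AE")
    out = (np.asarray(yield_t_mean, float) - np.asarray(yield_c_mean, float)) / fn
    return float(out) if out.ndim == 0 else out


def classify_responsiveness(fr, yield_c_mean,
                            fertile_threshold: float = FERTILE_YIELD_THRESHOLD):
    """Assign each (FR, control yield) pair to exactly one responsiveness class.

    FR > 1 → responsive; FR ≤ 1 with control yield above the benchmark →
    fertile non-responsive; otherwise poor non-responsive.  The FR = 1
    boundary (no response) is non-responsive.
    """
    fr_arr = np.asarray(fr, dtype=float)
    yc = np.asarray(yield_c_mean, dtype=float)
    if np.any(fr_arr <= 0) or np.any(yc <= 0):
        raise ValueError("fr and control yield must be > 0")
    out = np.where(
        fr_arr > 1.0, RESPONSIVE,
        np.where(yc > fertile_threshold, FERTILE_NONRESPONSIVE, POOR_NONRESPONSIVE),
    )
    return str(out[()]) if out.ndim == 0 else out


def compute_effects(df: pd.DataFrame,
                    fertile_threshold: float = FERTILE_YIELD_THRESHOLD) -> pd.DataFrame:
    """Build the effects table from a harmonized, sd-complete trial table.

    One row per observation with ``ln_fr``, ``fr``, ``fr_var``, ``n_ae``
    (missing where FN = 0), ``responsiveness`` and all moderators present
    in ``df``.
    """
    effects = pd.DataFrame(index=df.index)
    effects["ln_fr"] = ln_fr(df["yield_t_mean"], df["yield_c_mean"])
    effects["fr"] = np.exp(effects["ln_fr"])
    effects["fr_var"] = fr_variance(
        df["yield_t_sd"], df["n_t"], df["yield_t_mean"],
        df["yield_c_sd"], df["n_c"], df["yield_c_mean"],
    )
    fn = df["n_rate"].to_numpy(dtype=float)
    nae = np.full(len(df), np.nan)
    pos = fn > 0
    nae[pos] = (df["yield_t_mean"].to_numpy(float)[pos]
                - df["yield_c_mean"].to_numpy(float)[pos]) / fn[pos]
    effects["n_ae"] = nae
    effects["responsiveness"] = classify_responsiveness(
        effects["fr"], df["yield_c_mean"], fertile_threshold)
    for col in MODERATOR_COLUMNS:
        if col in df:
            effects[col] = df[col]
    return effects
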