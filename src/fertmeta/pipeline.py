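"""End-to-end analysis pipeline: load/generate → harmonize → impute →
effect sizes → pooled random-effects fit → publication-bias diagnostics →
subgroup summaries → standardized GLM + VIP → power-law fits.

The stage order follows the analysis design: dependent variables (ln FR,
N-AE) are computed first, then the meta-analysis quantifies heterogeneity
and compares categorical subgroups, and finally regression on continuous
moderators ranks explanatory factors.  Every artifact is a plain CSV or
JSON table; a manifest records the configuration and seed so a run is
reproducible byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import effect_size, imputation, meta_analysis, regression_vip, trial_db
from .synthetic_data import SyntheticConfig, config_to_dict, generate

logger = logging.getLogger("fertmeta.pipeline")

DEFAULT_SOIL_VARIABLES = (
    "soil_ph", "total_c", "total_n", "p_olsen",
    "exch_k", "clay", "sand", "silt", "rainfall",
)
DEFAULT_SUBGROUP_VARIABLES = (
    "soil_order", "texture_class", "aez", "nutrient_type", "manager",
    "n_rate_bin",
)
DEFAULT_N_RATE_BINS = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
GLM_BASE_PREDICTORS = (
    "soil_ph", "total_c", "p_olsen", "n_rate", "exch_k", "clay", "silt",
    "rainfall",
)
REGIONS = ("kenya", "ssa_other")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Settings for one pipeline run (YAML-loadable)."""

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    units: dict = field(default_factory=dict)
    unit_map: dict = field(default_factory=dict)
    soil_order_map: dict = field(default_factory=dict)
    soil_variables: tuple = DEFAULT_SOIL_VARIABLES
    sd_multiplier: float = 1.5
    threshold_r: float = 0.8
    use_abs_r: bool = False
    pmm_k: int = 5
    pmm_iterations: int = 10
    fertile_threshold: float = effect_size.FERTILE_YIELD_THRESHOLD
    subgroup_variables: tuple = DEFAULT_SUBGROUP_VARIABLES
    subgroup_weighting: str = "fixed"
    n_rate_bins: tuple = DEFAULT_N_RATE_BINS
    log_ph: bool = False       # prose/table sources disagree; table wins
    vip_components: int | None = None
    trimfill_side: str = "auto"
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        edges = tuple(self.n_rate_bins)
        if any(hi <= lo for lo, hi in zip(edges, edges[1:])):
            raise ValueError("n_rate_bins edges must be strictly increasing")
        if self.input_path is None and self.synthetic is None:
            raise ValueError("either input_path or synthetic must be given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            for key in ("replicate_choices", "n_rate_range"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            raw["synthetic"] = SyntheticConfig(**syn)
        for key in ("soil_variables", "subgroup_variables", "n_rate_bins"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _bin_labels(edges) -> list[str]:
    return [f"{int(lo)}-{int(hi)}" for lo, hi in zip(edges, edges[1:])]


def summarize_categories(
    effects: pd.DataFrame,
    variables: tuple = ("soil_order", "texture_class", "aez", "manager",
                        "nutrient_type"),
    value_col: str = "n_ae",
) -> pd.DataFrame:
    """Descriptive mean / SE / n of N-AE per level of each categorical,
    split by region.  Single-record levels get a missing SE; levels absent
    in a region are simply not listed (the dash convention)."""
    rows = []
    for variable in variables:
        if variable not in effects.columns:
            continue
        for (region, level), grp in effects.groupby(["region", variable],
                                                    observed=True, sort=True):
            vals = grp[value_col].dropna()
            if vals.empty:
                continue
            n = len(vals)
            rows.append({
                "variable": variable, "level": level, "region": region,
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "n": n,
            })
    return pd.DataFrame(rows, columns=["variable", "level", "region",
                                       "mean", "se", "n"])


def _refit_to_dict(fit: meta_analysis.REFit) -> dict:
    lo, hi = fit.ci
    return {
        "mu": fit.mu, "se_mu": fit.se_mu, "ci_low": lo, "ci_high": hi,
        "fr": float(np.exp(fit.mu)), "tau2": fit.tau2,
        "q_t": fit.q_t, "df": fit.df, "p_q": fit.p_q, "k": fit.k,
    }


def _glm_tables(effects: pd.DataFrame, response: str, dropped: set,
                config: PipelineConfig) -> tuple[pd.DataFrame | None,
                                                 pd.DataFrame | None]:
    """One region's GLM coefficient table and VIP table for one response."""
    base = [p for p in GLM_BASE_PREDICTORS if p not in dropped]
    if response == "n_ae":
        base = [p for p in base if p != "n_rate"]  # N-AE already divides by FN
    cols = [response] + base
    data = effects[cols].dropna()
    log_vars = tuple(v for v in regression_vip.DEFAULT_LOG_VARS if v in base)
    if config.log_ph and "soil_ph" in base:
        log_vars = log_vars + ("soil_ph",)
    data = regression_vip.transform_predictors(data, log_vars=log_vars,
                                               on_nonpositive="drop")
    predictors = [c for c in data.columns if c != response]
    if len(data) <= len(predictors) + 2:
        return None, None
    X, _scales = regression_vip.standardize(data[predictors])
    y = data[response].to_numpy()
    glm = regression_vip.fit_glm(y, X, response=response)
    coef = glm.coefficient_table()
    coef["response"] = response
    coef["r2"] = glm.r2
    coef["adjusted_r2"] = glm.adjusted_r2
    coef["n"] = glm.n
    vip = regression_vip.vip_scores(y, X, n_components=config.vip_components)
    vip_table = vip.table()
    vip_table["response"] = response
    vip_table["n_components"] = vip.n_components
    return coef, vip_table


def run(config: PipelineConfig) -> dict:
    """Execute all stages; return the report bundle as an in-memory dict.

    When ``config.outdir`` is set, every table is also written there
    (CSV/JSON) together with ``manifest.json``.
    """
    bundle: dict = {}
    counts: dict = {}

    # --- load or generate --------------------------------------------------
    if config.synthetic is not None:
        trials, truth = generate(config.synthetic)
        bundle["truth"] = truth
        read_errors: list = []
        logger.info("generated %d synthetic observations", len(trials))
    else:
        try:
            trials, read_errors = trial_db.read_trials(config.input_path,
                                                       units=config.units)
        except (OSError, trial_db.SchemaError) as exc:
            raise PipelineError("read", str(exc)) from exc
        logger.info("read %d observations (%d row errors)", len(trials),
                    len(read_errors))
    bundle["read_errors"] = read_errors
    counts["input"] = len(trials)
    if len(trials) == 0:
        raise PipelineError("read", "no valid observations")

    # --- harmonize ---------------------------------------------------------
    try:
        trials = trial_db.harmonize(trials, unit_map=config.unit_map,
                                    soil_order_map=config.soil_order_map)
    except trial_db.UnitError as exc:
        raise PipelineError("harmonize", str(exc)) from exc
    counts["harmonized"] = len(trials)

    # --- imputation cascade ------------------------------------------------
    try:
        trials, plan = imputation.impute_cascade(
            trials, list(config.soil_variables),
            sd_multiplier=config.sd_multiplier,
            threshold_r=config.threshold_r, use_abs_r=config.use_abs_r,
            pmm_k=config.pmm_k, pmm_iterations=config.pmm_iterations,
            seed=config.seed,
        )
    except imputation.ImputationError as exc:
        raise PipelineError("impute", str(exc)) from exc
    dropped = set(plan.dropped_vars)
    logger.info("imputation dropped variables: %s", sorted(dropped) or "none")
    bundle["trials"] = trials
    bundle["imputation_plan"] = plan

    # --- effect sizes ------------------------------------------------------
    effects = effect_size.compute_effects(trials,
                                          fertile_threshold=config.fertile_threshold)
    edges = tuple(config.n_rate_bins)
    effects["n_rate_bin"] = pd.cut(
        effects["n_rate"], bins=list(edges), labels=_bin_labels(edges),
        include_lowest=True).astype(object)
    bundle["effects"] = effects
    counts["effects"] = len(effects)

    # --- pooled random-effects fit, overall and per region -----------------
    pooled: dict = {}
    for name, sub in [("pooled", effects)] + [
            (r, effects[effects["region"] == r]) for r in REGIONS]:
        if len(sub) < 2:
            logger.info("skipping RE fit for %s (k=%d)", name, len(sub))
            continue
        fit = meta_analysis.fit_random_effects(sub["ln_fr"].to_numpy(),
                                               sub["fr_var"].to_numpy())
        pooled[name] = _refit_to_dict(fit)
    bundle["pooled_fit"] = pooled

    # --- publication-bias diagnostics (overall dataset) --------------------
    y = effects["ln_fr"].to_numpy()
    v = effects["fr_var"].to_numpy()
    bias: dict = {}
    try:
        egger = meta_analysis.egger_regression_test(y, v)
        bias["egger"] = {"slope": egger.slope, "se_slope": egger.se_slope,
                         "z": egger.z, "p": egger.p}
        tf = meta_analysis.trim_and_fill(y, v, side=config.trimfill_side)
        bias["trim_and_fill"] = {"k0": tf.k0, "side": tf.side,
                                 "adjusted_mu": tf.adjusted_mu,
                                 "center": tf.center}
    except meta_analysis.MetaAnalysisError as exc:
        logger.info("bias diagnostics skipped: %s", exc)
    bundle["bias"] = bias
    bundle["funnel"] = meta_analysis.funnel_data(effects)

    # --- subgroup summaries per region -------------------------------------
    sub_tables = []
    for region in REGIONS:
        sub = effects[effects["region"] == region]
        for variable in config.subgroup_variables:
            if variable not in sub.columns or sub[variable].dropna().empty:
                logger.info("subgroup %s skipped for %s", variable, region)
                continue
            tau2 = pooled.get(region, {}).get("tau2", 0.0)
            summary = meta_analysis.subgroup_weighted_means(
                sub, variable, weighting=config.subgroup_weighting, tau2=tau2)
            summary.insert(0, "region", region)
            sub_tables.append(summary)
    bundle["subgroups"] = (pd.concat(sub_tables, ignore_index=True)
                           if sub_tables else pd.DataFrame())

    # --- GLM + VIP per response and region ----------------------------------
    coef_tables, vip_tables = [], []
    for region in REGIONS:
        sub = effects[effects["region"] == region]
        for response in ("ln_fr", "n_ae"):
            coef, vip = _glm_tables(sub, response, dropped, config)
            if coef is None:
                logger.info("GLM %s/%s skipped (too few rows)", region, response)
                continue
            coef.insert(0, "region", region)
            vip.insert(0, "region", region)
            coef_tables.append(coef)
            vip_tables.append(vip)
    bundle["glm"] = (pd.concat(coef_tables, ignore_index=True)
                     if coef_tables else pd.DataFrame())
    bundle["vip"] = (pd.concat(vip_tables, ignore_index=True)
                     if vip_tables else pd.DataFrame())

    # --- power-law fit of FR on control yield, per region -------------------
    power: dict = {}
    for region in REGIONS:
        sub = effects[effects["region"] == region]
        if len(sub) < 3 or np.ptp(sub["yield_c_mean"].to_numpy()) == 0:
            continue
        fit = regression_vip.fit_power_law(sub["fr"], sub["yield_c_mean"])
        power[region] = {"a": fit.a, "b": fit.b, "se_b": fit.se_b,
                         "r2": fit.r2, "p": fit.p, "n": fit.n}
    bundle["power_law"] = power

    # --- N-AE descriptives ---------------------------------------------------
    cat_vars = tuple(va for va in config.subgroup_variables if va != "n_rate_bin")
    bundle["nae_descriptives"] = summarize_categories(effects, variables=cat_vars)

    counts["kenya"] = int((effects["region"] == "kenya").sum())
    counts["ssa_other"] = int((effects["region"] == "ssa_other").sum())
    bundle["counts"] = counts

    if config.outdir is not None:
        _write_bundle(bundle, config)
    return bundle


def _config_manifest(config: PipelineConfig) -> dict:
    d = {
        "input_path": config.input_path,
        "synthetic": (config_to_dict(config.synthetic)
                      if config.synthetic else None),
        "soil_variables": list(config.soil_variables),
        "sd_multiplier": config.sd_multiplier,
        "threshold_r": config.threshold_r,
        "use_abs_r": config.use_abs_r,
        "pmm_k": config.pmm_k,
        "pmm_iterations": config.pmm_iterations,
        "fertile_threshold": config.fertile_threshold,
        "subgroup_variables": list(config.subgroup_variables),
        "subgroup_weighting": config.subgroup_weighting,
        "n_rate_bins": list(config.n_rate_bins),
        "log_ph": config.log_ph,
        "vip_components": config.vip_components,
        "trimfill_side": config.trimfill_side,
        "seed": config.seed,
    }
    return d


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _dump_json(obj, name):
        with open(outdir / name, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")

    trial_db.write_trials(bundle["trials"], outdir / "trials_analyzed.csv")
    bundle["effects"].to_csv(outdir / "effects.csv", index=False)
    bundle["funnel"].to_csv(outdir / "funnel.csv", index=False)
    bundle["subgroups"].to_csv(outdir / "subgroups.csv", index=False)
    bundle["glm"].to_csv(outdir / "glm_coefficients.csv", index=False)
    bundle["vip"].to_csv(outdir / "vip.csv", index=False)
    bundle["nae_descriptives"].to_csv(outdir / "nae_descriptives.csv", index=False)
    if "truth" in bundle:
        bundle["truth"].to_csv(outdir / "ground_truth.csv", index=False)
    _dump_json(bundle["pooled_fit"], "pooled_fit.json")
    _dump_json(bundle["bias"], "bias.json")
    _dump_json(bundle["power_law"], "power_law.json")
    plan = bundle["imputation_plan"]
    _dump_json(
        {
            "threshold_r": plan.threshold_r,
            "dropped_vars": sorted(plan.dropped_vars),
            "pairs": [vars(p) for p in plan.pairs],
        },
        "imputation_plan.json",
    )
    _dump_json({"config": _config_manifest(config), "counts": bundle["counts"]},
               "manifest.json")
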