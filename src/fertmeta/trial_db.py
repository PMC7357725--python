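"""Trial-observation data model: CSV I/O, validation, unit/method harmonization.

The canonical container is a :class:`pandas.DataFrame` with one row per
treatment-control pair and the columns documented in ``schema.yaml``.  All
yields are kg ha⁻¹, soil C/N in g kg⁻¹, extractable P in mg kg⁻¹ on the
Olsen scale after harmonization, exchangeable cations in cmol kg⁻¹, texture
fractions in percent, rainfall in mm per growing season.

Soil P measured by the Bray-1 or Bray-2 assays is mapped onto the Olsen
scale with the published fixed factors (0.44 and 0.79 respectively); the
conversion is recorded in ``p_olsen_source`` / ``p_olsen_converted`` so a
derived value can always be traced back to its stored source column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

#: Published conversion factors onto the P-Olsen scale.
P_BRAY1_TO_OLSEN = 0.44
P_BRAY2_TO_OLSEN = 0.79

MANDATORY_COLUMNS = (
    "study_id",
    "region",
    "yield_t_mean",
    "yield_c_mean",
    "n_t",
    "n_c",
    "n_rate",
)

NUMERIC_COLUMNS = (
    "yield_t_mean", "yield_c_mean",
    "yield_t_sd", "yield_c_sd",
    "yield_t_se", "yield_c_se",
    "yield_t_cv", "yield_c_cv",
    "n_t", "n_c", "n_rate",
    "soil_ph", "total_c", "total_n",
    "p_olsen", "p_bray1", "p_bray2",
    "exch_k", "exch_ca", "exch_mg",
    "clay", "sand", "silt",
    "rainfall", "altitude",
)

CATEGORICAL_COLUMNS = (
    "study_id", "site_id", "region",
    "soil_order", "texture_class", "aez",
    "nutrient_type", "manager",
)

#: Columns in the canonical schema, in writing order.
ALL_COLUMNS = tuple(
    c for c in (
        "study_id", "site_id", "region",
        "yield_t_mean", "yield_c_mean",
        "yield_t_sd", "yield_c_sd", "yield_t_se", "yield_c_se",
        "yield_t_cv", "yield_c_cv",
        "n_t", "n_c", "n_rate",
        "soil_ph", "total_c", "total_n",
        "p_olsen", "p_bray1", "p_bray2",
        "exch_k", "exch_ca", "exch_mg",
        "clay", "sand", "silt", "rainfall", "altitude",
        "soil_order", "texture_class", "aez", "nutrient_type", "manager",
    )
)

P_COLUMNS = ("p_olsen", "p_bray1", "p_bray2")


class SchemaError(ValueError):
    """Input file does not match the documented trial schema."""


class UnitError(ValueError):
    """A declared source unit has no conversion rule."""


@dataclass(frozen=True)
class RowError:
    """A per-row validation failure (row index is positional in the file)."""

    row: int
    column: str
    message: str


def load_schema() -> dict:
    """Return the machine-readable column schema shipped with the package."""
    text = resources.files("fertmeta").joinpath("schema.yaml").read_text()
    return yaml.safe_load(text)


def validate(df: pd.DataFrame) -> list[RowError]:
    """Collect invariant violations per row without mutating ``df``.

    Checks: positive yield means, non-negative sds/se/cv and n_rate,
    replicate counts >= 1, texture fractions in [0, 100] summing to
    95–105 when all three are present, and at most one *measured*
    extractable-P method per observation (a converted ``p_olsen`` flagged
    in ``p_olsen_converted`` does not count as measured).
    """
    errors: list[RowError] = []

    def _flag(mask: pd.Series, column: str, message: str) -> None:
        for pos in np.flatnonzero(mask.to_numpy()):
            errors.append(RowError(int(pos), column, message))

    for col in ("yield_t_mean", "yield_c_mean"):
        if col in df:
            _flag(df[col].notna() & (df[col] <= 0), col, "yield mean must be > 0")
    for col in ("yield_t_sd", "yield_c_sd", "yield_t_se", "yield_c_se",
                "yield_t_cv", "yield_c_cv"):
        if col in df:
            _flag(df[col].notna() & (df[col] < 0), col, "dispersion must be >= 0")
    for col in ("n_t", "n_c"):
        if col in df:
            _flag(df[col].notna() & (df[col] < 1), col, "replicate count must be >= 1")
    if "n_rate" in df:
        _flag(df["n_rate"].notna() & (df["n_rate"] < 0), "n_rate", "N rate must be >= 0")

    for col in ("clay", "sand", "silt"):
        if col in df:
            bad = df[col].notna() & ((df[col] < 0) | (df[col] > 100))
            _flag(bad, col, "texture fraction outside [0, 100]")
    if all(c in df for c in ("clay", "sand", "silt")):
        present = df[["clay", "sand", "silt"]].notna().all(axis=1)
        total = df[["clay", "sand", "silt"]].sum(axis=1)
        bad = present & ((total < 95) | (total > 105))
        _flag(bad, "clay", "clay+sand+silt outside [95, 105]")

    p_present = pd.DataFrame(
        {c: df[c].notna() if c in df else pd.Series(False, index=df.index)
         for c in P_COLUMNS}
    )
    if "p_olsen_converted" in df:
        converted = df["p_olsen_converted"].fillna(False).astype(bool)
        p_present.loc[converted.to_numpy(), "p_olsen"] = False
    _flag(p_present.sum(axis=1) > 1, "p_olsen",
          "more than one measured extractable-P method")
    return errors


def read_trials(
    path, *, units: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, list[RowError]]:
    """Read a trial CSV; return valid rows and a per-row error report.

    Rows violating a schema invariant (or carrying a non-numeric token in a
    numeric column) are dropped from the returned frame and reported, never
    silently discarded.  Header names are matched case-insensitively; empty
    cells are missing values.  ``units`` optionally declares non-canonical
    source units per column (consumed later by :func:`harmonize`) and is
    stored in ``df.attrs["units"]``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"mandatory column(s) missing: {', '.join(missing)}")

    df = pd.DataFrame(index=raw.index)
    errors: list[RowError] = []
    for col in raw.columns:
        series = raw[col].replace("", np.nan)
        if col in NUMERIC_COLUMNS:
            numeric = pd.to_numeric(series, errors="coerce")
            bad = series.notna() & numeric.isna()
            for pos in np.flatnonzero(bad.to_numpy()):
                errors.append(RowError(int(pos), col,
                                       f"non-numeric value {series.iloc[pos]!r}"))
            df[col] = numeric
        else:
            df[col] = series

    errors.extend(validate(df))
    bad_rows = sorted({e.row for e in errors})
    df = df.drop(index=df.index[bad_rows]).reset_index(drop=True)
    df.attrs["units"] = dict(units or {})
    return df, errors


def write_trials(df: pd.DataFrame, path) -> None:
    """Write the trial table in the canonical CSV dialect (empty = missing)."""
    df.to_csv(path, index=False, na_rep="")


def convert_p(value, method: str):
    """Convert a Bray extractable-P value onto the Olsen scale.

    ``method`` is ``"bray1"`` (factor 0.44) or ``"bray2"`` (factor 0.79).
    Accepts scalars or arrays; negative values are rejected.
    """
    factors = {"bray1": P_BRAY1_TO_OLSEN, "bray2": P_BRAY2_TO_OLSEN}
    if method not in factors:
        raise ValueError(f"unknown P method {method!r}")
    arr = np.asarray(value, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("extractable P must be >= 0")
    out = factors[method] * arr
    return float(out) if np.isscalar(value) else out


def harmonize(
    df: pd.DataFrame,
    unit_map: Mapping[str, Mapping[str, float]] | None = None,
    soil_order_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Bring a trial table into canonical units and a single P-Olsen column.

    ``unit_map`` declares multiplicative rules ``{column: {source_unit:
    factor}}`` (e.g. ``{"yield_t_mean": {"t/ha": 1000.0}}``); which source
    unit each column is currently in is read from ``df.attrs["units"]``.
    After conversion the column's declared unit becomes canonical, so the
    operation is idempotent.  A declared non-canonical unit with no rule
    raises :class:`UnitError`.

    Bray-measured P is converted to the Olsen scale where ``p_olsen`` is
    missing; provenance lands in ``p_olsen_source`` ({measured, bray1,
    bray2}) and ``p_olsen_converted``.  If a row carries both a measured
    ``p_olsen`` and a Bray value (which should not occur in practice), the
    measured value wins and a warning is emitted.  ``soil_order_map``
    optionally relabels ``soil_order`` through a user-supplied table.
    """
    out = df.copy()
    units = dict(df.attrs.get("units", {}))
    unit_map = unit_map or {}
    for col, unit in list(units.items()):
        if unit in (None, "", "canonical"):
            continue
        rules = unit_map.get(col, {})
        if unit not in rules:
            raise UnitError(f"no conversion rule for column {col!r} in unit {unit!r}")
        out[col] = out[col] * float(rules[unit])
        units[col] = "canonical"
    out.attrs["units"] = units

    for c in P_COLUMNS:
        if c not in out:
            out[c] = np.nan
    if "p_olsen_source" not in out:
        out["p_olsen_source"] = pd.Series(
            np.where(out["p_olsen"].notna(), "measured", None), index=out.index,
            dtype=object,
        )
    if "p_olsen_converted" not in out:
        out["p_olsen_converted"] = False

    both = out["p_olsen"].notna() & (out["p_bray1"].notna() | out["p_bray2"].notna())
    both &= out["p_olsen_source"].eq("measured")
    if both.any():
        warnings.warn(
            f"{int(both.sum())} row(s) carry both measured P-Olsen and a Bray "
            "value; keeping the measured P-Olsen", stacklevel=2,
        )
    for method, col in (("bray1", "p_bray1"), ("bray2", "p_bray2")):
        mask = out["p_olsen"].isna() & out[col].notna()
        if mask.any():
            out.loc[mask, "p_olsen"] = convert_p(out.loc[mask, col].to_numpy(), method)
            out.loc[mask, "p_olsen_source"] = method
            out.loc[mask, "p_olsen_converted"] = True

    if soil_order_map and "soil_order" in out:
        out["soil_order"] = out["soil_order"].map(
            lambda v: soil_order_map.get(v, v) if pd.notna(v) else v
        )
    return out
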