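"""Readers and writers for the tabular inputs and outputs.

All files are plain CSV.  Readers validate schemas eagerly: missing required
columns raise :class:`SchemaError`, unknown columns only warn, and malformed
values point at the offending row.  Writers are thin ``pandas`` wrappers kept
here so every output goes through one place.

Expected schemas
----------------
stage     ``date,level_m``            ISO dates, strictly increasing
catch     ``date,species_id,count``
effort    ``cycle_id,effort_m2``
trait     ``species_id,max_sl_mm,maturation_sl_mm,fecundity,oocyte_diam_mm,parental_care_score``
diet      ``species_id,item_category,volume_prop``
labels    ``species_id,life_history,trophic_level``
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .hydrology import StageSeries

__all__ = [
    "SchemaError",
    "read_stage_series",
    "read_catch_table",
    "read_effort_table",
    "read_trait_table",
    "read_diet_table",
    "read_labels_table",
    "write_table",
    "DIET_CATEGORIES",
    "LIFE_HISTORY_GROUPS",
    "TROPHIC_LEVELS",
]

DIET_CATEGORIES = (
    "detritus", "algae", "plant", "invertebrate", "plankton", "fish", "other",
)
LIFE_HISTORY_GROUPS = ("ES", "EL", "IS", "PL", "PS")
TROPHIC_LEVELS = (1.0, 1.5, 2.0, 3.0)


class SchemaError(ValueError):
    """A table does not conform to its expected schema."""


def _read_csv(path: str | Path, required: list[str], name: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{name} file {path} is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} file {path} lacks required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{name} file {path}: ignoring unknown columns {extra}",
                      stacklevel=3)
    if df.empty:
        raise SchemaError(f"{name} file {path} has a header but no rows")
    return df[required]


def read_stage_series(path: str | Path) -> StageSeries:
    """Read a daily water-level record (``date,level_m``).

    Dates must be strictly increasing and unique; gaps are tolerated and
    simply absent (never interpolated).  Non-numeric levels are reported with
    their row number (1-based, excluding the header).
    """
    df = _read_csv(path, ["date", "level_m"], "stage")
    try:
        dates = pd.DatetimeIndex(pd.to_datetime(df["date"], format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"stage file {path}: unparseable date ({exc})") from None
    levels = pd.to_numeric(df["level_m"], errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isfinite(levels))
    if bad.size:
        raise SchemaError(
            f"stage file {path}: non-numeric level_m at row {bad[0] + 1} "
            f"(value {df['level_m'].iloc[bad[0]]!r})"
        )
    if dates.has_duplicates:
        dup = dates[dates.duplicated()][0]
        raise SchemaError(f"stage file {path}: duplicated date {dup.date()}")
    if not dates.is_monotonic_increasing:
        raise SchemaError(f"stage file {path}: dates must be strictly increasing")
    return StageSeries(dates=dates, levels=levels)


def read_catch_table(path: str | Path) -> pd.DataFrame:
    """Read catch records (``date,species_id,count``)."""
    df = _read_csv(path, ["date", "species_id", "count"], "catch")
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    df["count"] = pd.to_numeric(df["count"], errors="raise")
    if (df["count"] < 0).any():
        raise SchemaError(f"catch file {path}: negative counts")
    return df


def read_effort_table(path: str | Path) -> pd.DataFrame:
    """Read per-cycle sampling effort (``cycle_id,effort_m2``), keyed by cycle."""
    df = _read_csv(path, ["cycle_id", "effort_m2"], "effort")
    df = df.copy()
    df["effort_m2"] = pd.to_numeric(df["effort_m2"], errors="raise")
    if df["cycle_id"].duplicated().any():
        raise SchemaError(f"effort file {path}: duplicated cycle_id")
    if (df["effort_m2"] <= 0).any():
        raise SchemaError(f"effort file {path}: effort must be positive")
    return df.set_index("cycle_id")


TRAIT_COLUMNS = [
    "species_id", "max_sl_mm", "maturation_sl_mm", "fecundity",
    "oocyte_diam_mm", "parental_care_score",
]


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read the five life-history traits per species, keyed by species."""
    df = _read_csv(path, TRAIT_COLUMNS, "trait").copy()
    if df["species_id"].duplicated().any():
        raise SchemaError(f"trait file {path}: duplicated species_id")
    df = df.set_index("species_id")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        col = numeric.columns[numeric.isna().any()][0]
        raise SchemaError(f"trait file {path}: non-numeric value in {col}")
    # parental care is an ordinal score and may legitimately be 0
    strictly_positive = ["max_sl_mm", "maturation_sl_mm", "fecundity", "oocyte_diam_mm"]
    if (numeric[strictly_positive] <= 0).any().any():
        raise SchemaError(f"trait file {path}: size/fecundity traits must be positive")
    if (numeric["parental_care_score"] < 0).any():
        raise SchemaError(f"trait file {path}: parental_care_score must be >= 0")
    if (numeric["maturation_sl_mm"] > numeric["max_sl_mm"]).any():
        raise SchemaError(f"trait file {path}: maturation_sl_mm exceeds max_sl_mm")
    return numeric


def read_diet_table(path: str | Path, tol: float = 0.05) -> pd.DataFrame:
    """Read volumetric diet proportions (``species_id,item_category,volume_prop``).

    Returns a species x category proportion matrix.  Per-species proportions
    are renormalized to sum to 1; a deviation beyond ``tol`` raises, a smaller
    one only warns (rounding slack in hand-built tables).
    """
    df = _read_csv(path, ["species_id", "item_category", "volume_prop"], "diet").copy()
    bad_cat = set(df["item_category"]) - set(DIET_CATEGORIES)
    if bad_cat:
        raise SchemaError(f"diet file {path}: unknown item categories {sorted(bad_cat)}")
    df["volume_prop"] = pd.to_numeric(df["volume_prop"], errors="raise")
    if (df["volume_prop"] < 0).any():
        raise SchemaError(f"diet file {path}: negative proportions")
    wide = (df.pivot_table(index="species_id", columns="item_category",
                           values="volume_prop", aggfunc="sum", fill_value=0.0)
              .reindex(columns=list(DIET_CATEGORIES), fill_value=0.0))
    sums = wide.sum(axis=1)
    if (sums == 0).any():
        empty = sums.index[sums == 0][0]
        raise SchemaError(f"diet file {path}: species {empty} has an empty diet")
    off = (sums - 1.0).abs()
    if (off > tol).any():
        sp = off.idxmax()
        raise SchemaError(
            f"diet file {path}: proportions for {sp} sum to {sums[sp]:.3f}"
        )
    if (off > 1e-9).any():
        warnings.warn(
            f"diet file {path}: proportions renormalized for "
            f"{int((off > 1e-9).sum())} species", stacklevel=2,
        )
    return wide.div(sums, axis=0)


def read_labels_table(path: str | Path) -> pd.DataFrame:
    """Read functional group labels (``species_id,life_history,trophic_level``)."""
    df = _read_csv(path, ["species_id", "life_history", "trophic_level"], "labels").copy()
    if df["species_id"].duplicated().any():
        raise SchemaError(f"labels file {path}: duplicated species_id")
    bad = set(df["life_history"]) - set(LIFE_HISTORY_GROUPS)
    if bad:
        raise SchemaError(f"labels file {path}: unknown life-history groups {sorted(bad)}")
    df["trophic_level"] = pd.to_numeric(df["trophic_level"], errors="raise")
    bad_t = set(df["trophic_level"]) - set(TROPHIC_LEVELS)
    if bad_t:
        raise SchemaError(f"labels file {path}: unknown trophic levels {sorted(bad_t)}")
    return df.set_index("species_id")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a result table as plain CSV (parent directories created)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
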