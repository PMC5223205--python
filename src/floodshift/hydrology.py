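"""Flood-pulse segmentation and annual hydrological metrics.

A floodplain year is organised around the flood pulse: the river stage falls
below a low threshold (dry season), climbs through a mid band (rising), tops
the high threshold (flood) and descends again (receding).  This module
segments a daily stage record into annual flood-pulse cycles — one cycle per
upward crossing of the low threshold — and computes, per cycle, the seven
metrics used to describe hydrological dynamics: pulse amplitude, annual
minimum and maximum stage, and the day counts of the four seasons.

Season conventions
------------------
``dry`` is strictly below the low threshold, ``flood`` strictly above the
high threshold, and the closed band in between splits by the direction of
stage change: ``rising`` while ascending, ``receding`` while descending.
Flat days inherit the previous day's direction (the first day of a record
borrows the sign of the following step), so every day receives exactly one
label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig

__all__ = [
    "StageSeries",
    "FloodPulseCycle",
    "HydroMetrics",
    "SEASONS",
    "classify_day",
    "day_directions",
    "segment_cycles",
    "cycle_metrics",
    "hydro_feature_matrix",
    "METRIC_COLUMNS",
]

SEASONS = ("dry", "rising", "flood", "receding")

METRIC_COLUMNS = [
    "amplitude_m",
    "min_m",
    "max_m",
    "days_dry",
    "days_rising",
    "days_flood",
    "days_receding",
]


@dataclass(frozen=True)
class StageSeries:
    """A dated daily water-level record (m above gauge datum).

    Dates are calendar dates, strictly increasing; gaps (missing days) are
    permitted and recorded, never interpolated.
    """

    dates: pd.DatetimeIndex
    levels: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "levels", levels)
        if len(self.dates) != len(levels):
            raise ValueError("dates and levels must have equal length")
        if len(self.dates) == 0:
            raise ValueError("stage series is empty")
        diffs = np.diff(self.dates.view("int64"))
        if np.any(diffs <= 0):
            raise ValueError("dates must be strictly increasing")
        if not np.all(np.isfinite(levels)):
            raise ValueError("levels must be finite")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def n_missing_days(self) -> int:
        """Calendar days absent between the first and last record."""
        span = (self.dates[-1] - self.dates[0]).days + 1
        return int(span - len(self.dates))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "level_m": self.levels})


@dataclass(frozen=True)
class FloodPulseCycle:
    """One annual flood pulse: upward low-threshold crossing to the next.

    The dry-season days preceding the next upward crossing belong to this
    cycle, so each complete cycle contains exactly one dry season.
    """

    cycle_id: str
    dates: pd.DatetimeIndex
    levels: np.ndarray
    seasons: np.ndarray  # one label from SEASONS per member day
    usable: bool = True

    @property
    def start_date(self) -> pd.Timestamp:
        return self.dates[0]

    @property
    def end_date(self) -> pd.Timestamp:
        return self.dates[-1]

    @property
    def n_days(self) -> int:
        """Calendar length of the cycle in days, gaps included."""
        return int((self.dates[-1] - self.dates[0]).days + 1)

    @property
    def n_missing_days(self) -> int:
        return self.n_days - len(self.dates)

    @property
    def gap_fraction(self) -> float:
        return self.n_missing_days / self.n_days


@dataclass(frozen=True)
class HydroMetrics:
    """The seven per-cycle hydrological metrics."""

    cycle_id: str
    amplitude_m: float
    min_m: float
    max_m: float
    days_dry: int
    days_rising: int
    days_flood: int
    days_receding: int

    def as_dict(self) -> dict:
        return {
            "cycle_id": self.cycle_id,
            "amplitude_m": self.amplitude_m,
            "min_m": self.min_m,
            "max_m": self.max_m,
            "days_dry": self.days_dry,
            "days_rising": self.days_rising,
            "days_flood": self.days_flood,
            "days_receding": self.days_receding,
        }


def classify_day(level: float, direction: str, config: RunConfig | None = None) -> str:
    """Assign a season label to a single day.

    ``direction`` is one of ``ascending``/``descending``/``flat``; flat must
    already have been resolved by the carry-forward rule (see
    :func:`day_directions`), so it is rejected only inside the mid band where
    it would be ambiguous.
    """
    cfg = config or RunConfig()
    if level < cfg.season_low_threshold:
        return "dry"
    if level > cfg.season_high_threshold:
        return "flood"
    if direction == "ascending":
        return "rising"
    if direction == "descending":
        return "receding"
    raise ValueError(
        "flat direction is ambiguous in the mid band; resolve it via the "
        "carry-forward rule (day_directions) first"
    )


def day_directions(levels: np.ndarray) -> np.ndarray:
    """Direction of stage change per day with the carry-forward rule.

    Direction of day ``t`` is the sign of ``level[t] - level[t-1]``; zero
    differences inherit the previous day's direction, and the first day uses
    the sign of the following step.  A wholly constant record is labelled
    ascending by convention (it never enters the mid band in practice).
    """
    levels = np.asarray(levels, dtype=float)
    n = len(levels)
    if n < 2:
        return np.array(["ascending"] * n, dtype=object)
    signs = np.sign(np.diff(levels))  # signs[t-1] applies to day t
    first = 0.0
    for s in signs:
        if s != 0.0:
            first = s
            break
    out = np.empty(n, dtype=object)
    prev = first if first != 0.0 else 1.0
    out[0] = "ascending" if prev > 0 else "descending"
    for t in range(1, n):
        s = signs[t - 1]
        if s != 0.0:
            prev = s
        out[t] = "ascending" if prev > 0 else "descending"
    return out


def _season_labels(levels: np.ndarray, config: RunConfig) -> np.ndarray:
    directions = day_directions(levels)
    low, high = config.season_low_threshold, config.season_high_threshold
    out = np.empty(len(levels), dtype=object)
    for i, (lv, d) in enumerate(zip(levels, directions)):
        if lv < low:
            out[i] = "dry"
        elif lv > high:
            out[i] = "flood"
        else:
            out[i] = "rising" if d == "ascending" else "receding"
    return out


def segment_cycles(series: StageSeries, config: RunConfig | None = None,
                   hysteresis_m: float = 0.25) -> list[FloodPulseCycle]:
    """Cut a stage record into complete annual flood-pulse cycles.

    A cycle starts on the first day at or above the low threshold after the
    stage has been below it (an upward crossing) and ends the day before the
    next upward crossing.  Crossing detection uses a small hysteresis: after
    a crossing fires, the next one arms only once the stage has dropped below
    ``low - hysteresis_m``, so day-to-day gauge noise at the threshold cannot
    spawn spurious micro-cycles.  Partial leading/trailing segments are
    dropped with a warning.  Cycles whose within-cycle gap fraction exceeds
    ``config.max_gap_fraction`` are kept but flagged unusable.
    """
    cfg = config or RunConfig()
    levels = series.levels
    low = cfg.season_low_threshold
    if levels.min() >= low or levels.max() < low:
        raise ValueError(
            "stage series never crosses the low threshold; no flood-pulse "
            "cycle can be delimited"
        )

    crossings = []
    armed = levels[0] < low
    for i in range(1, len(levels)):
        if levels[i] < low - hysteresis_m:
            armed = True
        elif armed and levels[i] >= low:
            crossings.append(i)
            armed = False
    if len(crossings) < 2:
        warnings.warn(
            "fewer than two upward crossings of the low threshold: no "
            "complete cycle", stacklevel=2,
        )
        return []

    seasons = _season_labels(levels, cfg)
    cycles: list[FloodPulseCycle] = []
    for start, stop in zip(crossings[:-1], crossings[1:]):
        dates = series.dates[start:stop]
        cycle_levels = levels[start:stop]
        cycle_id = f"{dates[0].year}-{dates[-1].year}"
        cycle = FloodPulseCycle(
            cycle_id=cycle_id,
            dates=dates,
            levels=cycle_levels,
            seasons=seasons[start:stop],
        )
        if cycle.gap_fraction > cfg.max_gap_fraction:
            warnings.warn(
                f"cycle {cycle_id}: {cycle.gap_fraction:.1%} of days missing "
                f"exceeds the {cfg.max_gap_fraction:.0%} tolerance; flagged "
                "unusable", stacklevel=2,
            )
            cycle = FloodPulseCycle(
                cycle_id=cycle_id, dates=dates, levels=cycle_levels,
                seasons=seasons[start:stop], usable=False,
            )
        cycles.append(cycle)

    n_dropped_lead = crossings[0]
    n_dropped_trail = len(levels) - crossings[-1]
    if n_dropped_lead or n_dropped_trail:
        warnings.warn(
            f"dropped {n_dropped_lead} leading and {n_dropped_trail} trailing "
            "days belonging to partial cycles", stacklevel=2,
        )
    return cycles


def cycle_metrics(cycle: FloodPulseCycle) -> HydroMetrics:
    """Compute the seven hydrological metrics of one complete cycle.

    An unusable cycle (gap fraction exceeded) yields a record of missing
    markers (NaN) so downstream tables keep the cycle's row.
    """
    if not cycle.usable:
        return HydroMetrics(cycle.cycle_id, *(float("nan"),) * 3, *(-1,) * 4)
    counts = {s: int(np.sum(cycle.seasons == s)) for s in SEASONS}
    max_m = float(cycle.levels.max())
    min_m = float(cycle.levels.min())
    return HydroMetrics(
        cycle_id=cycle.cycle_id,
        amplitude_m=max_m - min_m,
        min_m=min_m,
        max_m=max_m,
        days_dry=counts["dry"],
        days_rising=counts["rising"],
        days_flood=counts["flood"],
        days_receding=counts["receding"],
    )


def metrics_table(cycles: list[FloodPulseCycle]) -> pd.DataFrame:
    """Raw cycle x 7 metric table indexed by cycle id (unusable cycles NaN)."""
    rows = []
    for c in cycles:
        m = cycle_metrics(c)
        row = m.as_dict()
        if not c.usable:
            for k in METRIC_COLUMNS:
                row[k] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows).set_index("cycle_id")
    return df[METRIC_COLUMNS]


def hydro_feature_matrix(series: StageSeries | list[FloodPulseCycle],
                         config: RunConfig | None = None) -> pd.DataFrame:
    """Standardized cycle x 7 metric matrix (each column mean 0, sd 1).

    Accepts either a raw stage series (segmented internally) or an already
    segmented cycle list.  Standardization uses the sample (n-1) standard
    deviation; a zero-variance column is left at 0 with a warning.  Unusable
    cycles are excluded from the matrix.
    """
    cfg = config or RunConfig()
    cycles = (segment_cycles(series, cfg)
              if isinstance(series, StageSeries) else series)
    usable = [c for c in cycles if c.usable]
    if len(usable) < 3:
        raise ValueError("need at least 3 complete usable cycles to standardize")
    raw = metrics_table(usable)
    out = raw.copy().astype(float)
    for col in out.columns:
        sd = out[col].std(ddof=1)
        mean = out[col].mean()
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"metric {col} has zero variance; left at 0", stacklevel=2)
            out[col] = 0.0
        else:
            out[col] = (out[col] - mean) / sd
    return out
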