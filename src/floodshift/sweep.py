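"""Missing-value robustness sweep for a single gapped cycle.

When one cycle of an annual series is missing (the study's 2005-2006 gap),
the model ranking could in principle hinge on the unobserved value.  The
sweep makes that worry quantitative: every candidate value from the observed
minimum to the observed maximum, stepped by a configurable increment, is
inserted at the missing cycle, the full AICc model selection is rerun, and
the proportion of grid values at which each family wins is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regime import AnnualSeries
from .response import FAMILIES, select_best

__all__ = ["SweepResult", "sweep_grid", "sweep_missing"]


@dataclass
class SweepResult:
    """Winners over the value grid and per-family winning proportions."""

    grid: np.ndarray
    winners: list            # per grid value: list of tied winning families
    proportions: pd.Series   # family -> fraction of grid won (sums to 1)
    missing_label: object

    @property
    def top_family(self) -> str:
        return self.proportions.idxmax()


def sweep_grid(lo: float, hi: float, increment: float) -> np.ndarray:
    """Inclusive grid from ``lo`` to ``hi``; the final step is truncated so the
    grid ends exactly at ``hi``."""
    if increment <= 0:
        raise ValueError("increment must be positive")
    if hi < lo:
        raise ValueError("grid upper bound below lower bound")
    n = int(np.floor((hi - lo) / increment + 1e-9))
    grid = lo + increment * np.arange(n + 1)
    if grid[-1] < hi - 1e-12:
        grid = np.append(grid, hi)
    else:
        grid[-1] = hi
    return grid


def sweep_missing(series: AnnualSeries, missing_label, tau: float | None,
                  families: tuple = FAMILIES, increment: float = 0.001,
                  error: str = "iid") -> SweepResult:
    """Insert each grid value at the missing cycle and rerun model selection.

    ``series`` holds the observed values only; ``missing_label`` names the
    single absent cycle (it must not already be present).  Ties in AICc
    (within 1e-9) are counted fractionally across the tied families so the
    proportions always sum to 1.
    """
    if missing_label in series.labels:
        raise ValueError(f"label {missing_label!r} is present, not missing")
    miss_year = (float(str(missing_label).split("-")[0].split("–")[0])
                 if isinstance(missing_label, str) else float(missing_label))
    numeric = series.numeric_labels
    if not numeric.min() < miss_year < numeric.max():
        raise ValueError("the missing cycle must lie inside the observed span")

    pos = int(np.searchsorted(numeric, miss_year))
    labels = list(series.labels[:pos]) + [missing_label] + list(series.labels[pos:])

    lo, hi = float(series.values.min()), float(series.values.max())
    grid = sweep_grid(lo, hi, increment)

    weights = {f: 0.0 for f in families}
    winners: list = []
    for v in grid:
        values = np.concatenate([series.values[:pos], [v], series.values[pos:]])
        filled = AnnualSeries(labels=tuple(labels), values=values,
                              name=series.name)
        comp = select_best(filled, tau=tau, families=families, error=error)
        best_aicc = comp.best.aicc
        tied = [f.family for f in comp.fits if f.aicc - best_aicc <= 1e-9]
        winners.append(tied)
        for fam in tied:
            weights[fam] += 1.0 / len(tied)

    proportions = pd.Series(weights, name="proportion_best") / len(grid)
    return SweepResult(grid=grid, winners=winners, proportions=proportions,
                       missing_label=missing_label)
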