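"""Sequential t-test regime-shift detection (STARS) with AR(1) prewhitening.

STARS scans an annual series online.  From the cut-off length ``l`` it
derives a critical difference ``diff = t_crit * sqrt(2 * sigma_l^2 / l)``
(two-sided Student t at the chosen significance, 2l-2 degrees of freedom,
with ``sigma_l^2`` the average sample variance over all consecutive l-point
windows).  A point deviating from the current regime mean by more than
``diff`` becomes a candidate shift; over the following up-to-l points a
cumulative Regime Shift Index accumulates the normalized exceedance beyond
``mean +/- diff``.  If the cumulative index ever turns negative the candidate
is rejected and absorbed; if it stays positive through the full window the
shift is confirmed and a new regime starts at the candidate.  A candidate
whose window is cut short by the series end keeps a positive index but rests
on fewer than ``l`` points: it is reported as tentative, not confirmed.
Regime means always use the most recent ``min(l, regime length)`` points.

Because the sequential t-test assumes independent observations, series with
red noise are first passed through a white-noise filter: the lag-1
autoregression coefficient is estimated by ordinary least squares and the
series is replaced by ``x_t - alpha * x_{t-1}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnnualSeries",
    "StarsParams",
    "ShiftResult",
    "estimate_ar1",
    "prewhiten",
    "stars",
]


@dataclass(frozen=True)
class AnnualSeries:
    """A (label, value) sequence of annual observations.

    Labels are years (ints) or flood-pulse cycle ids sortable as years;
    explicitly missing years are simply absent — never imputed.
    """

    labels: tuple
    values: np.ndarray
    name: str = "series"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != len(values):
            raise ValueError("labels and values must have equal length")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        numeric = self.numeric_labels
        if np.any(np.diff(numeric) <= 0):
            raise ValueError("labels must be strictly increasing")

    @property
    def numeric_labels(self) -> np.ndarray:
        """Labels as floats; cycle ids 'YYYY-YYYY' map to their start year."""
        out = []
        for lab in self.labels:
            if isinstance(lab, str):
                out.append(float(lab.split("-")[0].split("–")[0]))
            else:
                out.append(float(lab))
        return np.asarray(out)

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_series(cls, s: pd.Series, name: str | None = None) -> "AnnualSeries":
        return cls(labels=tuple(s.index), values=s.to_numpy(dtype=float),
                   name=name or (s.name or "series"))


@dataclass(frozen=True)
class StarsParams:
    """STARS settings: significance level, cut-off length, prewhitening flag.

    Defaults follow common practice for hydrological series (p=0.05, l=10);
    biological series typically use p=0.01 with l of 7 or 10.
    """

    significance: float = 0.05
    cutoff: int = 10
    prewhiten: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.significance < 1.0:
            raise ValueError("significance must lie in (0, 1)")
        if self.cutoff < 3:
            raise ValueError("cutoff length must be at least 3")


@dataclass
class ShiftResult:
    """Confirmed shifts, regime means and diagnostics of one STARS run."""

    shifts: list            # label of the first point of each new regime
    regime_means: list      # one mean per regime (filtered scale if prewhitened)
    rsi: dict               # candidate label -> RSI (confirmed and tentative)
    tentative_shifts: list  # candidates whose confirmation window was truncated
                            # by the series end (RSI positive so far, unconfirmed)
    diff: float             # critical mean difference
    sigma_l2: float         # average l-point window variance
    alpha: float | None     # AR(1) estimate used for prewhitening (None if off)
    gap_flags: list = field(default_factory=list)  # shifts whose RSI window spanned a gap

    @property
    def n_shifts(self) -> int:
        return len(self.shifts)


def estimate_ar1(values: np.ndarray) -> float:
    """OLS estimate of the lag-1 autoregression coefficient.

    The slope of the centred regression of ``x_t`` on ``x_{t-1}``, clamped to
    (-0.99, 0.99) so the white-noise filter stays invertible.  A
    zero-variance series returns 0 with a warning.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("AR(1) estimation needs at least 3 points")
    xc = x - x.mean()
    denom = float(np.sum(xc[:-1] ** 2))
    if denom == 0.0:
        warnings.warn("zero-variance series: AR(1) coefficient set to 0",
                      stacklevel=2)
        return 0.0
    alpha = float(np.sum(xc[1:] * xc[:-1]) / denom)
    return float(np.clip(alpha, -0.99, 0.99))


def prewhiten(series: AnnualSeries, alpha: float) -> AnnualSeries:
    """Remove lag-1 autocorrelation: ``x'_t = x_t - alpha * x_{t-1}``.

    The first value is scaled by ``(1 - alpha)`` so a constant series maps to
    a constant series.  Labels are preserved.
    """
    if not abs(alpha) < 1.0:
        raise ValueError("|alpha| must be below 1")
    x = series.values
    out = np.empty_like(x)
    out[0] = x[0] * (1.0 - alpha)
    out[1:] = x[1:] - alpha * x[:-1]
    return AnnualSeries(labels=series.labels, values=out, name=series.name)


def _window_variance(values: np.ndarray, l: int) -> float:
    """Average sample variance over all consecutive l-point windows."""
    n = len(values)
    variances = [np.var(values[i:i + l], ddof=1) for i in range(n - l + 1)]
    return float(np.mean(variances))


def stars(series: AnnualSeries, params: StarsParams | None = None) -> ShiftResult:
    """Run the sequential t-test regime-shift scan on an annual series.

    Returns every confirmed shift (labelled by the first point of the new
    regime) with its Regime Shift Index, plus the critical difference,
    the window variance and, when prewhitening is on, the AR(1) estimate.
    A shift whose confirmation window spanned a gap in the labels is flagged
    in ``gap_flags``.
    """
    p = params or StarsParams()
    l = p.cutoff
    n = len(series)
    if l > n:
        raise ValueError(f"cutoff length {l} exceeds series length {n}")

    alpha: float | None = None
    work = series
    if p.prewhiten:
        alpha = estimate_ar1(series.values)
        work = prewhiten(series, alpha)

    x = work.values
    labels = list(work.labels)
    numeric = work.numeric_labels

    sigma_l2 = _window_variance(x, l)
    sigma_l = float(np.sqrt(sigma_l2))
    t_crit = float(stats.t.ppf(1.0 - p.significance / 2.0, df=2 * l - 2))
    diff = t_crit * float(np.sqrt(2.0 * sigma_l2 / l))

    shifts: list = []
    tentative: list = []
    rsi_confirmed: dict = {}
    gap_flags: list = []
    regime_start = 0  # index of first point of the current regime

    def regime_mean(upto: int) -> float:
        """Mean of the most recent min(l, length) points of the current regime."""
        lo = max(regime_start, upto - l + 1)
        return float(np.mean(x[lo:upto + 1]))

    i = l  # points 0..l-1 initialize the first regime
    current_mean = float(np.mean(x[:l]))
    while i < n:
        deviation = x[i] - current_mean
        if abs(deviation) <= diff or sigma_l == 0.0:
            current_mean = regime_mean(i)
            i += 1
            continue
        sign = 1.0 if deviation > 0 else -1.0
        boundary = current_mean + sign * diff
        window_end = min(i + l, n)
        cum = 0.0
        confirmed = True
        for j in range(i, window_end):
            cum += sign * (x[j] - boundary) / (l * sigma_l)
            if cum < 0.0:
                confirmed = False
                break
        if confirmed and window_end < i + l:
            # the series ended inside the confirmation window: the RSI is
            # positive so far but rests on fewer than l points — tentative
            tentative.append(labels[i])
            rsi_confirmed[labels[i]] = cum
            current_mean = regime_mean(i)
            i += 1
            continue
        if confirmed:
            shifts.append(labels[i])
            rsi_confirmed[labels[i]] = cum
            # flag if the confirmation window crossed a labelled gap
            span = numeric[i:window_end]
            if len(span) > 1 and np.any(np.diff(span) > 1.0):
                gap_flags.append(labels[i])
            regime_start = i
            current_mean = regime_mean(i)
            i += 1
        else:
            # candidate rejected: absorb the point into the current regime
            current_mean = regime_mean(i)
            i += 1

    # per-regime means over the most recent min(l, regime length) points
    boundaries = [0] + [labels.index(s) for s in shifts] + [n]
    means = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        lo = max(a, b - l)
        means.append(float(np.mean(x[lo:b])))

    return ShiftResult(
        shifts=shifts,
        regime_means=means,
        rsi=rsi_confirmed,
        tentative_shifts=tentative,
        diff=diff,
        sigma_l2=sigma_l2,
        alpha=alpha,
        gap_flags=gap_flags,
    )
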