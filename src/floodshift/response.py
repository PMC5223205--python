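"""Response-function models, generalized least-squares fits and AICc selection.

Seven candidate shapes describe how an annual state variable moves through a
regime change whose moment ``tau`` has been fixed beforehand (by STARS):

========== =====================================================
null        constant mean ``a``
linear      ``a + b*t``
step_mean   ``a`` before ``tau``, ``a + c`` from ``tau`` on
linear_linear  independent lines before/after ``tau``
linear_stable  line before ``tau``, constant ``m`` after
stable_linear  constant ``m`` before ``tau``, line after
sigmoid     ``a + c / (1 + exp(-(t - t0)/s))`` (free centre ``t0``)
========== =====================================================

Families linear in their parameters are solved per-segment in closed form;
the sigmoid uses bounded multi-start nonlinear least squares.  Errors may be
iid Gaussian, AR(1)-correlated (``phi^|i-j|`` correlation, coefficient
profiled on a grid then polished) or AR(1) with a separate variance on each
side of ``tau``.  Models are ranked by AICc; following the two-pass
procedure, if the best iid fit leaves lag-1 autocorrelated residuals every
family is refitted with AR(1) errors and re-ranked.

The parameter count ``k`` entering AICc includes every estimated quantity —
mean parameters, each variance, and phi when fitted — uniformly across
families; the fixed ``tau`` is not counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .regime import AnnualSeries

__all__ = [
    "FAMILIES",
    "ERROR_STRUCTURES",
    "FitResult",
    "ModelComparison",
    "model_mean",
    "fit",
    "aicc",
    "select_best",
    "residual_lag1",
    "ar1_loglik",
]

FAMILIES = (
    "null", "linear", "step_mean", "linear_linear",
    "linear_stable", "stable_linear", "sigmoid",
)
ERROR_STRUCTURES = ("iid", "ar1", "ar1_hetero")

SEGMENTED = ("step_mean", "linear_linear", "linear_stable", "stable_linear")

_PARAM_NAMES = {
    "null": ("a",),
    "linear": ("a", "b"),
    "step_mean": ("a", "c"),
    "linear_linear": ("a", "b", "a2", "b2"),
    "linear_stable": ("a", "b", "m"),
    "stable_linear": ("m", "a", "b"),
    "sigmoid": ("a", "c", "t0", "s"),
}

_SIGMOID_MIN_SLOPE = 0.1  # years; prevents collapse onto step_mean


def model_mean(family: str, params: dict, t, tau: float | None = None) -> np.ndarray:
    """Evaluate a family's mean function at times ``t``."""
    t = np.asarray(t, dtype=float)
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if family in SEGMENTED and tau is None:
        raise ValueError(f"{family} requires a change point tau")
    if family == "null":
        return np.full_like(t, params["a"])
    if family == "linear":
        return params["a"] + params["b"] * t
    post = t >= tau if tau is not None else None
    if family == "step_mean":
        return params["a"] + params["c"] * post
    if family == "linear_linear":
        return np.where(post, params["a2"] + params["b2"] * t,
                        params["a"] + params["b"] * t)
    if family == "linear_stable":
        return np.where(post, params["m"], params["a"] + params["b"] * t)
    if family == "stable_linear":
        return np.where(post, params["a"] + params["b"] * t, params["m"])
    # sigmoid
    s = params["s"]
    if s == 0:
        raise ValueError("sigmoid slope parameter s must be nonzero")
    z = np.clip((t - params["t0"]) / s, -500, 500)
    return params["a"] + params["c"] / (1.0 + np.exp(-z))


def _design(family: str, t: np.ndarray, tau: float | None) -> np.ndarray:
    """Design matrix of a linear-in-parameters family."""
    one = np.ones_like(t)
    post = (t >= tau).astype(float) if tau is not None else None
    if family == "null":
        return one[:, None]
    if family == "linear":
        return np.column_stack([one, t])
    pre = 1.0 - post
    if family == "step_mean":
        return np.column_stack([one, post])
    if family == "linear_linear":
        return np.column_stack([pre, t * pre, post, t * post])
    if family == "linear_stable":
        return np.column_stack([pre, t * pre, post])
    if family == "stable_linear":
        return np.column_stack([pre, post, t * post])
    raise ValueError(f"{family} is not linear in its parameters")


# ---------------------------------------------------------------------------
# AR(1) likelihood machinery


def _whiten(v: np.ndarray, phi: float) -> np.ndarray:
    """Prais-Winsten transform: z'z/(1-phi^2) equals v' R(phi)^-1 v."""
    z = np.empty_like(v)
    z[0] = np.sqrt(1.0 - phi**2) * v[0]
    z[1:] = v[1:] - phi * v[:-1]
    return z


def _quad_logdet(resid: np.ndarray, phi: float,
                 weights: np.ndarray | None) -> tuple[float, float]:
    """Quadratic form e' (S R S)^-1 e and log|S R S| for AR(1) correlation R
    with weight (relative standard deviation) matrix S = diag(weights)."""
    n = len(resid)
    e = resid / weights if weights is not None else resid
    z = _whiten(e, phi)
    quad = float(np.sum(z**2) / (1.0 - phi**2))
    logdet = (n - 1) * np.log(1.0 - phi**2)
    if weights is not None:
        logdet += 2.0 * float(np.sum(np.log(weights)))
    return quad, logdet


def ar1_loglik(resid: np.ndarray, phi: float, sigma2: float,
               weights: np.ndarray | None = None) -> float:
    """Exact Gaussian log-likelihood of residuals with covariance
    ``sigma2 * S R(phi) S`` computed through the closed-form tridiagonal
    inverse of the AR(1) correlation matrix."""
    resid = np.asarray(resid, dtype=float)
    n = len(resid)
    quad, logdet = _quad_logdet(resid, phi, weights)
    return float(-0.5 * (n * np.log(2.0 * np.pi * sigma2)
                         + logdet + quad / sigma2))


def _profile_loglik(resid: np.ndarray, phi: float,
                    weights: np.ndarray | None) -> tuple[float, float]:
    """Log-likelihood with the overall variance profiled out (ML scale)."""
    n = len(resid)
    quad, logdet = _quad_logdet(resid, phi, weights)
    floor = 1e-12 * max(float(np.var(resid)), 1e-12)
    sigma2 = max(quad / n, floor)
    ll = -0.5 * (n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet)
    return float(ll), float(sigma2)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """One family's fit: estimates, likelihood, AICc and residuals."""

    family: str
    params: dict
    n: int
    k: int
    loglik: float
    aicc: float
    sigma2: float
    phi: float | None = None
    variance_ratio: float | None = None  # post/pre variance (ar1_hetero)
    tau: float | None = None
    error_structure: str = "iid"
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    fitted: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True


@dataclass
class ModelComparison:
    """AICc ranking of the candidate families for one series.

    ``fits`` is sorted by AICc; ``best`` is the selected model after the
    parsimony rule (smallest ``k`` among fits within ``parsimony_delta``
    AICc units of the minimum — models that close are statistically
    equivalent, so the simplest description is preferred).
    """

    fits: list                  # FitResult, ranked by AICc (lowest first)
    best: FitResult
    error_structure: str
    autocorr_flagged: bool
    tau: float | None

    @property
    def best_family(self) -> str:
        return self.best.family

    def delta_aicc(self) -> dict:
        base = self.fits[0].aicc
        return {f.family: f.aicc - base for f in self.fits}


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with the finite-sample correction."""
    if n - k - 1 < 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n - k - 1 < 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _fit_mean_gls(family: str, t: np.ndarray, y: np.ndarray, tau: float | None,
                  phi: float, weights: np.ndarray | None) -> tuple[dict, np.ndarray]:
    """Mean parameters minimizing the GLS quadratic form at fixed phi/weights."""
    X = _design(family, t, tau)
    Xw = X / weights[:, None] if weights is not None else X
    yw = y / weights if weights is not None else y
    Xz = np.apply_along_axis(_whiten, 0, Xw, phi)
    yz = _whiten(yw, phi)
    beta, *_ = np.linalg.lstsq(Xz, yz, rcond=None)
    params = dict(zip(_PARAM_NAMES[family], beta))
    return params, X @ beta


def _sigmoid_starts(t: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Five deterministic starting points with centres spread over the series."""
    lo, hi = float(t.min()), float(t.max())
    span = hi - lo
    c0 = float(y[t >= np.quantile(t, 0.75)].mean() - y[t <= np.quantile(t, 0.25)].mean())
    a0 = float(y[: max(3, len(y) // 4)].mean())
    starts = []
    for q in (0.2, 0.35, 0.5, 0.65, 0.8):
        starts.append(np.array([a0, c0 if c0 != 0 else np.ptp(y) or 1.0,
                                lo + q * span, max(span / 10.0, _SIGMOID_MIN_SLOPE)]))
    return starts


def _fit_sigmoid(t: np.ndarray, y: np.ndarray, phi: float,
                 weights: np.ndarray | None) -> tuple[dict, np.ndarray, bool]:
    """Multi-start bounded nonlinear least squares on whitened residuals."""
    lo, hi = float(t.min()), float(t.max())
    span = hi - lo

    def whitened_resid(theta: np.ndarray) -> np.ndarray:
        a, c, t0, s = theta
        mu = model_mean("sigmoid", {"a": a, "c": c, "t0": t0, "s": s}, t)
        r = (y - mu) / weights if weights is not None else y - mu
        # ||z||^2 is proportional to the GLS quadratic form r' R^-1 r
        return _whiten(r, phi)

    bounds = (np.array([-np.inf, -np.inf, lo, _SIGMOID_MIN_SLOPE]),
              np.array([np.inf, np.inf, hi, max(span, _SIGMOID_MIN_SLOPE * 2)]))
    best = None
    for x0 in _sigmoid_starts(t, y):
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            res = optimize.least_squares(whitened_resid, x0, bounds=bounds,
                                         max_nfev=200)
        except Exception:  # pragma: no cover - optimizer edge failures
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return {}, np.full_like(y, np.nan), False
    params = dict(zip(_PARAM_NAMES["sigmoid"], best.x))
    return params, model_mean("sigmoid", params, t), True


def _k_for(family: str, error: str) -> int:
    k = len(_PARAM_NAMES[family]) + 1  # mean parameters + variance
    if error in ("ar1", "ar1_hetero"):
        k += 1  # phi
    if error == "ar1_hetero":
        k += 1  # second variance
    return k


_PHI_GRID = np.linspace(-0.9, 0.9, 19)
_DELTA_GRID = np.geomspace(0.2, 5.0, 9)  # post/pre standard-deviation ratio


def fit(series: AnnualSeries, family: str, tau: float | None = None,
        error: str = "iid") -> FitResult:
    """Fit one response-function family to an annual series.

    ``tau`` (a numeric year label) is required for the segmented families and
    used to place the variance break under ``ar1_hetero``.  The returned
    log-likelihood is the Gaussian ML value with the variance profiled out.
    """
    if error not in ERROR_STRUCTURES:
        raise ValueError(f"unknown error structure {error!r}")
    t = series.numeric_labels
    y = series.values
    n = len(y)
    k = _k_for(family, error)
    if n < k + 2:
        raise ValueError(f"series too short (n={n}) to fit {family} with k={k}")
    if family in SEGMENTED:
        if tau is None:
            raise ValueError(f"{family} requires tau")
        if not t.min() < tau <= t.max():
            raise ValueError("tau must lie strictly inside the series")

    def weights_for(delta: float) -> np.ndarray | None:
        if error != "ar1_hetero":
            return None
        if tau is None:
            raise ValueError("ar1_hetero requires tau to place the variance break")
        return np.where(t >= tau, delta, 1.0)

    def solve(phi: float, delta: float):
        w = weights_for(delta)
        if family == "sigmoid":
            params, mu, ok = _fit_sigmoid(t, y, phi, w)
        else:
            params, mu = _fit_mean_gls(family, t, y, tau, phi, w)
            ok = True
        ll, sigma2 = _profile_loglik(y - mu, phi, w)
        return params, mu, ll, sigma2, ok

    if error == "iid":
        params, mu, ll, sigma2, ok = solve(0.0, 1.0)
        phi_hat, delta_hat = None, None
    else:
        deltas = _DELTA_GRID if error == "ar1_hetero" else np.array([1.0])
        best = None
        for d in deltas:
            for phi in _PHI_GRID:
                out = solve(phi, d)
                if best is None or out[2] > best[2]:
                    best = (*out[:2], out[2], out[3], out[4], phi, d)
        phi0, d0 = best[5], best[6]
        if error == "ar1":
            res = optimize.minimize_scalar(
                lambda p: -solve(float(p), 1.0)[2],
                bounds=(max(-0.98, phi0 - 0.1), min(0.98, phi0 + 0.1)),
                method="bounded", options={"xatol": 1e-4},
            )
            phi_hat, delta_hat = float(res.x), None
            params, mu, ll, sigma2, ok = solve(phi_hat, 1.0)
        else:
            res = optimize.minimize(
                lambda v: -solve(float(np.clip(v[0], -0.98, 0.98)),
                                 float(np.exp(v[1])))[2],
                x0=np.array([phi0, np.log(d0)]), method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 200},
            )
            phi_hat = float(np.clip(res.x[0], -0.98, 0.98))
            delta_hat = float(np.exp(res.x[1]))
            params, mu, ll, sigma2, ok = solve(phi_hat, delta_hat)

    if not ok:
        warnings.warn(f"{family}: nonlinear fit failed to converge", stacklevel=2)
        return FitResult(family=family, params={}, n=n, k=k, loglik=-np.inf,
                         aicc=np.inf, sigma2=np.nan, phi=phi_hat, tau=tau,
                         error_structure=error, converged=False)
    return FitResult(
        family=family, params=params, n=n, k=k, loglik=ll,
        aicc=aicc(ll, k, n), sigma2=sigma2, phi=phi_hat,
        variance_ratio=None if delta_hat is None else delta_hat**2,
        tau=tau, error_structure=error,
        residuals=y - mu, fitted=mu,
    )


def residual_lag1(residuals: np.ndarray) -> tuple[float, bool]:
    """Lag-1 Pearson autocorrelation of residuals and its +/-1.96/sqrt(n) flag."""
    r = np.asarray(residuals, dtype=float)
    n = len(r)
    if n < 4:
        raise ValueError("need at least 4 residuals")
    a, b = r[:-1], r[1:]
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0, False
    r1 = float(np.corrcoef(a, b)[0, 1])
    return r1, bool(abs(r1) > 1.96 / np.sqrt(n))


def select_best(series: AnnualSeries, tau: float | None = None,
                families: tuple = FAMILIES, error: str = "iid",
                free_tau: bool = False,
                parsimony_delta: float = 2.0) -> ModelComparison:
    """Fit all candidate families and rank them by AICc.

    Mirrors the two-pass procedure: families are first fitted with the
    requested error structure (iid by default); if the best model's residuals
    show lag-1 autocorrelation beyond ``1.96/sqrt(n)``, every family is
    refitted with AR(1)-correlated errors and the ranking is redone.

    Models within ``parsimony_delta`` AICc units of the minimum are treated
    as equivalently supported and the one with fewest parameters is selected
    (the usual reading of a small AICc difference between nested candidates);
    set ``parsimony_delta=0`` to select the raw minimum.

    With ``free_tau=True`` the change point of each segmented family is
    profiled over interior years instead of being fixed.
    """
    def fit_one(family: str, err: str) -> FitResult:
        if free_tau and family in SEGMENTED:
            t = series.numeric_labels
            candidates = [v for v in t[1:] if t.min() < v <= t.max()]
            best = None
            for cand in candidates:
                try:
                    f = fit(series, family, tau=cand, error=err)
                except ValueError:
                    continue
                if best is None or f.loglik > best.loglik:
                    best = f
            if best is None:
                raise ValueError(f"no admissible tau for {family}")
            return best
        return fit(series, family, tau=tau, error=err)

    def run(err: str) -> list[FitResult]:
        fits = []
        for fam in families:
            try:
                f = fit_one(fam, err)
            except ValueError as exc:
                warnings.warn(f"{fam}: {exc}; excluded from ranking", stacklevel=2)
                continue
            if f.converged and np.isfinite(f.aicc):
                fits.append(f)
        if len(fits) < 2:
            raise ValueError("fewer than 2 admissible fits; cannot rank")
        order = {fam: i for i, fam in enumerate(FAMILIES)}
        fits.sort(key=lambda f: (f.aicc, order[f.family]))
        return fits

    order = {fam: i for i, fam in enumerate(FAMILIES)}

    def pick(fits: list[FitResult]) -> FitResult:
        close = [f for f in fits if f.aicc - fits[0].aicc <= parsimony_delta]
        close.sort(key=lambda f: (f.k, f.aicc, order[f.family]))
        return close[0]

    fits = run(error)
    r1, flagged = residual_lag1(pick(fits).residuals)
    final_error = error
    if flagged and error == "iid":
        final_error = "ar1"
        fits = run("ar1")
    return ModelComparison(fits=fits, best=pick(fits),
                           error_structure=final_error,
                           autocorr_flagged=flagged, tau=tau)
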