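"""Logistic grain-filling kinetics.

Grain dry weight over time follows the logistic law

    Y(t) = K / (1 + a * exp(-b * t))

with asymptotic weight ``K`` (mg/grain), shape coefficient ``a`` (> 0,
dimensionless) and rate coefficient ``b`` (> 0, 1/day); ``t`` is days
after flowering (DAF).  The grain-filling rate is its derivative

    V(t) = K * a * b * exp(-b * t) / (1 + a * exp(-b * t))^2

which peaks at ``t_peak = ln(a) / b`` with maximum rate ``V_max = K*b/4``.
Superior spikelets show a fast, early, asymmetric rate curve; inferior
spikelets a slower, later, near-symmetric one.

Fitting is plain (unweighted) nonlinear least squares with a deterministic
initialization: ``K0 = 1.05 * max(Y)``, then ``(a0, b0)`` from a linear
regression of ``logit(Y / K0)`` on ``t``.  Replicate standard deviations,
if provided, enable optional inverse-variance weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats


class FitError(RuntimeError):
    """Raised when the logistic fit cannot be performed or fails to converge."""


@dataclass(frozen=True)
class GrainWeightSeries:
    """Mean grain dry weight (mg) over days after flowering, one condition."""

    condition: str
    times: tuple[float, ...]
    weights: tuple[float, ...]
    replicate_sd: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if t.size != w.size:
            raise ValueError("times and weights must have equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if self.replicate_sd is not None and len(self.replicate_sd) != t.size:
            raise ValueError("replicate_sd length mismatch")


@dataclass(frozen=True)
class LogisticFit:
    K: float
    a: float
    b: float
    rss: float
    converged: bool
    n_points: int


def logistic_weight(t, K: float, a: float, b: float):
    """Y(t) = K / (1 + a e^{-bt}) — grain weight at time t (mg)."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + a * np.exp(-b * t))


def filling_rate(fit: LogisticFit | tuple[float, float, float], t) -> np.ndarray | float:
    """V(t) = K a b e^{-bt} / (1 + a e^{-bt})^2 — filling rate (mg/day)."""
    K, a, b = (fit.K, fit.a, fit.b) if isinstance(fit, LogisticFit) else fit
    t_arr = np.asarray(t, dtype=float)
    e = a * np.exp(-b * t_arr)
    v = K * b * e / (1.0 + e) ** 2
    return float(v) if np.isscalar(t) or t_arr.ndim == 0 else v


def _initial_guess(t: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    K0 = 1.05 * float(w.max())
    frac = np.clip(w / K0, 1e-9, 1 - 1e-9)
    # logit(Y/K0) = -ln a + b t
    logit = np.log(frac / (1.0 - frac))
    slope, intercept, *_ = stats.linregress(t, logit)
    b0 = max(float(slope), 1e-4)
    a0 = max(float(np.exp(-intercept)), 1e-8)
    return K0, a0, b0


def fit_logistic(series: GrainWeightSeries, weighted: bool = False) -> LogisticFit:
    """Least-squares logistic fit of a grain-weight time series.

    Requires at least 4 time points and non-constant weights.  The fit is
    deterministic: fixed initialization rule, parameter tolerance 1e-10,
    at most 10 000 function evaluations.  Non-convergence raises
    :class:`FitError` with the optimizer's diagnostics rather than
    returning a silently bad fit.
    """
    t = np.asarray(series.times, dtype=float)
    w = np.asarray(series.weights, dtype=float)
    if t.size < 4:
        raise FitError(
            f"logistic fit needs >= 4 time points to constrain K, a, b; got {t.size}"
        )
    if np.allclose(w, w[0]):
        raise FitError("degenerate series: weights are constant")
    sigma = None
    if weighted and series.replicate_sd is not None:
        sigma = np.asarray(series.replicate_sd, dtype=float)
        if np.any(sigma <= 0):
            raise FitError("inverse-variance weighting requires positive replicate_sd")
    p0 = _initial_guess(t, w)
    try:
        popt, _, info, msg, ier = optimize.curve_fit(
            logistic_weight,
            t,
            w,
            p0=p0,
            sigma=sigma,
            xtol=1e-10,
            ftol=1e-12,
            maxfev=10_000,
            full_output=True,
        )
    except RuntimeError as exc:
        raise FitError(f"logistic fit failed to converge: {exc}") from exc
    K, a, b = (float(v) for v in popt)
    converged = ier in (1, 2, 3, 4)
    if not converged:
        raise FitError(f"logistic fit did not converge: {msg}")
    if a <= 0 or b <= 0:
        raise FitError(f"fit left the parameter domain: a={a:.4g}, b={b:.4g}")
    resid = w - logistic_weight(t, K, a, b)
    return LogisticFit(
        K=K, a=a, b=b, rss=float(resid @ resid), converged=converged, n_points=t.size
    )


def kinetics_summary(
    fit: LogisticFit, completion_fraction: float = 0.95, grid_points: int = 512
) -> dict:
    """Derived kinetics of a fitted logistic curve.

    Returns closed-form quantities — peak time ``t_peak = ln(a)/b``, peak
    rate ``V_max = K b / 4``, time to a completion fraction ``f``
    (``t_f = ln(a f / (1-f)) / b``) — plus the mean filling rate over
    [0, t_f] and a descriptive asymmetry index: the moment skewness of the
    rate curve V(t) treated as a density over [0, t_99].  A symmetric rate
    curve (peak centred in the window) scores near 0; an early fast peak
    scores positive.
    """
    if not 0 < completion_fraction < 1:
        raise ValueError(f"completion fraction must lie in (0, 1), got {completion_fraction}")
    K, a, b = fit.K, fit.a, fit.b
    t_peak = math.log(a) / b
    v_max = K * b / 4.0
    f = completion_fraction
    t_f = math.log(a * f / (1.0 - f)) / b
    t99 = math.log(a * 0.99 / 0.01) / b
    grid = np.linspace(0.0, t99, grid_points)
    v = filling_rate(fit, grid)
    wsum = v.sum()
    mu = float((grid * v).sum() / wsum)
    var = float(((grid - mu) ** 2 * v).sum() / wsum)
    skew = float(((grid - mu) ** 3 * v).sum() / wsum) / var ** 1.5
    y0, yf = logistic_weight([0.0, t_f], K, a, b)
    return {
        "t_peak_daf": t_peak,
        "v_max_mg_per_day": v_max,
        "t_completion_daf": t_f,
        "completion_fraction": f,
        "mean_rate_mg_per_day": float((yf - y0) / t_f),
        "asymmetry_index": skew,
        "K_mg": K,
        "a": a,
        "b_per_day": b,
    }


def mean_rate(fit: LogisticFit, t1: float, t2: float) -> float:
    """Average filling rate (Y(t2) - Y(t1)) / (t2 - t1) over an interval."""
    if t2 <= t1:
        raise ValueError("need t2 > t1")
    y1, y2 = logistic_weight([t1, t2], fit.K, fit.a, fit.b)
    return float((y2 - y1) / (t2 - t1))
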