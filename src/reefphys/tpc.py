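"""Thermal performance curves and Q10 thermal sensitivity.

Three curve families, matching how each trait behaves across acclimation
temperature in this system:

* SMR rises roughly exponentially with temperature: ``value = a exp(b T)``.
* MMR is humped but shallow: a second-order polynomial.
* Aerobic scope is fitted with a Gaussian,
  ``value = amplitude * exp(-(T - topt)^2 / (2 sd^2))``, whose centre is
  the thermal optimum and whose sd is the performance breadth.

Q10 is the classical thermal-sensitivity coefficient
``(R2/R1)^(10/(T2-T1))``: the factor by which a rate changes per 10 degC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["TPCFit", "fit_exponential", "fit_poly2", "fit_gaussian", "q10"]

#: upper bound for the Gaussian breadth parameter, degC
BREADTH_MAX = 50.0
#: jittered restarts before a nonlinear fit is declared unconverged
N_RESTARTS = 5


@dataclass
class TPCFit:
    trait: str
    model: str  # "exponential" | "poly2" | "gaussian"
    params: dict
    r2: float
    n: int
    converged: bool
    flags: list[str] = field(default_factory=list)

    def predict(self, temps):
        t = np.asarray(temps, dtype=float)
        p = self.params
        if self.model == "exponential":
            return p["a"] * np.exp(p["b"] * t)
        if self.model == "poly2":
            return p["c0"] + p["c1"] * t + p["c2"] * t * t
        if self.model == "gaussian":
            return p["amplitude"] * np.exp(
                -((t - p["topt"]) ** 2) / (2.0 * p["breadth_sd"] ** 2)
            )
        raise ValueError(f"unknown model {self.model!r}")


def _r2(y, yhat) -> float:
    sst = np.sum((y - np.mean(y)) ** 2)
    if sst == 0:
        return float("nan")
    return float(1.0 - np.sum((y - yhat) ** 2) / sst)


def _clean(temps, values, min_distinct: int):
    t = np.asarray(temps, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if np.unique(t).size < min_distinct:
        raise ValueError(f"need at least {min_distinct} distinct temperatures")
    return t, y


def fit_exponential(temps, values, trait: str = "SMR") -> TPCFit:
    """Fit value = a exp(b T) by nonlinear least squares.

    Initialised from the log-linear OLS solution (which requires positive
    values); r2 is reported on the original scale, so it can be negative
    for a poor fit.
    """
    t, y = _clean(temps, values, 3)
    if np.any(y <= 0):
        raise ValueError("exponential fit requires positive values")
    # log-linear start
    b0, loga0 = np.polyfit(t, np.log(y), 1)
    p0 = [math.exp(loga0), b0]
    f = lambda T, a, b: a * np.exp(b * T)  # noqa: E731
    rng = np.random.default_rng(0)
    params, converged = None, False
    for attempt in range(N_RESTARTS + 1):
        try:
            start = p0 if attempt == 0 else [
                p0[0] * rng.lognormal(0, 0.2), p0[1] + rng.normal(0, 0.02)
            ]
            popt, _ = curve_fit(f, t, y, p0=start, maxfev=20000,
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
            params, converged = popt, True
            break
        except RuntimeError:
            continue
    if params is None:
        params = p0
    a, b = (float(v) for v in params)
    fit = TPCFit(
        trait=trait,
        model="exponential",
        params={"a": a, "b": b},
        r2=_r2(y, a * np.exp(b * t)),
        n=len(y),
        converged=converged,
    )
    if not converged:
        fit.flags.append("unconverged")
    return fit


def fit_poly2(temps, values, trait: str = "MMR") -> TPCFit:
    """OLS quadratic (closed form). The vertex is reported in params."""
    t, y = _clean(temps, values, 3)
    c2, c1, c0 = np.polyfit(t, y, 2)
    params = {"c0": float(c0), "c1": float(c1), "c2": float(c2)}
    if c2 != 0:
        vx = -c1 / (2.0 * c2)
        params["vertex_temp"] = float(vx)
        params["vertex_value"] = float(c0 + c1 * vx + c2 * vx * vx)
    yhat = c0 + c1 * t + c2 * t * t
    return TPCFit(trait=trait, model="poly2", params=params, r2=_r2(y, yhat),
                  n=len(y), converged=True)


def _binned_means(t, y):
    temps = np.unique(t)
    return temps, np.array([y[t == tt].mean() for tt in temps])


def fit_gaussian(temps, values, trait: str = "AS") -> TPCFit:
    """Fit the Gaussian aerobic-scope curve.

    Initialisation: topt at the temperature whose binned mean is largest,
    breadth at half the observed temperature span, amplitude at the largest
    binned mean. Bounds keep breadth in (0, 50] degC and topt within the
    sampled span plus/minus 10 degC. With exactly 3 distinct temperatures a
    3-parameter fit is exact and flagged as such; flat data leave the
    breadth at its bound and are flagged rather than silently reported.
    """
    t, y = _clean(temps, values, 3)
    n_distinct = np.unique(t).size
    bt, bm = _binned_means(t, y)
    span = t.max() - t.min()
    p0 = [float(bm.max()), float(bt[int(np.argmax(bm))]), max(span / 2.0, 1.0)]
    lo = [0.0, t.min() - 10.0, 1e-6]
    hi = [np.inf, t.max() + 10.0, BREADTH_MAX]
    f = lambda T, amp, topt, sd: amp * np.exp(-((T - topt) ** 2) / (2.0 * sd * sd))  # noqa: E731
    rng = np.random.default_rng(0)
    params, converged = None, False
    for attempt in range(N_RESTARTS + 1):
        try:
            if attempt == 0:
                start = p0
            else:
                start = [
                    p0[0] * rng.lognormal(0, 0.2),
                    float(np.clip(p0[1] + rng.normal(0, 2.0), lo[1], hi[1])),
                    float(np.clip(p0[2] * rng.lognormal(0, 0.3), 0.5, BREADTH_MAX)),
                ]
            popt, _ = curve_fit(
                f, t, y, p0=start, bounds=(lo, hi), maxfev=20000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            params, converged = popt, True
            break
        except RuntimeError:
            continue
    if params is None:
        params = p0
    amp, topt, sd = (float(v) for v in params)
    fit = TPCFit(
        trait=trait,
        model="gaussian",
        params={"amplitude": amp, "topt": topt, "breadth_sd": sd},
        r2=_r2(y, f(t, amp, topt, sd)),
        n=len(y),
        converged=converged,
    )
    if not converged:
        fit.flags.append("unconverged")
    if n_distinct == 3:
        fit.flags.append("exact_fit_3_temps")
    if sd >= BREADTH_MAX - 1e-6:
        fit.flags.append("breadth_at_bound")
        fit.converged = False
    return fit


def q10(r1: float, r2: float, t1: float, t2: float) -> float:
    """Thermal sensitivity Q10 = (R2/R1)^(10/(T2-T1)).

    Inputs are oriented internally so that t2 > t1; the same physical pair
    therefore gives the same Q10 regardless of argument order.
    """
    if r1 <= 0 or r2 <= 0:
        raise ValueError("rates must be positive")
    if t1 == t2:
        raise ValueError("temperatures must differ")
    if t2 < t1:
        r1, r2, t1, t2 = r2, r1, t2, t1
    return (r2 / r1) ** (10.0 / (t2 - t1))
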