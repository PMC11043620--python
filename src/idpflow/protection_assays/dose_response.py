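"""Four-parameter logistic (Hill slope 1) dose-response fitting.

The model is f(x) = low + (high - low) / (1 + 10^(logEC50 - x)), where "low"
and "high" are the asymptotes at low and high x. This single parameterization
covers descending CF-leakage curves and ascending electrolyte-leakage curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["DoseResponseFit", "dose_response_fit", "four_param_logistic"]


def four_param_logistic(x, low, high, logec50):
    x = np.asarray(x, dtype=float)
    return low + (high - low) / (1.0 + 10.0 ** (logec50 - x))


@dataclass(frozen=True)
class DoseResponseFit:
    asymptote_low_x: float
    asymptote_high_x: float
    logEC50: float
    se: tuple[float, float, float]     # per-parameter standard errors
    residuals: np.ndarray
    degenerate: bool = False           # constant-response input
    ec50_outside_range: bool = False

    @property
    def stabilization_capacity(self) -> float:
        """The high-x asymptote (plateau reached at full occupancy)."""
        return self.asymptote_high_x

    def predict(self, x):
        return four_param_logistic(x, self.asymptote_low_x,
                                   self.asymptote_high_x, self.logEC50)


def _starts(x: np.ndarray, y: np.ndarray):
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    k = max(len(xs) // 4, 1)
    low0 = float(np.mean(ys[:k]))
    high0 = float(np.mean(ys[-k:]))
    mids = [float(np.median(xs)), float(np.quantile(xs, 0.25)),
            float(np.quantile(xs, 0.75))]
    for mid in mids:
        yield (low0, high0, mid)
        yield (high0, low0, mid)


def dose_response_fit(x, y, descending_allowed: bool = True) -> DoseResponseFit:
    """Least-squares 4PL fit with multi-start initialization from quantiles.

    ``x`` is log10(occupancy) (or temperature for freeze curves); replicate
    y values at the same x are allowed. Degenerate (constant-y) input is
    flagged rather than rejected; an EC50 outside the sampled x range sets a
    warning flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(np.unique(x)) < 5:
        raise ValueError("need at least 5 distinct x values")

    if np.ptp(y) == 0:
        warnings.warn("constant response; dose-response fit is degenerate")
        return DoseResponseFit(float(y[0]), float(y[0]), float(np.median(x)),
                               (0.0, 0.0, float("inf")),
                               residuals=np.zeros_like(y), degenerate=True)

    best = None
    for p0 in _starts(x, y):
        try:
            popt, pcov = curve_fit(four_param_logistic, x, y, p0=p0,
                                   maxfev=20000)
        except RuntimeError:
            continue
        resid = y - four_param_logistic(x, *popt)
        cost = float(resid @ resid)
        if best is None or cost < best[2]:
            best = (popt, pcov, cost, resid)
    if best is None:
        raise RuntimeError("dose-response fit did not converge from any start; "
                           f"x-range [{x.min():.3g}, {x.max():.3g}]")
    popt, pcov, _, resid = best
    low, high, logec50 = (float(v) for v in popt)
    if not descending_allowed and high < low:
        raise ValueError("descending response encountered but not allowed")
    se = tuple(float(np.sqrt(v)) if np.isfinite(v) and v >= 0 else float("nan")
               for v in np.diag(pcov))
    outside = not (x.min() <= logec50 <= x.max())
    if outside:
        warnings.warn("fitted EC50 lies outside the sampled x range")
    return DoseResponseFit(low, high, logec50, se, residuals=resid,
                           ec50_outside_range=outside)
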