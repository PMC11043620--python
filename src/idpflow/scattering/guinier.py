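"""Guinier analysis with self-consistent low-q window selection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import ScatteringCurve

__all__ = ["GuinierResult", "guinier_fit", "GuinierFitError"]

SAXS_LIMIT = 1.3   # q_max * R_G validity bound for X-rays
SANS_LIMIT = 1.1   # stricter bound used for neutron data

_MIN_POINTS = 5
_MAX_ROUNDS = 50


class GuinierFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class GuinierResult:
    R_G: float            # Å
    R_G_se: float
    I0: float
    window: tuple[float, float]   # (q_min, q_max) of the accepted points
    n_points: int
    limit: float
    qmax_RG: float        # realized q_max * R_G, <= limit
    weighted: bool

    def __post_init__(self) -> None:
        if self.qmax_RG > self.limit + 1e-9:
            raise ValueError("realized qmax*R_G exceeds the requested limit")
        if self.n_points < _MIN_POINTS:
            raise ValueError("Guinier window must contain >= 5 points")


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares line y = a + b x; returns a, b, var(a), var(b)."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx <= 0:
        raise GuinierFitError("degenerate q-range in Guinier window")
    b = np.sum(w * (x - xm) * (y - ym)) / sxx
    a = ym - b * xm
    n = len(x)
    resid = y - (a + b * x)
    # scale weights to residual variance for SE estimates
    s2 = np.sum(w * resid**2) / max(n - 2, 1)
    var_b = s2 / sxx
    var_a = s2 * (1.0 / W + xm**2 / sxx)
    return a, b, var_a, var_b


def _fit_window(curve: ScatteringCurve, idx: np.ndarray):
    q = curve.q[idx]
    I = curve.I[idx]
    if np.any(I <= 0):
        raise GuinierFitError("non-positive intensity inside Guinier window")
    x = q**2
    y = np.log(I)
    if curve.sigma is not None:
        w = (I / curve.sigma[idx]) ** 2   # var(ln I) = (sigma/I)^2
        weighted = True
    else:
        w = np.ones_like(x)
        weighted = False
    a, b, var_a, var_b = _wls_line(x, y, w)
    if b >= 0:
        raise GuinierFitError("Guinier slope is non-negative; no R_G")
    rg = float(np.sqrt(-3.0 * b))
    rg_se = float(1.5 / rg * np.sqrt(var_b))
    return rg, rg_se, float(np.exp(a)), weighted


def guinier_fit(curve: ScatteringCurve, limit: float = SAXS_LIMIT,
                q_min: float | None = None) -> GuinierResult:
    """Fit ln I = ln I0 - R_G^2 q^2 / 3 on a self-consistently chosen window.

    Starting from the lowest usable q, the window is grown (or shrunk) until
    the largest included q satisfies q_max * R_G(fit) <= ``limit`` and the
    window reproduces itself under refitting. Sigma-weighted when the curve
    carries uncertainties.
    """
    usable = curve.I > 0
    if q_min is not None:
        usable &= curve.q >= q_min
    order = np.flatnonzero(usable)
    if len(order) < 8:
        raise GuinierFitError("need at least 8 usable low-q points")

    def window(n_pts: int) -> np.ndarray:
        return order[:n_pts]

    n = 8
    seen: set[int] = set()
    rg = rg_se = i0 = None
    weighted = False
    for _ in range(_MAX_ROUNDS):
        idx = window(n)
        rg, rg_se, i0, weighted = _fit_window(curve, idx)
        q_allow = limit / rg
        n_new = int(np.searchsorted(curve.q[order], q_allow, side="right"))
        n_new = max(n_new, _MIN_POINTS)
        n_new = min(n_new, len(order))
        if n_new == n:
            break
        if n_new in seen:       # cycle: prefer the smaller (safer) window
            n = min(n, n_new)
            idx = window(n)
            rg, rg_se, i0, weighted = _fit_window(curve, idx)
            break
        seen.add(n)
        n = n_new

    # hard enforcement of the validity bound
    while n > _MIN_POINTS and curve.q[window(n)[-1]] * rg > limit:
        n -= 1
        rg, rg_se, i0, weighted = _fit_window(curve, window(n))
    idx = window(n)
    qmax = float(curve.q[idx[-1]])
    if qmax * rg > limit + 1e-9:
        raise GuinierFitError(
            f"no stable window with >= {_MIN_POINTS} points satisfies "
            f"q_max*R_G <= {limit}")
    return GuinierResult(R_G=rg, R_G_se=rg_se, I0=i0,
                         window=(float(curve.q[idx[0]]), qmax),
                         n_points=int(n), limit=float(limit),
                         qmax_RG=float(qmax * rg), weighted=weighted)
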