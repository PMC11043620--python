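"""Two-regime Guinier/power-law (generalized Gauss) fitting.

The model is the s = 0 member of Hammouda's family: a Guinier exponential
below the crossover Q1 and D*q^(-d) above it, with Q1 and D fixed by
continuity of I and dI/dq, leaving (G, R_G, d) as the free parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .curves import ScatteringCurve
from .guinier import GuinierFitError, guinier_fit

__all__ = ["GuinierPorodResult", "guinier_porod_fit", "gp_model"]

_D_BOUNDS = (1.0, 4.0)
_D_STARTS = (1.5, 2.0, 3.0, 4.0)


@dataclass(frozen=True)
class GuinierPorodResult:
    R_G: float
    d: float
    G: float
    Q1: float
    residual: float            # root-mean-square of the fit residuals
    background: float = 0.0
    d_at_bound: bool = False

    def __post_init__(self) -> None:
        expected_q1 = np.sqrt(1.5 * self.d) / self.R_G
        if not np.isclose(self.Q1, expected_q1, rtol=1e-6):
            raise ValueError("Q1 inconsistent with (R_G, d) continuity relation")


def gp_model(q: np.ndarray, G: float, R_G: float, d: float,
             background: float = 0.0) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    q1 = np.sqrt(1.5 * d) / R_G
    D = G * np.exp(-d / 2.0) * q1**d
    I = np.where(q <= q1, G * np.exp(-(q**2) * R_G**2 / 3.0), D * q ** (-d))
    return I + background


def guinier_porod_fit(curve: ScatteringCurve,
                      fit_background: bool = False) -> GuinierPorodResult:
    """Least-squares fit of (G, R_G, d), multi-started over d.

    Sigma-weighted when uncertainties are present. An optional flat additive
    background can be floated (off by default). Raises on non-convergence;
    warns when d is pinned at a bound.
    """
    q, I = curve.q, curve.I
    if len(q) < 10:
        raise ValueError("need at least 10 points spanning both regimes")
    w = 1.0 / curve.sigma if curve.sigma is not None else np.ones_like(I)

    # initial scale/size guesses
    try:
        g0 = guinier_fit(curve)
        rg0, G0 = g0.R_G, g0.I0
    except GuinierFitError:
        rg0 = 1.0 / q[len(q) // 4]
        G0 = float(I[0])

    lo = [1e-12, 1e-3, _D_BOUNDS[0]]
    hi = [np.inf, np.inf, _D_BOUNDS[1]]
    if fit_background:
        lo.append(-np.inf)
        hi.append(np.inf)

    def residuals(p):
        bg = p[3] if fit_background else 0.0
        return w * (gp_model(q, p[0], p[1], p[2], bg) - I)

    best = None
    for d0 in _D_STARTS:
        p0 = [G0, rg0, d0] + ([0.0] if fit_background else [])
        try:
            sol = least_squares(residuals, p0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except ValueError:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("Guinier-Porod fit failed to converge from any start")

    G, rg, d = best.x[:3]
    bg = float(best.x[3]) if fit_background else 0.0
    at_bound = bool(np.isclose(d, _D_BOUNDS[0]) or np.isclose(d, _D_BOUNDS[1]))
    if at_bound:
        warnings.warn(f"power-law exponent pinned at bound d={d:.3g}")
    rms = float(np.sqrt(2.0 * best.cost / len(q)))
    return GuinierPorodResult(R_G=float(rg), d=float(d), G=float(G),
                              Q1=float(np.sqrt(1.5 * d) / rg),
                              residual=rms, background=bg, d_at_bound=at_bound)
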