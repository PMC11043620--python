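"""Cumulant analysis of DLS autocorrelation functions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlogram import CorrelogramTable, stokes_einstein_radius

__all__ = ["HydroResult", "CumulantResult", "cumulant_fit"]

_FLOOR_FRAC = 1e-3   # fit only where g2-1 exceeds this fraction of its maximum


@dataclass(frozen=True)
class HydroResult:
    D: float              # m^2/s
    R_S_nm: float
    R_S_se_nm: float
    method: str           # 'cumulant' | 'regularized'


@dataclass(frozen=True)
class CumulantResult:
    Gamma: float          # mean decay rate, 1/s
    Gamma_se: float
    PDI: float            # mu2 / Gamma^2 (0 for order-1 fits)
    hydro: HydroResult


def cumulant_fit(corr: CorrelogramTable, order: int = 2) -> CumulantResult:
    """Fit ln sqrt(g2 - 1) = ln sqrt(beta) - Gamma tau (+ mu2 tau^2 / 2).

    D = Gamma / q^2 with q from the instrument fields; R_S via Stokes-Einstein.
    Raises on non-decaying input.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    g = corr.g2m1
    keep = g > max(g.max(), 0) * _FLOOR_FRAC
    if keep.sum() < 10:
        raise ValueError("fewer than 10 usable lags above the noise floor")
    tau = corr.tau[keep]
    y = np.log(np.sqrt(g[keep]))

    deg = order
    coeffs, cov = np.polyfit(tau, y, deg, cov=True)
    if deg == 1:
        slope, _ = coeffs
        gamma = -slope
        gamma_var = cov[0, 0]
        mu2 = 0.0
    else:
        c2, c1, _ = coeffs
        gamma = -c1
        gamma_var = cov[1, 1]
        mu2 = 2.0 * c2
    if gamma <= 0:
        raise ValueError("correlogram does not decay; no diffusive mode")

    q = corr.instrument.q
    D = gamma / q**2
    rs_m = stokes_einstein_radius(D, corr.instrument.temperature_K,
                                  corr.instrument.viscosity_Pa_s)
    # R_S ~ 1/Gamma, so relative errors match
    rs_se = rs_m * np.sqrt(gamma_var) / gamma
    pdi = float(mu2 / gamma**2) if order == 2 else 0.0
    hydro = HydroResult(D=float(D), R_S_nm=float(rs_m * 1e9),
                        R_S_se_nm=float(rs_se * 1e9), method="cumulant")
    return CumulantResult(Gamma=float(gamma), Gamma_se=float(np.sqrt(gamma_var)),
                          PDI=pdi, hydro=hydro)
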