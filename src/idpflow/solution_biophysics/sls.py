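"""Static light scattering: apparent mass and infinite-dilution extrapolation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.constants as const

__all__ = ["SLSOptics", "apparent_mass", "extrapolate_zero_concentration",
           "MassSeries", "relative_mass_series"]

# Toluene Rayleigh ratio at 532 nm, cm^-1 (configurable standard constant).
TOLUENE_RAYLEIGH_532 = 2.79e-5


@dataclass(frozen=True)
class SLSOptics:
    refractive_index: float = 1.333
    wavelength_nm: float = 532.0
    toluene_rayleigh: float = TOLUENE_RAYLEIGH_532   # cm^-1

    @property
    def K_cm(self) -> float:
        """Optical constant K = 4 pi^2 n^2 (dn/dc)^2 / (N_A lambda^4), cgs.

        Returned per (dn/dc)^2; multiply by (dn/dc in mL/g)^2 to get
        mol cm^2 / g^2 with lambda in cm.
        """
        lam_cm = self.wavelength_nm * 1e-7
        return 4.0 * np.pi**2 * self.refractive_index**2 / (const.N_A * lam_cm**4)


def apparent_mass(intensity_ratio: float, c_mg_ml: float, dndc_ml_g: float,
                  optics: SLSOptics = SLSOptics()) -> float:
    """M_app = R_theta / (K c), with R_theta from the toluene standard.

    ``intensity_ratio`` is sample intensity normalized to toluene; c in
    mg/mL (= g/mL * 1e-3); result in g/mol.
    """
    if c_mg_ml <= 0:
        raise ValueError("concentration must be positive")
    if intensity_ratio <= 0 or dndc_ml_g <= 0:
        raise ValueError("intensity ratio and dn/dc must be positive")
    r_theta = intensity_ratio * optics.toluene_rayleigh          # cm^-1
    K = optics.K_cm * dndc_ml_g**2                               # mol cm^2 / g^2
    c_g_ml = c_mg_ml * 1e-3
    return r_theta / (K * c_g_ml)


def forward_intensity_ratio(M_g_mol: float, c_mg_ml: float, dndc_ml_g: float,
                            optics: SLSOptics = SLSOptics()) -> float:
    """Inverse of :func:`apparent_mass`: the toluene-normalized intensity an
    ideal solution of mass M would produce (used by synthetic fixtures)."""
    K = optics.K_cm * dndc_ml_g**2
    return K * (c_mg_ml * 1e-3) * M_g_mol / optics.toluene_rayleigh


def extrapolate_zero_concentration(series) -> tuple[float, float]:
    """OLS intercept (and its SE) of value vs concentration.

    ``series`` is an iterable of (c, value) pairs with >= 3 distinct
    concentrations; returns (intercept, intercept_SE).
    """
    pts = np.asarray(list(series), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("series must be (c, value) pairs")
    c, v = pts[:, 0], pts[:, 1]
    if len(np.unique(c)) < 3:
        raise ValueError("need >= 3 distinct concentrations for extrapolation")
    X = np.column_stack([np.ones_like(c), c])
    coef, res, *_ = np.linalg.lstsq(X, v, rcond=None)
    fitted = X @ coef
    dof = max(len(c) - 2, 1)
    s2 = float(np.sum((v - fitted) ** 2)) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return float(coef[0]), float(np.sqrt(cov[0, 0]))


@dataclass(frozen=True)
class MassSeries:
    concentrations: np.ndarray    # mg/mL
    apparent_masses: np.ndarray   # g/mol
    M0: float                     # extrapolated mass at c -> 0
    M0_se: float
    M_rel: float                  # M0 / M_monomer
    M_monomer: float


def relative_mass_series(concentrations, intensity_ratios, dndc_ml_g: float,
                         M_monomer: float,
                         optics: SLSOptics = SLSOptics()) -> MassSeries:
    """Apparent masses per concentration, extrapolated to infinite dilution
    and expressed relative to the monomer mass."""
    c = np.asarray(concentrations, dtype=float)
    ratios = np.asarray(intensity_ratios, dtype=float)
    masses = np.array([apparent_mass(r, ci, dndc_ml_g, optics)
                       for r, ci in zip(ratios, c)])
    m0, se = extrapolate_zero_concentration(zip(c, masses))
    return MassSeries(concentrations=c, apparent_masses=masses, M0=m0,
                      M0_se=se, M_rel=m0 / M_monomer, M_monomer=M_monomer)
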