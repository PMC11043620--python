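"""DLS correlogram container and instrument optics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.constants as const

__all__ = ["Instrument", "CorrelogramTable", "stokes_einstein_radius",
           "stokes_einstein_diffusion", "WATER_VISCOSITY_23C"]

WATER_VISCOSITY_23C = 0.9325e-3   # Pa*s, water at 23 degC (default label only)


@dataclass(frozen=True)
class Instrument:
    """Single-angle light-scattering optics; defaults: 532 nm, 90 deg, water."""

    wavelength_nm: float = 532.0
    angle_deg: float = 90.0
    refractive_index: float = 1.333
    temperature_K: float = 296.15
    viscosity_Pa_s: float = WATER_VISCOSITY_23C

    @property
    def q(self) -> float:
        """Scattering vector magnitude in 1/m: q = 4*pi*n/lambda * sin(angle/2)."""
        lam = self.wavelength_nm * 1e-9
        return 4.0 * np.pi * self.refractive_index / lam * np.sin(
            np.deg2rad(self.angle_deg) / 2.0)


@dataclass
class CorrelogramTable:
    tau: np.ndarray        # lag times, s, increasing and positive
    g2m1: np.ndarray       # g2(tau) - 1
    instrument: Instrument = field(default_factory=Instrument)

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.g2m1 = np.asarray(self.g2m1, dtype=float)
        if self.tau.shape != self.g2m1.shape or self.tau.ndim != 1:
            raise ValueError("tau and g2m1 must be 1-D arrays of equal length")
        if np.any(self.tau <= 0) or np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau must be strictly increasing and positive")


def stokes_einstein_radius(D: float, temperature_K: float, viscosity_Pa_s: float) -> float:
    """R_S = k_B T / (6 pi eta D); D in m^2/s, result in m."""
    return const.k * temperature_K / (6.0 * np.pi * viscosity_Pa_s * D)


def stokes_einstein_diffusion(R_S_m: float, temperature_K: float, viscosity_Pa_s: float) -> float:
    """Inverse of :func:`stokes_einstein_radius` (exact round trip)."""
    return const.k * temperature_K / (6.0 * np.pi * viscosity_Pa_s * R_S_m)
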