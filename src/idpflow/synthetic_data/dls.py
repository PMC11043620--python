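"""Forward models for DLS correlograms and SLS concentration series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..solution_biophysics.correlogram import (CorrelogramTable, Instrument,
                                               stokes_einstein_diffusion)
from ..solution_biophysics.sls import SLSOptics, forward_intensity_ratio

__all__ = ["DLSTruth", "make_dls_correlogram", "SLSTruth", "make_sls_series"]


@dataclass(frozen=True)
class DLSTruth:
    """Mixture of diffusing species: (R_S in nm, intensity weight) pairs."""

    components: tuple[tuple[float, float], ...]
    instrument: Instrument = field(default_factory=Instrument)
    beta: float = 1.0
    noise: float = 0.0              # additive Gaussian SD on g2-1
    seed: int = 0
    n_lags: int = 120
    tau_span: tuple[float, float] | None = None   # s; auto from decay rates

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("need at least one component")
        weights = np.array([w for _, w in self.components], dtype=float)
        radii = np.array([r for r, _ in self.components], dtype=float)
        if np.any(radii <= 0):
            raise ValueError("R_S values must be positive")
        if np.any(weights <= 0) or not np.isclose(weights.sum(), 1.0):
            raise ValueError("weights must be positive and sum to 1")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def make_dls_correlogram(truth: DLSTruth) -> CorrelogramTable:
    """g2(tau) - 1 = beta * (sum_i w_i exp(-Gamma_i tau))^2 plus noise.

    Gamma_i = D_i q^2 with D_i from Stokes-Einstein at the instrument's
    temperature and viscosity.
    """
    rng = np.random.default_rng(truth.seed)
    inst = truth.instrument
    q = inst.q
    gammas = np.array([
        stokes_einstein_diffusion(r * 1e-9, inst.temperature_K,
                                  inst.viscosity_Pa_s) * q**2
        for r, _ in truth.components])
    weights = np.array([w for _, w in truth.components])
    if truth.tau_span is None:
        tau = np.geomspace(0.01 / gammas.max(), 10.0 / gammas.min(), truth.n_lags)
    else:
        tau = np.geomspace(truth.tau_span[0], truth.tau_span[1], truth.n_lags)
    g1 = np.sum(weights[:, None] * np.exp(-gammas[:, None] * tau[None, :]), axis=0)
    g2m1 = truth.beta * g1**2
    if truth.noise > 0:
        g2m1 = g2m1 + truth.noise * rng.standard_normal(g2m1.shape)
    return CorrelogramTable(tau=tau, g2m1=g2m1, instrument=inst)


@dataclass(frozen=True)
class SLSTruth:
    """Ideal-solution SLS series with an optional linear interaction slope."""

    M_g_mol: float
    dndc_ml_g: float = 0.185
    concentrations_mg_mL: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
    interaction_slope: float = 0.0      # dM_app/dc, (g/mol)/(mg/mL)
    noise_frac: float = 0.0
    seed: int = 0
    optics: SLSOptics = field(default_factory=SLSOptics)

    def __post_init__(self) -> None:
        if self.M_g_mol <= 0:
            raise ValueError("mass must be positive")


def make_sls_series(truth: SLSTruth) -> tuple[np.ndarray, np.ndarray]:
    """(concentrations, toluene-normalized intensities) for the given truth.

    The apparent mass at concentration c is M + interaction_slope * c, so the
    infinite-dilution extrapolation recovers M.
    """
    rng = np.random.default_rng(truth.seed)
    c = np.asarray(truth.concentrations_mg_mL, dtype=float)
    m_app = truth.M_g_mol + truth.interaction_slope * c
    ratios = np.array([forward_intensity_ratio(m, ci, truth.dndc_ml_g, truth.optics)
                       for m, ci in zip(m_app, c)])
    if truth.noise_frac > 0:
        ratios = ratios * (1.0 + truth.noise_frac * rng.standard_normal(ratios.shape))
    return c, ratios
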