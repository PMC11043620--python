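"""Forward model for two-regime (Guinier into power-law) scattering curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..scattering.curves import ScatteringCurve

__all__ = ["GuinierPorodTruth", "make_guinier_porod_curve", "guinier_porod_intensity"]


@dataclass(frozen=True)
class GuinierPorodTruth:
    """Ground truth for a Guinier regime crossing into a q^(-d) power law."""

    R_G: float                 # Å
    d: float                   # power-law exponent, 1..4
    G: float = 1.0             # forward-scattering scale
    noise_frac: float = 0.0    # relative (multiplicative) Gaussian noise
    q_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.005, 0.5, 200))
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "q_grid", np.asarray(self.q_grid, dtype=float))
        if self.R_G <= 0:
            raise ValueError("R_G must be positive")
        if not 1.0 <= self.d <= 4.0:
            raise ValueError("d must be in [1, 4]")
        if self.G <= 0:
            raise ValueError("G must be positive")
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be >= 0")
        q = self.q_grid
        if q.ndim != 1 or len(q) < 2 or np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise ValueError("q_grid must be strictly increasing and positive")

    @property
    def Q1(self) -> float:
        """Crossover q fixed by C1 continuity: Q1 = sqrt(3 d / 2) / R_G."""
        return np.sqrt(1.5 * self.d) / self.R_G


def guinier_porod_intensity(q: np.ndarray, G: float, R_G: float, d: float) -> np.ndarray:
    """Noise-free model intensity; continuous and once-differentiable at Q1."""
    q = np.asarray(q, dtype=float)
    q1 = np.sqrt(1.5 * d) / R_G
    D = G * np.exp(-d / 2.0) * q1**d
    return np.where(q <= q1, G * np.exp(-(q**2) * R_G**2 / 3.0), D * q ** (-d))


def make_guinier_porod_curve(truth: GuinierPorodTruth) -> ScatteringCurve:
    """Sample the model on ``truth.q_grid`` with multiplicative Gaussian noise.

    The uncertainty column is ``noise_frac * I``; with ``noise_frac == 0`` the
    sigma column is omitted. If no grid point lies below the crossover Q1 the
    returned curve carries ``metadata['no_guinier_regime'] = True``.
    """
    rng = np.random.default_rng(truth.seed)
    ideal = guinier_porod_intensity(truth.q_grid, truth.G, truth.R_G, truth.d)
    if truth.noise_frac > 0:
        intensity = ideal * (1.0 + truth.noise_frac * rng.standard_normal(ideal.shape))
        sigma = truth.noise_frac * ideal
    else:
        intensity = ideal
        sigma = None
    meta = {"source": "guinier_porod_forward_model", "Q1": truth.Q1}
    if truth.q_grid[0] > truth.Q1:
        meta["no_guinier_regime"] = True
    return ScatteringCurve(q=truth.q_grid.copy(), I=intensity, sigma=sigma, metadata=meta)
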