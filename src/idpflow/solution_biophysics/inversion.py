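"""Regularized inverse Laplace transform of DLS correlograms.

A documented, reproducible stand-in for CONTIN-style analysis: non-negative
least squares with second-difference Tikhonov smoothing on a log-spaced
decay-time grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .correlogram import (CorrelogramTable, stokes_einstein_diffusion,
                          stokes_einstein_radius)
from .cumulant import HydroResult

__all__ = ["SizeDistribution", "regularized_inversion", "default_decay_grid"]

DEFAULT_ALPHA = 0.1


@dataclass(frozen=True)
class SizeDistribution:
    decay_times: np.ndarray    # s, the inversion grid
    weights: np.ndarray        # non-negative intensity weights
    radii_nm: np.ndarray       # grid mapped through Stokes-Einstein
    residual: float            # ||A w - g1||
    smoothness: float          # ||L w||
    alpha: float
    hydro: HydroResult         # intensity-weighted mean R_S

    def modes(self, min_weight_frac: float = 0.05) -> list[tuple[float, float]]:
        """(R_S_nm, weight) of local maxima of the weight vector.

        Maxima below ``min_weight_frac`` of the tallest mode are discarded.
        """
        w = self.weights
        out = []
        for i in range(len(w)):
            left = w[i - 1] if i > 0 else -np.inf
            right = w[i + 1] if i < len(w) - 1 else -np.inf
            if w[i] > 0 and w[i] >= left and w[i] > right:
                out.append((float(self.radii_nm[i]), float(w[i])))
        if out:
            wmax = max(m[1] for m in out)
            out = [m for m in out if m[1] >= min_weight_frac * wmax]
        return out


def default_decay_grid(corr: CorrelogramTable, n_nodes: int = 60) -> np.ndarray:
    """Log-spaced decay-time grid spanning the measured lag range."""
    return np.geomspace(corr.tau[0] / 3.0, corr.tau[-1] * 3.0, n_nodes)


def _second_difference(n: int) -> np.ndarray:
    L = np.zeros((n - 2, n))
    for i in range(n - 2):
        L[i, i: i + 3] = (1.0, -2.0, 1.0)
    return L


def regularized_inversion(corr: CorrelogramTable,
                          grid: np.ndarray | None = None,
                          alpha: float = DEFAULT_ALPHA) -> SizeDistribution:
    """Minimize ||g1 - A w||^2 + alpha ||L w||^2 subject to w >= 0.

    A[i, j] = exp(-tau_i / t_j); L is the second-difference operator. The
    field amplitude g1 is sqrt(max(g2 - 1, 0) / beta) with beta estimated
    from the shortest lags. Raises when the solution is identically zero
    (suggesting a smaller alpha).
    """
    if grid is None:
        grid = default_decay_grid(corr)
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 30:
        raise ValueError("decay-time grid needs >= 30 nodes")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be positive and increasing")

    beta = float(np.median(corr.g2m1[:3]))
    if beta <= 0:
        raise ValueError("correlogram amplitude is non-positive")
    g1 = np.sqrt(np.clip(corr.g2m1 / beta, 0.0, None))

    A = np.exp(-corr.tau[:, None] / grid[None, :])
    L = _second_difference(len(grid))
    A_aug = np.vstack([A, np.sqrt(alpha) * L])
    b_aug = np.concatenate([g1, np.zeros(L.shape[0])])
    w, _ = nnls(A_aug, b_aug)
    if not np.any(w > 0):
        raise ValueError("all-zero solution; try a smaller alpha")

    inst = corr.instrument
    q = inst.q
    # t = 1/(D q^2)  =>  D = 1/(t q^2)  =>  R_S = kB T t q^2 / (6 pi eta)
    D_grid = 1.0 / (grid * q**2)
    radii_nm = np.array([stokes_einstein_radius(D, inst.temperature_K,
                                                inst.viscosity_Pa_s) * 1e9
                         for D in D_grid])
    mean_rs = float(np.sum(w * radii_nm) / np.sum(w))
    mean_D = stokes_einstein_diffusion(mean_rs * 1e-9, inst.temperature_K,
                                       inst.viscosity_Pa_s)
    hydro = HydroResult(D=mean_D, R_S_nm=mean_rs, R_S_se_nm=float("nan"),
                        method="regularized")
    return SizeDistribution(decay_times=grid, weights=w, radii_nm=radii_nm,
                            residual=float(np.linalg.norm(A @ w - g1)),
                            smoothness=float(np.linalg.norm(L @ w)),
                            alpha=float(alpha), hydro=hydro)
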