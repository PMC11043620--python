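"""Dimensionless Kratky transform and peak diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .curves import ScatteringCurve

__all__ = ["KratkyCurve", "kratky_transform"]

_FLAT_TOL = 1e-9


@dataclass(frozen=True)
class KratkyCurve:
    x: np.ndarray          # q * R_G, dimensionless
    y: np.ndarray          # (q R_G)^2 * I / I0
    peak_x: float | None   # location of an interior maximum, or None


def kratky_transform(curve: ScatteringCurve, R_G: float, I0: float) -> KratkyCurve:
    """Dimensionless Kratky curve; a globule peaks near x = sqrt(3) ~ 1.73.

    Peak detection runs on a 3-point running median of y and reports an
    interior maximum only; flat curves (e.g. a pure q^-2 power law) yield
    ``peak_x = None``.
    """
    if R_G <= 0 or I0 <= 0:
        raise ValueError("R_G and I0 must be positive")
    x = curve.q * R_G
    y = x**2 * curve.I / I0
    smooth = median_filter(y, size=3, mode="nearest")
    span = smooth.max() - smooth.min()
    peak_x: float | None = None
    if span > _FLAT_TOL * max(abs(smooth.max()), 1e-300):
        i = int(np.argmax(smooth))
        if 0 < i < len(x) - 1:
            peak_x = float(x[i])
    return KratkyCurve(x=x, y=y, peak_x=peak_x)
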