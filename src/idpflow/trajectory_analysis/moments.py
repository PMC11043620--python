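"""Hydrophobic moment from helical-wheel projection (Eisenberg consensus scale)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EISENBERG_SCALE", "hydrophobic_moment", "HydrophobicMoment"]

# Eisenberg, Schwarz, Komaromy & Wall (1984) consensus hydrophobicity scale.
EISENBERG_SCALE: dict[str, float] = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}


@dataclass(frozen=True)
class HydrophobicMoment:
    magnitude: float          # per-residue normalized |mu_H|
    direction: float          # degrees, angle of the resultant in the wheel
    window_start: int         # 0-based offset of the evaluated window


def hydrophobic_moment(sequence: str, window: int | None = None,
                       periodicity: float = 100.0) -> list[HydrophobicMoment]:
    """Sliding-window hydrophobic moment of a one-letter residue string.

    Residue n contributes its scale value along angle n * ``periodicity``;
    the per-window resultant magnitude is divided by the window length.
    ``window=None`` evaluates the full sequence as a single window.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(EISENBERG_SCALE)
    if bad:
        raise ValueError(f"unknown residue code(s): {sorted(bad)}")
    if window is None:
        window = len(seq)
    if not 1 <= window <= len(seq):
        raise ValueError("window must be in [1, len(sequence)]")

    values = np.array([EISENBERG_SCALE[c] for c in seq])
    delta = np.deg2rad(periodicity)
    out = []
    for start in range(len(seq) - window + 1):
        h = values[start: start + window]
        angles = delta * np.arange(window)
        x = float(np.sum(h * np.cos(angles)))
        y = float(np.sum(h * np.sin(angles)))
        out.append(HydrophobicMoment(
            magnitude=float(np.hypot(x, y)) / window,
            direction=float(np.degrees(np.arctan2(y, x))),
            window_start=start))
    return out
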