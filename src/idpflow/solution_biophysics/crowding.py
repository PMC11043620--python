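"""Crowder volume fractions from partial specific volumes."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CrowderSpec", "volume_fraction", "BSA_PARTIAL_SPECIFIC_VOLUME"]

BSA_PARTIAL_SPECIFIC_VOLUME = 0.735   # mL/g


@dataclass(frozen=True)
class CrowderSpec:
    concentration_g_L: float
    partial_specific_volume_mL_g: float = BSA_PARTIAL_SPECIFIC_VOLUME

    def __post_init__(self) -> None:
        if self.concentration_g_L < 0:
            raise ValueError("concentration must be non-negative")
        if self.partial_specific_volume_mL_g <= 0:
            raise ValueError("partial specific volume must be positive")


def volume_fraction(spec: CrowderSpec) -> float:
    """phi in % v/v: phi = c * nu / 10 for c in g/L and nu in mL/g."""
    phi = spec.concentration_g_L * spec.partial_specific_volume_mL_g / 10.0
    if phi > 100.0:
        raise ValueError("volume fraction exceeds 100% v/v; check units")
    return phi
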