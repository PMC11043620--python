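"""Alpha-helix fraction from mean-residue ellipticity at 222 nm."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = ["CDConstants", "CDRecord", "cd_helicity"]


@dataclass(frozen=True)
class CDConstants:
    """Reference ellipticities in deg cm^2 dmol^-1.

    Defaults are the fixed two-point constants (coil at -2340; 100% helix at
    -32640, i.e. f_H = -(theta222 + 2340) / 30300). A chain-length-corrected
    helix reference theta_helix_inf * (1 - k / n_res) can be requested by
    passing ``n_res``.
    """

    theta_coil: float = -2340.0
    theta_helix: float = -32640.0
    theta_helix_inf: float = -39500.0
    chain_length_k: float = 2.57

    def helix_reference(self, n_res: int | None = None) -> float:
        if n_res is None:
            return self.theta_helix
        if n_res <= self.chain_length_k:
            raise ValueError("n_res too small for chain-length correction")
        return self.theta_helix_inf * (1.0 - self.chain_length_k / n_res)


@dataclass(frozen=True)
class CDRecord:
    theta_mrw_222: float
    f_helix: float          # clipped to [0, 1]
    f_helix_raw: float      # unclipped estimate
    theta_coil: float
    theta_helix: float


def cd_helicity(theta_mrw_222: float, constants: CDConstants = CDConstants(),
                n_res: int | None = None) -> CDRecord:
    """Linear two-point helix-fraction estimate from theta_MRW at 222 nm."""
    th_h = constants.helix_reference(n_res)
    th_c = constants.theta_coil
    raw = (theta_mrw_222 - th_c) / (th_h - th_c)
    f = min(max(raw, 0.0), 1.0)
    if f != raw:
        warnings.warn(f"helix fraction {raw:.3f} outside [0, 1]; clipped")
    return CDRecord(theta_mrw_222=float(theta_mrw_222), f_helix=float(f),
                    f_helix_raw=float(raw), theta_coil=th_c, theta_helix=th_h)
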