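"""Carboxyfluorescein leakage and electrolyte-leakage (LT50) analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import DoseResponseFit, dose_response_fit

__all__ = ["cf_leakage_percent", "lt50_from_electrolyte_leakage",
           "FreezingToleranceResult"]


def cf_leakage_percent(F_pre: float, F_post: float, F_triton: float) -> float:
    """100 * (F_post - F_pre) / (F_triton - F_pre), clipped to [0, 100].

    F_pre/F_post are fluorescence before/after the freeze-thaw treatment and
    F_triton after full dye release by detergent lysis.
    """
    if F_pre < 0:
        raise ValueError("fluorescence readings must be non-negative")
    if F_triton <= F_pre:
        raise ValueError("F_triton must exceed F_pre (full-release reference)")
    raw = 100.0 * (F_post - F_pre) / (F_triton - F_pre)
    return float(min(max(raw, 0.0), 100.0))


@dataclass(frozen=True)
class FreezingToleranceResult:
    lt50_C: float
    lt50_se_C: float
    fit: DoseResponseFit
    n_replicates: int
    genotype: str | None = None


def lt50_from_electrolyte_leakage(table: pd.DataFrame,
                                  control_temperature: float | None = None,
                                  ) -> dict[str, FreezingToleranceResult]:
    """LT50 per genotype from before/after-boiling conductivities.

    ``table`` columns: genotype, replicate, temperature, cond_before,
    cond_after. Raw leakage is 100 * cond_before / cond_after; the unfrozen
    control (rows at ``control_temperature``, default the warmest tested
    temperature) is removed by rescaling so the control maps to 0% and full
    release to 100%. A 4PL fit of leakage vs temperature yields LT50 as the
    location parameter; at the LT50 the leakage is half way between the
    asymptotes.
    """
    required = {"genotype", "replicate", "temperature", "cond_before", "cond_after"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = table.copy()
    if (df["cond_after"] <= 0).any():
        raise ValueError("cond_after must be positive")
    df["leakage"] = 100.0 * df["cond_before"] / df["cond_after"]

    if control_temperature is None:
        control_temperature = float(df["temperature"].max())
    out: dict[str, FreezingToleranceResult] = {}
    for gen, sub in df.groupby("genotype"):
        ctrl = sub[sub["temperature"] == control_temperature]
        if ctrl.empty:
            raise ValueError(f"no unfrozen control rows for genotype {gen!r}")
        if sub["temperature"].nunique() < 5:
            raise ValueError("need >= 5 temperatures per genotype")
        l0 = float(ctrl["leakage"].mean())
        if l0 >= 100.0:
            raise ValueError("control leakage is already complete")
        frozen = sub[sub["temperature"] != control_temperature]
        norm = 100.0 * (frozen["leakage"] - l0) / (100.0 - l0)
        fit = dose_response_fit(frozen["temperature"].to_numpy(),
                                norm.to_numpy())
        if not (frozen["temperature"].min() <= fit.logEC50
                <= frozen["temperature"].max()):
            pass  # flagged inside the fit already
        out[str(gen)] = FreezingToleranceResult(
            lt50_C=fit.logEC50, lt50_se_C=fit.se[2], fit=fit,
            n_replicates=int(sub["replicate"].nunique()), genotype=str(gen))
    return out
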