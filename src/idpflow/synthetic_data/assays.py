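"""Dose-response assay tables with replicate noise and known ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..protection_assays.dose_response import four_param_logistic

__all__ = ["AssayTruth", "make_assay_table", "make_conductivity_table",
           "ASSAY_KINDS"]

ASSAY_KINDS = ("cf_leakage", "electrolyte", "ldh_activity")


@dataclass(frozen=True)
class AssayTruth:
    low_x_asymptote: float
    high_x_asymptote: float
    logEC50: float
    x_values: tuple[float, ...]
    replicate_sd: float = 0.0
    n_replicates: int = 3
    seed: int = 0
    cycle_decay: float = 0.8     # per freeze-thaw cycle (ldh_activity only)
    n_cycles: int = 5

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")
        if not self.x_values:
            raise ValueError("x_values must be non-empty")


def make_assay_table(truth: AssayTruth, kind: str = "cf_leakage") -> pd.DataFrame:
    """Replicate observations of the Hill-slope-1 logistic plus Gaussian noise.

    Columns: x, replicate, y (and cycle for 'ldh_activity', where cycles
    0..n_cycles apply a multiplicative per-cycle decay to the response).
    """
    if kind not in ASSAY_KINDS:
        raise ValueError(f"kind must be one of {ASSAY_KINDS}")
    rng = np.random.default_rng(truth.seed)
    x = np.asarray(truth.x_values, dtype=float)
    mean = four_param_logistic(x, truth.low_x_asymptote,
                               truth.high_x_asymptote, truth.logEC50)
    rows = []
    cycles = range(truth.n_cycles + 1) if kind == "ldh_activity" else (None,)
    for cycle in cycles:
        scale = truth.cycle_decay**cycle if cycle is not None else 1.0
        for rep in range(1, truth.n_replicates + 1):
            noise = (truth.replicate_sd * rng.standard_normal(x.shape)
                     if truth.replicate_sd > 0 else np.zeros_like(x))
            y = mean * scale + noise
            for xi, yi in zip(x, y):
                row = {"x": xi, "replicate": rep, "y": yi}
                if cycle is not None:
                    row["cycle"] = cycle
                rows.append(row)
    return pd.DataFrame(rows)


def make_conductivity_table(truth: AssayTruth, genotype: str = "WT",
                            control_temperature: float = 4.0,
                            control_leakage: float = 5.0) -> pd.DataFrame:
    """Per-replicate before/after-boiling conductivities vs temperature.

    ``truth.x_values`` are the freeze temperatures (degC) and ``truth.logEC50``
    is the LT50. The logistic gives normalized leakage (percent of span);
    raw leakage interpolates between the unfrozen-control level and full
    release, so the downstream control normalization inverts exactly.
    Columns: genotype, replicate, temperature, cond_before, cond_after.
    """
    rng = np.random.default_rng(truth.seed)
    temps = np.asarray(truth.x_values, dtype=float)
    if control_temperature <= temps.max():
        raise ValueError("control temperature must exceed all freeze temperatures")
    norm = four_param_logistic(temps, truth.low_x_asymptote,
                               truth.high_x_asymptote, truth.logEC50)
    raw = control_leakage + (100.0 - control_leakage) * norm / 100.0
    rows = []
    cond_after = 100.0
    for rep in range(1, truth.n_replicates + 1):
        noise = (truth.replicate_sd * rng.standard_normal(temps.shape)
                 if truth.replicate_sd > 0 else np.zeros_like(temps))
        for t, leak in zip(temps, np.clip(raw + noise, 0.0, 100.0)):
            rows.append({"genotype": genotype, "replicate": rep,
                         "temperature": t, "cond_before": leak,
                         "cond_after": cond_after})
        rows.append({"genotype": genotype, "replicate": rep,
                     "temperature": control_temperature,
                     "cond_before": control_leakage, "cond_after": cond_after})
    return pd.DataFrame(rows)
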