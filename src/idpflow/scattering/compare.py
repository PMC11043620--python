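"""Condition-wise comparison tables for size/compaction trends."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .guinier import GuinierResult
from .guinier_porod import GuinierPorodResult

__all__ = ["compare_conditions"]


def _monotone_flags(values: np.ndarray) -> list[str]:
    """'up'/'down'/'flat' per step relative to the previous condition."""
    flags = [""]
    for prev, cur in zip(values[:-1], values[1:]):
        flags.append("up" if cur > prev else ("down" if cur < prev else "flat"))
    return flags


def compare_conditions(
    results: list[tuple[object, GuinierResult, GuinierPorodResult]],
) -> pd.DataFrame:
    """Tabulate R_G and d against an ordered list of conditions.

    One row per condition with fitted values and SEs, plus step-wise
    monotonicity flags (empty for a single condition).
    """
    if not results:
        raise ValueError("need at least one condition")
    rows = []
    for cond, gres, gpres in results:
        rows.append({
            "condition": cond,
            "R_G": gres.R_G,
            "R_G_se": gres.R_G_se,
            "qmax_RG": gres.qmax_RG,
            "d": gpres.d,
            "R_G_gp": gpres.R_G,
            "gp_residual": gpres.residual,
        })
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        table["R_G_trend"] = _monotone_flags(table["R_G"].to_numpy())
        table["d_trend"] = _monotone_flags(table["d"].to_numpy())
    else:
        table["R_G_trend"] = ""
        table["d_trend"] = ""
    return table
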