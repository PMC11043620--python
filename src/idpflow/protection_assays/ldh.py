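"""LDH activity retention normalized to unfrozen no-protectant controls."""

from __future__ import annotations

import pandas as pd

__all__ = ["ldh_retention"]


def ldh_retention(activities: pd.DataFrame, unfrozen_control: float) -> pd.DataFrame:
    """Normalize activities by the unfrozen no-protectant control.

    ``activities`` columns: variant, occupancy, cycle, and either an
    ``activity`` column of replicate measurements (several rows per group)
    or a single value per (variant, occupancy, cycle). Returns per-group
    mean retention with SE and replicate count.
    """
    if unfrozen_control <= 0:
        raise ValueError("unfrozen control activity must be positive")
    required = {"variant", "occupancy", "cycle", "activity"}
    missing = required - set(activities.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = activities.copy()
    df["retention"] = df["activity"] / unfrozen_control
    grouped = df.groupby(["variant", "occupancy", "cycle"])["retention"]
    out = grouped.agg(retention="mean", retention_se="sem", n="count").reset_index()
    out["retention_se"] = out["retention_se"].fillna(0.0)
    return out
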