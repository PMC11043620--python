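"""Scattering curve container and ASCII (.dat dialect) I/O.

q is stored in Å⁻¹ (definition q = 4*pi/lambda * sin(theta/2)); files in
nm⁻¹ are converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ScatteringCurve", "read_scattering_file", "write_scattering_file"]


@dataclass
class ScatteringCurve:
    q: np.ndarray                       # Å⁻¹, strictly increasing
    I: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")

    def __len__(self) -> int:
        return len(self.q)

    def scaled(self, factor: float) -> "ScatteringCurve":
        """Curve with I (and sigma) multiplied by ``factor``."""
        sig = None if self.sigma is None else self.sigma * factor
        return ScatteringCurve(self.q.copy(), self.I * factor, sig, dict(self.metadata))


def read_scattering_file(path: str | Path, units: str = "A^-1") -> ScatteringCurve:
    """Read a whitespace/comma-delimited ASCII curve (q, I[, sigma]).

    '#'-prefixed lines and blank lines are skipped. ``units`` is either
    'A^-1' (default) or 'nm^-1'; nm⁻¹ values are divided by 10. Rows with
    non-positive intensity are dropped with a warning.
    """
    if units not in ("A^-1", "nm^-1"):
        raise ValueError("units must be 'A^-1' or 'nm^-1'")
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            rows.append([float(p) for p in parts[:3]])
    if not rows:
        raise ValueError(f"no data rows in {path}")
    ncol = min(len(r) for r in rows)
    if ncol < 2:
        raise ValueError(f"need at least 2 columns in {path}")
    data = np.array([r[:ncol] for r in rows], dtype=float)
    keep = data[:, 1] > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} rows with non-positive intensity")
        data = data[keep]
    q = data[:, 0]
    if units == "nm^-1":
        q = q / 10.0
    if np.any(np.diff(q) <= 0):
        raise ValueError("q column is not strictly increasing")
    sigma = data[:, 2] if ncol >= 3 else None
    return ScatteringCurve(q, data[:, 1], sigma,
                           metadata={"path": str(path), "dropped_rows": n_dropped})


def write_scattering_file(curve: ScatteringCurve, path: str | Path) -> None:
    """Write a 3-column (or 2-column) ASCII curve with a '#' header."""
    with open(path, "w") as fh:
        fh.write("# q [A^-1]  I  sigma\n" if curve.sigma is not None
                 else "# q [A^-1]  I\n")
        for i in range(len(curve)):
            if curve.sigma is not None:
                fh.write(f"{curve.q[i]:.9e} {curve.I[i]:.9e} {curve.sigma[i]:.9e}\n")
            else:
                fh.write(f"{curve.q[i]:.9e} {curve.I[i]:.9e}\n")
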