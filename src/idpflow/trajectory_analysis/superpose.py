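"""Rigid-body superposition (Kabsch) and RMSD time series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import BACKBONE_ATOMS, Structure, Trajectory

__all__ = ["SuperposeResult", "kabsch_superpose", "rmsd_timeseries"]


@dataclass(frozen=True)
class SuperposeResult:
    rotation: np.ndarray      # (3, 3) proper rotation, det = +1
    translation: np.ndarray   # applied after rotation
    rmsd: float               # Å, at the optimum


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperposeResult:
    if mobile.shape != reference.shape:
        raise ValueError("selections must map 1:1 between structures")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms for superposition")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    # smallest two singular values ~0 => collinear selection
    if S[1] < 1e-8 * max(S[0], 1e-300):
        raise ValueError("selection is collinear; superposition is degenerate")
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])        # reflection guard
    R = Vt.T @ D @ U.T
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))
    t = rc - R @ mc
    return SuperposeResult(rotation=R, translation=t, rmsd=rmsd)


def kabsch_superpose(mobile: Structure, reference: Structure,
                     atom_selection: tuple[str, ...] = BACKBONE_ATOMS) -> SuperposeResult:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    The returned RMSD is the global minimum over proper rigid transforms
    (rotation determinant +1; mirror images are not matched).
    """
    m_mask = mobile.topology.select(atom_names=atom_selection, protein_only=True)
    r_mask = reference.topology.select(atom_names=atom_selection, protein_only=True)
    if m_mask.sum() != r_mask.sum():
        raise ValueError("atom selections differ in size between structures")
    return _kabsch(mobile.coords[m_mask], reference.coords[r_mask])


def rmsd_timeseries(traj: Trajectory, reference: Structure,
                    atom_selection: tuple[str, ...] = BACKBONE_ATOMS) -> np.ndarray:
    """Per-frame backbone RMSD to ``reference``, each frame independently
    superposed."""
    mask = traj.topology.select(atom_names=atom_selection, protein_only=True)
    ref_mask = reference.topology.select(atom_names=atom_selection, protein_only=True)
    if mask.sum() != ref_mask.sum():
        raise ValueError("reference topology does not match trajectory selection")
    ref = reference.coords[ref_mask]
    return np.array([_kabsch(traj.coords[f][mask], ref).rmsd
                     for f in range(traj.n_frames)])
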