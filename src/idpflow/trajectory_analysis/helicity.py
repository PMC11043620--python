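"""Helix/coil assignment from the backbone i -> i+4 hydrogen-bond pattern.

This is the alpha-helix criterion itself (O_i ... H-N_{i+4}) rather than the
full eight-class assignment: two consecutive helical turns - bonds starting
at residues i-1 and i - mark residues i..i+3 helical, so every assigned run
is at least four residues long and a lone accidental bond never counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..geometry import angle_deg
from .hbonds import HBondCriteria
from .structure import Trajectory

__all__ = ["HelicityTimeline", "assign_helicity"]


@dataclass(frozen=True)
class HelicityTimeline:
    helical: np.ndarray          # (n_frames, n_res) boolean indicator
    helix_fraction: np.ndarray   # (n_frames,) helical residues / total
    residue_ratio: np.ndarray    # (n_res,) frame-averaged per-residue helicity
    residues: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if np.any(self.helix_fraction < 0) or np.any(self.helix_fraction > 1):
            raise ValueError("helix fractions must lie in [0, 1]")

    @property
    def coil_fraction(self) -> np.ndarray:
        return 1.0 - self.helix_fraction


def _chain_atom_index(traj: Trajectory, cid: str, name: str) -> dict[int, int]:
    top = traj.topology
    mask = (top.chain_ids == cid) & (top.atom_names == name) & ~top.is_solvent
    return {int(r): int(a) for r, a in zip(top.res_indices[mask], np.flatnonzero(mask))}


def assign_helicity(traj: Trajectory,
                    criteria: HBondCriteria = HBondCriteria()) -> HelicityTimeline:
    """Per-residue, per-frame helix indicator plus helix/coil fractions."""
    top = traj.topology
    residues: list[tuple[str, int]] = []
    chain_maps = []
    for cid in top.chains():
        maps = {nm: _chain_atom_index(traj, cid, nm) for nm in ("N", "H", "O")}
        res_ids = sorted(maps["N"])
        if len(res_ids) < 5:
            warnings.warn(f"chain {cid!r} shorter than 5 residues; assigned all-coil")
        residues.extend((cid, r) for r in res_ids)
        chain_maps.append((cid, res_ids, maps))

    n_res = len(residues)
    helical = np.zeros((traj.n_frames, n_res), dtype=bool)
    d_max = criteria.max_donor_acceptor_distance

    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        offset = 0
        for cid, res_ids, maps in chain_maps:
            m = len(res_ids)
            bond = np.zeros(m, dtype=bool)
            for k, r in enumerate(res_ids):
                o_i = maps["O"].get(r)
                n_j = maps["N"].get(r + 4)
                h_j = maps["H"].get(r + 4)
                if o_i is None or n_j is None or h_j is None:
                    continue
                if np.linalg.norm(xyz[n_j] - xyz[o_i]) > d_max:
                    continue
                if angle_deg(xyz[n_j], xyz[h_j], xyz[o_i]) <= criteria.min_angle:
                    continue
                bond[k] = True
            helix = np.zeros(m, dtype=bool)
            for k in range(1, m):
                if bond[k - 1] and bond[k]:
                    helix[k: min(k + 4, m)] = True
            helical[f, offset: offset + m] = helix
            offset += m

    frac = helical.mean(axis=1) if n_res else np.zeros(traj.n_frames)
    ratio = helical.mean(axis=0) if traj.n_frames else np.zeros(n_res)
    return HelicityTimeline(helical=helical, helix_fraction=frac,
                            residue_ratio=ratio, residues=tuple(residues))
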