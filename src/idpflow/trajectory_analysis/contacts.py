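"""Residue-residue contact probability maps pooled over replicates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Trajectory

__all__ = ["ContactMap", "contact_probability_map", "top_contacts"]

DEFAULT_CONTACT_CUTOFF = 3.5   # Å, closest heavy-atom distance
_ADJACENT_EXCLUSION = 2        # |i-j| <= 2 within a chain is trivially close


@dataclass(frozen=True)
class ContactMap:
    """Symmetric matrix of contact probabilities over residue pairs.

    Residues are listed as (chain_id, 1-based index); ``concat_index``
    additionally numbers them consecutively across chains (the 1..N dimer
    convention used for whole-complex maps).
    """

    probabilities: np.ndarray         # (n_res, n_res), values in [0, 1]
    residues: tuple[tuple[str, int], ...]
    cutoff: float
    n_frames: int

    def __post_init__(self) -> None:
        P = self.probabilities
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("probability matrix must be square")
        if not np.allclose(P, P.T):
            raise ValueError("probability matrix must be symmetric")
        if P.size and (P.min() < 0 or P.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def concat_index(self) -> dict[tuple[str, int], int]:
        return {res: i + 1 for i, res in enumerate(self.residues)}

    def is_intra(self, i: int, j: int) -> bool:
        return self.residues[i][0] == self.residues[j][0]


def _residue_atom_groups(traj: Trajectory):
    top = traj.topology
    heavy = (~top.is_solvent) & (top.elements != "H")
    residues: list[tuple[str, int]] = []
    groups: list[np.ndarray] = []
    for cid in top.chains():
        cmask = heavy & (top.chain_ids == cid)
        for r in np.unique(top.res_indices[cmask]):
            residues.append((cid, int(r)))
            groups.append(np.flatnonzero(cmask & (top.res_indices == r)))
    return residues, groups


def contact_probability_map(trajs: list[Trajectory],
                            cutoff: float = DEFAULT_CONTACT_CUTOFF) -> ContactMap:
    """P_ij = fraction of pooled frames with min heavy-atom distance <= cutoff.

    All replicate trajectories are pooled with equal frame weight and must
    share a topology (same residue list).
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    residues, groups = _residue_atom_groups(trajs[0])
    for t in trajs[1:]:
        res_t, _ = _residue_atom_groups(t)
        if res_t != residues:
            raise ValueError("all trajectories must share the same residue topology")
    n = len(residues)
    counts = np.zeros((n, n))
    total = 0
    for traj in trajs:
        for f in range(traj.n_frames):
            xyz = traj.coords[f]
            total += 1
            for i in range(n):
                gi = xyz[groups[i]]
                for j in range(i + 1, n):
                    gj = xyz[groups[j]]
                    d2 = np.sum((gi[:, None, :] - gj[None, :, :]) ** 2, axis=-1)
                    if d2.min() <= cutoff**2:
                        counts[i, j] += 1
    counts += counts.T
    P = counts / total
    np.fill_diagonal(P, 0.0)
    return ContactMap(P, tuple(residues), float(cutoff), total)


def top_contacts(cmap: ContactMap, threshold: float = 0.75):
    """Pairs with P >= threshold, high to low, ties by (i, j) ascending.

    Sequence-adjacent pairs (|i - j| <= 2 within one chain) are excluded.
    Each entry is ((chain_i, idx_i), (chain_j, idx_j), P, 'intra'|'inter').
    """
    n = len(cmap.residues)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            ci, ri = cmap.residues[i]
            cj, rj = cmap.residues[j]
            if ci == cj and abs(ri - rj) <= _ADJACENT_EXCLUSION:
                continue
            p = cmap.probabilities[i, j]
            if p >= threshold:
                rows.append((cmap.residues[i], cmap.residues[j], float(p),
                             "intra" if ci == cj else "inter"))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return rows
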