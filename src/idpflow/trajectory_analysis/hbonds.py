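"""Geometric hydrogen-bond detection and per-frame statistics.

A donor is an N or O atom with at least one covalently attached hydrogen
(H within 1.25 Å in the same residue); acceptors are O atoms and N atoms
without attached hydrogens. A triplet counts when the donor-acceptor
distance is <= ``max_donor_acceptor_distance`` and the donor-H-acceptor
angle is strictly greater than ``min_angle``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ..geometry import BOND_N_H, unit
from .structure import Structure, Topology, Trajectory

__all__ = ["HBondCriteria", "HBond", "detect_hbonds", "hbond_timeseries",
           "place_amide_hydrogens", "MissingHydrogensError"]

_COVALENT_H_CUTOFF = 1.25


class MissingHydrogensError(ValueError):
    """Raised when donors carry no hydrogens; place them geometrically first
    (see :func:`place_amide_hydrogens`)."""


@dataclass(frozen=True)
class HBondCriteria:
    max_donor_acceptor_distance: float = 3.5   # Å
    min_angle: float = 120.0                   # degrees, strict

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 < self.min_angle < 180.0:
            raise ValueError("angle cutoff must be in (0, 180)")


@dataclass(frozen=True)
class HBond:
    donor: int      # atom indices into the topology
    hydrogen: int
    acceptor: int


def _donors_acceptors(top: Topology, coords: np.ndarray):
    """Return (donor_idx, hydrogen_idx) pairs and acceptor indices."""
    heavy_dn = np.flatnonzero(np.isin(top.elements, ["N", "O"]))
    h_idx = np.flatnonzero(top.elements == "H")
    pairs = []
    has_h = np.zeros(top.n_atoms, dtype=bool)
    if len(h_idx):
        tree = cKDTree(coords[h_idx])
        for a in heavy_dn:
            for jh in tree.query_ball_point(coords[a], _COVALENT_H_CUTOFF):
                h = h_idx[jh]
                same_res = (top.chain_ids[h] == top.chain_ids[a]
                            and top.res_indices[h] == top.res_indices[a])
                if same_res:
                    pairs.append((a, h))
                    has_h[a] = True
    acceptors = np.flatnonzero(
        (top.elements == "O") | ((top.elements == "N") & ~has_h))
    return pairs, acceptors


def detect_hbonds(frame: Structure, criteria: HBondCriteria = HBondCriteria()) -> list[HBond]:
    """All (donor, hydrogen, acceptor) triplets meeting the criteria.

    Same-residue pairs are excluded. Raises :class:`MissingHydrogensError`
    when potential N donors exist but no hydrogens are present at all.
    """
    top = frame.topology
    coords = frame.coords
    pairs, acceptors = _donors_acceptors(top, coords)
    if not pairs:
        if np.any(top.elements == "N"):
            raise MissingHydrogensError(
                "no donor hydrogens found; add amide hydrogens geometrically "
                "with place_amide_hydrogens() before H-bond detection")
        return []
    acc_tree = cKDTree(coords[acceptors])
    out: list[HBond] = []
    cos_min = np.cos(np.deg2rad(criteria.min_angle))
    for d, h in pairs:
        for ja in acc_tree.query_ball_point(coords[d], criteria.max_donor_acceptor_distance):
            a = acceptors[ja]
            if a == d:
                continue
            if (top.chain_ids[a] == top.chain_ids[d]
                    and top.res_indices[a] == top.res_indices[d]):
                continue
            u = unit(coords[d] - coords[h])
            v = unit(coords[a] - coords[h])
            # angle > min_angle  <=>  cos(angle) < cos(min_angle)
            if float(u @ v) < cos_min:
                out.append(HBond(int(d), int(h), int(a)))
    return out


def hbond_timeseries(traj: Trajectory, criteria: HBondCriteria = HBondCriteria()):
    """Per-frame H-bond counts split into protein-protein and protein-water.

    Classification uses the solvent flag of the two heavy partners; a bond
    with at least one solvent partner counts as protein-water unless both
    partners are solvent (solvent-solvent bonds are ignored).
    Returns (protein_protein, protein_water) integer arrays.
    """
    solv = traj.topology.is_solvent
    pp = np.zeros(traj.n_frames, dtype=int)
    pw = np.zeros(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        for hb in detect_hbonds(traj.frame(f), criteria):
            sd, sa = solv[hb.donor], solv[hb.acceptor]
            if sd and sa:
                continue
            if sd or sa:
                pw[f] += 1
            else:
                pp[f] += 1
    return pp, pw


def place_amide_hydrogens(struct: Structure) -> Structure:
    """Return a copy with missing backbone amide hydrogens added.

    H is placed on the bisector of the C(i-1)-N(i) and CA(i)-N(i) directions,
    1.01 Å from N, for every protein residue after the first in each chain.
    """
    top = struct.topology
    coords = struct.coords
    new_rows = []
    for cid in top.chains():
        cmask = (top.chain_ids == cid) & ~top.is_solvent
        residues = np.unique(top.res_indices[cmask])
        for r in residues[1:]:
            rmask = cmask & (top.res_indices == r)
            if np.any(top.atom_names[rmask] == "H"):
                continue
            try:
                n_i = np.flatnonzero(rmask & (top.atom_names == "N"))[0]
                ca_i = np.flatnonzero(rmask & (top.atom_names == "CA"))[0]
                c_prev = np.flatnonzero(cmask & (top.res_indices == r - 1)
                                        & (top.atom_names == "C"))[0]
            except IndexError:
                continue
            bis = unit(coords[c_prev] - coords[n_i]) + unit(coords[ca_i] - coords[n_i])
            h = coords[n_i] - BOND_N_H * unit(bis)
            new_rows.append((n_i, h, cid, r))
    if not new_rows:
        return Structure(top, coords.copy())
    # insert each H directly after its N to keep residues contiguous
    order = np.argsort([row[0] for row in new_rows])
    insert_at = [new_rows[i][0] + 1 for i in order]
    arrays = {
        "chain_ids": list(top.chain_ids), "res_indices": list(top.res_indices),
        "res_names": list(top.res_names), "atom_names": list(top.atom_names),
        "elements": list(top.elements), "is_solvent": list(top.is_solvent),
    }
    coord_list = list(coords)
    for off, i in enumerate(order):
        n_i, h, cid, r = new_rows[i]
        pos = insert_at[i] + off
        coord_list.insert(pos, h)
        arrays["chain_ids"].insert(pos, cid)
        arrays["res_indices"].insert(pos, r)
        arrays["res_names"].insert(pos, top.res_names[n_i])
        arrays["atom_names"].insert(pos, "H")
        arrays["elements"].insert(pos, "H")
        arrays["is_solvent"].insert(pos, False)
    new_top = Topology(np.array(arrays["chain_ids"]), np.array(arrays["res_indices"]),
                       np.array(arrays["res_names"]), np.array(arrays["atom_names"]),
                       np.array(arrays["elements"]), np.array(arrays["is_solvent"]))
    return Structure(new_top, np.asarray(coord_list))
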