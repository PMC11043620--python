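"""Coordinate/topology containers and multi-model PDB I/O."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Topology", "Structure", "Trajectory", "read_pdb", "write_pdb"]


@dataclass
class Topology:
    """Per-atom labels shared by every frame of a trajectory.

    Residue indices are 1-based and contiguous within each chain.
    """

    chain_ids: np.ndarray          # (n_atoms,) '<U2'
    res_indices: np.ndarray        # (n_atoms,) int
    res_names: np.ndarray          # (n_atoms,) '<U4'
    atom_names: np.ndarray         # (n_atoms,) '<U4'
    elements: np.ndarray           # (n_atoms,) '<U2'
    is_solvent: np.ndarray         # (n_atoms,) bool

    def __post_init__(self) -> None:
        self.chain_ids = np.asarray(self.chain_ids)
        self.res_indices = np.asarray(self.res_indices, dtype=int)
        self.res_names = np.asarray(self.res_names)
        self.atom_names = np.asarray(self.atom_names)
        self.elements = np.asarray(self.elements)
        self.is_solvent = np.asarray(self.is_solvent, dtype=bool)
        n = len(self.atom_names)
        for arr in (self.chain_ids, self.res_indices, self.res_names,
                    self.elements, self.is_solvent):
            if len(arr) != n:
                raise ValueError("topology arrays must share one length")
        for cid in np.unique(self.chain_ids[~self.is_solvent]):
            idx = np.unique(self.res_indices[(self.chain_ids == cid) & ~self.is_solvent])
            if len(idx) and not np.array_equal(idx, np.arange(idx[0], idx[0] + len(idx))):
                raise ValueError(f"residue indices not contiguous in chain {cid!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def select(self, *, atom_names=None, chain_id=None, protein_only: bool = False) -> np.ndarray:
        """Boolean mask over atoms."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if atom_names is not None:
            mask &= np.isin(self.atom_names, list(atom_names))
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        if protein_only:
            mask &= ~self.is_solvent
        return mask

    def chains(self) -> list[str]:
        """Protein chain ids in order of first appearance."""
        seen: list[str] = []
        for cid, solv in zip(self.chain_ids, self.is_solvent):
            if not solv and cid not in seen:
                seen.append(str(cid))
        return seen


BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Structure:
    """A single frame: topology plus coordinates in Å."""

    topology: Topology
    coords: np.ndarray  # (n_atoms, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError("coords shape does not match topology")


@dataclass
class Trajectory:
    """An ordered stack of frames over one topology."""

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("coords must be (n_frames, n_atoms, 3) matching topology")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return Structure(self.topology, self.coords[i])


_SOLVENT_RESNAMES = {"HOH", "WAT", "SOL", "TIP", "T4P"}


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name.lstrip("0123456789")
    return name[:1].upper()


def write_pdb(traj: Trajectory | Structure, path: str | Path | io.TextIOBase) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL records)."""
    if isinstance(traj, Structure):
        traj = Trajectory(traj.topology, traj.coords[None, :, :])
    top = traj.topology

    def _emit(fh) -> None:
        for m in range(traj.n_frames):
            fh.write(f"MODEL     {m + 1:4d}\n")
            serial = 0
            xyz = traj.coords[m]
            for a in range(top.n_atoms):
                if np.isnan(xyz[a]).any():
                    continue
                serial += 1
                name = top.atom_names[a]
                pdb_name = f" {name:<3s}" if len(name) < 4 else name
                record = "HETATM" if top.is_solvent[a] and top.res_names[a] not in ("HOH",) else "ATOM  "
                fh.write(
                    f"{record}{serial % 100000:5d} {pdb_name:<4s} "
                    f"{top.res_names[a]:<3s} {str(top.chain_ids[a])[:1]}"
                    f"{top.res_indices[a] % 10000:4d}    "
                    f"{xyz[a, 0]:8.3f}{xyz[a, 1]:8.3f}{xyz[a, 2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {top.elements[a]:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")

    if isinstance(path, (str, Path)):
        with open(path, "w") as fh:
            _emit(fh)
    else:
        _emit(path)


def read_pdb(path: str | Path) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    Uses Biopython's parser; all models must share the same atom list.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no models found in {path}")

    chain_ids, res_idx, res_names, atom_names, elements, solvent = [], [], [], [], [], []
    frames = []
    for im, model in enumerate(models):
        coords = []
        keys = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    coords.append(atom.coord)
                    keys.append((chain.id, residue.id[1], residue.resname.strip(),
                                 atom.get_name()))
                    if im == 0:
                        chain_ids.append(chain.id)
                        res_idx.append(residue.id[1])
                        rn = residue.resname.strip()
                        res_names.append(rn)
                        atom_names.append(atom.get_name())
                        el = (atom.element or "").strip() or _guess_element(atom.get_name())
                        elements.append(el)
                        solvent.append(rn in _SOLVENT_RESNAMES)
        frames.append(np.asarray(coords, dtype=float))
    n0 = len(frames[0])
    if any(len(f) != n0 for f in frames):
        raise ValueError("models differ in atom count")
    top = Topology(np.array(chain_ids), np.array(res_idx), np.array(res_names),
                   np.array(atom_names), np.array(elements), np.array(solvent))
    return Trajectory(top, np.stack(frames))
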