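"""Helix and helix-coil trajectory fixtures with known ground truth.

The trajectory generator erodes an initially fully helical chain from both
termini: at every frame the outermost helical residue on each side turns to
coil with a fixed probability, never invading a protected core span. Coil
residues get dihedrals redrawn each frame from the broad beta/PPII basin so
that a hydrogen-bond based helicity detector cleanly separates the classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..geometry import ALPHA_PHI, ALPHA_PSI, build_backbone, principal_axis_align
from ..trajectory_analysis.structure import Structure, Topology, Trajectory

__all__ = ["HelixCoilParams", "make_ideal_helix", "make_helix_coil_trajectory",
           "make_chain"]

_COIL_PHI = (-180.0, -60.0)
_COIL_PSI = (60.0, 180.0)


@dataclass(frozen=True)
class HelixCoilParams:
    n_res: int
    n_frames: int
    n_chains: int = 1
    unravel_rate: float = 0.1
    core_span: tuple[int, int] = (1, 1)   # 1-based inclusive, guaranteed helical
    seed: int = 0
    chain_separation: float = 10.0         # inter-axis distance for dimers, Å
    n_waters: int = 0                      # optional explicit water shell

    def __post_init__(self) -> None:
        if self.n_res < 5:
            raise ValueError("n_res must be >= 5")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_chains not in (1, 2):
            raise ValueError("n_chains must be 1 or 2")
        if not 0.0 <= self.unravel_rate <= 1.0:
            raise ValueError("unravel_rate must be in [0, 1]")
        lo, hi = self.core_span
        if not (1 <= lo <= hi <= self.n_res):
            raise ValueError("core_span must lie within [1, n_res]")
        if self.n_waters < 0:
            raise ValueError("n_waters must be >= 0")


def _chain_topology(n_res: int, chain_id: str, res_name: str = "ALA") -> Topology:
    names = ["N", "H", "CA", "C", "O"]
    elements = {"N": "N", "H": "H", "CA": "C", "C": "C", "O": "O"}
    atom_names, res_idx = [], []
    for r in range(1, n_res + 1):
        for nm in names:
            if r == 1 and nm == "H":   # no amide H on the first residue
                continue
            atom_names.append(nm)
            res_idx.append(r)
    n = len(atom_names)
    return Topology(
        chain_ids=np.full(n, chain_id),
        res_indices=np.array(res_idx),
        res_names=np.full(n, res_name),
        atom_names=np.array(atom_names),
        elements=np.array([elements[a] for a in atom_names]),
        is_solvent=np.zeros(n, dtype=bool),
    )


def _assemble_chain_coords(bb: dict[str, np.ndarray]) -> np.ndarray:
    """Interleave backbone arrays into the topology atom order."""
    n_res = bb["N"].shape[0]
    rows = []
    for r in range(n_res):
        rows.append(bb["N"][r])
        if r > 0:
            rows.append(bb["H"][r])
        rows.append(bb["CA"][r])
        rows.append(bb["C"][r])
        rows.append(bb["O"][r])
    return np.asarray(rows)


def make_ideal_helix(n_res: int, chain_id: str = "A") -> Structure:
    """Backbone (N, H, CA, C, O) of a canonical alpha-helix.

    phi = -57 deg, psi = -47 deg, ideal bond geometry; the helix axis is
    aligned with z. Deterministic: two calls with the same arguments return
    identical coordinates.
    """
    if n_res < 5:
        raise ValueError("n_res must be >= 5")
    bb = build_backbone(np.full(n_res, ALPHA_PHI), np.full(n_res, ALPHA_PSI))
    coords = _assemble_chain_coords(bb)
    # align on CA positions so the rise is read off the z coordinate
    top = _chain_topology(n_res, chain_id)
    ca_rows = top.atom_names == "CA"
    coords = principal_axis_align(coords, guide=coords[ca_rows])
    return Structure(top, coords)


def make_chain(phi, psi, chain_id: str = "A") -> Structure:
    """Backbone chain with arbitrary per-residue (phi, psi) torsions (deg)."""
    phi = np.asarray(phi, dtype=float)
    bb = build_backbone(phi, np.asarray(psi, dtype=float))
    return Structure(_chain_topology(len(phi), chain_id),
                     _assemble_chain_coords(bb))


def _water_topology(n_waters: int) -> Topology:
    atom_names = np.tile(["O", "H1", "H2"], n_waters)
    res_idx = np.repeat(np.arange(1, n_waters + 1), 3)
    n = 3 * n_waters
    return Topology(
        chain_ids=np.full(n, "W"),
        res_indices=res_idx,
        res_names=np.full(n, "HOH"),
        atom_names=atom_names,
        elements=np.tile(["O", "H", "H"], n_waters),
        is_solvent=np.ones(n, dtype=bool),
    )


def _water_coords(rng: np.random.Generator, n_waters: int, box: float) -> np.ndarray:
    """Rigid TIP3P-like waters at random positions/orientations in a cube."""
    o = rng.uniform(-box / 2, box / 2, size=(n_waters, 3))
    coords = np.empty((3 * n_waters, 3))
    for i in range(n_waters):
        # random orthonormal pair for the two O-H bonds (104.5 deg apart)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        v = rng.normal(size=3)
        v -= u * (u @ v)
        v /= np.linalg.norm(v)
        h1 = u
        h2 = np.cos(np.deg2rad(104.5)) * u + np.sin(np.deg2rad(104.5)) * v
        coords[3 * i] = o[i]
        coords[3 * i + 1] = o[i] + 0.9572 * h1
        coords[3 * i + 2] = o[i] + 0.9572 * h2
    return coords


def _concat_topologies(tops: list[Topology]) -> Topology:
    return Topology(
        np.concatenate([t.chain_ids for t in tops]),
        np.concatenate([t.res_indices for t in tops]),
        np.concatenate([t.res_names for t in tops]),
        np.concatenate([t.atom_names for t in tops]),
        np.concatenate([t.elements for t in tops]),
        np.concatenate([t.is_solvent for t in tops]),
    )


def make_helix_coil_trajectory(params: HelixCoilParams) -> Trajectory:
    """Multi-frame trajectory whose helical segment shrinks from the termini.

    Frame 0 is fully helical. At each subsequent frame the left and right
    helix boundaries each advance toward ``core_span`` with probability
    ``unravel_rate``. Coil residues are rebuilt every frame with dihedrals
    drawn uniformly from the beta/PPII basin. For ``n_chains == 2`` the
    second chain is rotated 180 deg (antiparallel) and offset by
    ``chain_separation`` Å. The per-frame, per-chain ground-truth helical
    spans are stored in ``metadata['helical_spans']``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_res
    lo, hi = params.core_span

    tops = [_chain_topology(n, cid) for cid in "AB"[: params.n_chains]]
    if params.n_waters:
        tops.append(_water_topology(params.n_waters))
    top = _concat_topologies(tops)

    # terminal-erosion Markov chain, one per chain
    spans = [[1, n] for _ in range(params.n_chains)]
    span_history: list[list[tuple[int, int]]] = []
    frames = []
    for f in range(params.n_frames):
        if f > 0:
            for s in spans:
                if s[0] < lo and rng.random() < params.unravel_rate:
                    s[0] += 1
                if s[1] > hi and rng.random() < params.unravel_rate:
                    s[1] -= 1
        span_history.append([tuple(s) for s in spans])

        chain_coords = []
        for c, s in enumerate(spans):
            phi = rng.uniform(*_COIL_PHI, size=n)
            psi = rng.uniform(*_COIL_PSI, size=n)
            helical = np.zeros(n, dtype=bool)
            helical[s[0] - 1: s[1]] = True
            phi[helical] = ALPHA_PHI
            psi[helical] = ALPHA_PSI
            bb = build_backbone(phi, psi)
            coords = _assemble_chain_coords(bb)
            ca = coords[tops[c].atom_names == "CA"]
            coords = principal_axis_align(coords, guide=ca)
            if c == 1:
                # antiparallel partner: flip the axis, offset laterally
                coords = coords @ np.diag([1.0, -1.0, -1.0])
                coords = coords + np.array([params.chain_separation, 0.0, 0.0])
            chain_coords.append(coords)
        if params.n_waters:
            box = 3.0 * n  # generous cube around the protein
            chain_coords.append(_water_coords(rng, params.n_waters, box))
        frames.append(np.vstack(chain_coords))

    return Trajectory(top, np.stack(frames),
                      metadata={"helical_spans": span_history,
                                "params": params})
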