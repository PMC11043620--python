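"""Backbone orientational correlation of successive CA->CA unit vectors.

Entry (i, j) is |< v_i . v_j >| averaged over frames, with v_i the normalized
vector from CA_i to CA_{i+1}. Rigidly co-moving segments give values near 1;
independently tumbling or constantly orthogonal vector pairs give ~0. The
absolute value is taken because only the presence of correlation matters.
"""

from __future__ import annotations

import numpy as np

from .structure import Trajectory

__all__ = ["orientational_correlation"]


def orientational_correlation(traj: Trajectory) -> np.ndarray:
    """|mean over frames of v_i . v_j| for all backbone vector pairs.

    Vectors never span a chain boundary; pairs across chains are included.
    Returns an (n_vec, n_vec) matrix with unit diagonal, or an empty matrix
    when no chain contributes at least one CA->CA segment.
    """
    top = traj.topology
    vec_cols: list[np.ndarray] = []
    for cid in top.chains():
        mask = (top.chain_ids == cid) & (top.atom_names == "CA") & ~top.is_solvent
        idx = np.flatnonzero(mask)
        order = np.argsort(top.res_indices[idx])
        idx = idx[order]
        if len(idx) < 2:
            continue
        ca = traj.coords[:, idx, :]                       # (F, m, 3)
        v = np.diff(ca, axis=1)
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        vec_cols.append(v)
    if not vec_cols:
        return np.empty((0, 0))
    v = np.concatenate(vec_cols, axis=1)                  # (F, n_vec, 3)
    corr = np.einsum("fik,fjk->ij", v, v) / v.shape[0]
    return np.abs(corr)
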