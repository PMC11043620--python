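import numpy as np
import pytest
from scipy.optimize import brentq

from idpflow.geometry import angle_deg
from idpflow.synthetic_data import HelixCoilParams, make_helix_coil_trajectory
from idpflow.trajectory_analysis import (HBondCriteria, MissingHydrogensError,
                                         Structure, Topology, Trajectory,
                                         detect_hbonds, hbond_timeseries,
                                         place_amide_hydrogens)


def _donor_acceptor_structure(distance, angle):
    """Minimal N-H ... O system with given donor-acceptor distance and
    donor-H-acceptor angle (found numerically)."""
    N = np.zeros(3)
    O = np.array([distance, 0.0, 0.0])

    def angle_at(theta):
        H = N + np.array([np.cos(theta), np.sin(theta), 0.0])
        return angle_deg(N, H, O) - angle

    theta = brentq(angle_at, 1e-6, np.pi - 1e-6)
    H = N + np.array([np.cos(theta), np.sin(theta), 0.0])
    top = Topology(np.array(["A", "A", "A"]), np.array([1, 1, 2]),
                   np.array(["GLY", "GLY", "GLY"]), np.array(["N", "H", "O"]),
                   np.array(["N", "H", "O"]), np.zeros(3, dtype=bool))
    return Structure(top, np.vstack([N, H, O]))


def _brute_force_hbonds(struct, criteria):
    """Independent oracle: scan every donor(H)/acceptor pair directly."""
    top = struct.topology
    xyz = struct.coords
    pairs = []
    for d in np.flatnonzero(np.isin(top.elements, ["N", "O"])):
        for h in np.flatnonzero(top.elements == "H"):
            if (top.chain_ids[h] == top.chain_ids[d]
                    and top.res_indices[h] == top.res_indices[d]
                    and np.linalg.norm(xyz[h] - xyz[d]) < 1.25):
                pairs.append((d, h))
    has_h = {d for d, _ in pairs}
    acceptors = [a for a in range(top.n_atoms)
                 if top.elements[a] == "O"
                 or (top.elements[a] == "N" and a not in has_h)]
    found = []
    for d, h in pairs:
        for a in acceptors:
            if a == d:
                continue
            if (top.chain_ids[a] == top.chain_ids[d]
                    and top.res_indices[a] == top.res_indices[d]):
                continue
            if np.linalg.norm(xyz[a] - xyz[d]) > criteria.max_donor_acceptor_distance:
                continue
            if angle_deg(xyz[d], xyz[h], xyz[a]) > criteria.min_angle:
                found.append((d, h, a))
    return found


def test_within_cutoffs_counted():
    s = _donor_acceptor_structure(3.4, 150.0)
    assert len(detect_hbonds(s)) == 1


def test_distance_beyond_cutoff_not_counted():
    s = _donor_acceptor_structure(3.6, 170.0)
    assert detect_hbonds(s) == []


def test_angle_below_cutoff_not_counted():
    s = _donor_acceptor_structure(3.0, 110.0)
    assert detect_hbonds(s) == []


def test_ideal_helix_i_to_i4_count(helix18):
    bonds = detect_hbonds(helix18)
    assert len(bonds) == 14
    top = helix18.topology
    for hb in bonds:
        assert top.res_indices[hb.acceptor] + 4 == top.res_indices[hb.donor]


def test_matches_brute_force_oracle(helix89):
    crit = HBondCriteria()
    ours = {(b.donor, b.hydrogen, b.acceptor) for b in detect_hbonds(helix89, crit)}
    oracle = set(map(tuple, _brute_force_hbonds(helix89, crit)))
    assert ours == oracle


def test_missing_hydrogens_raises_then_placement_fixes(helix18):
    top = helix18.topology
    keep = top.atom_names != "H"
    stripped = Structure(
        Topology(top.chain_ids[keep], top.res_indices[keep], top.res_names[keep],
                 top.atom_names[keep], top.elements[keep], top.is_solvent[keep]),
        helix18.coords[keep])
    with pytest.raises(MissingHydrogensError):
        detect_hbonds(stripped)
    rebuilt = place_amide_hydrogens(stripped)
    assert len(detect_hbonds(rebuilt)) == 14


def test_criteria_validation():
    with pytest.raises(ValueError):
        HBondCriteria(max_donor_acceptor_distance=-1.0)
    with pytest.raises(ValueError):
        HBondCriteria(min_angle=200.0)


class TestHbondTimeseries:
    def test_no_water_means_zero_pw(self, helix18):
        traj = Trajectory(helix18.topology, helix18.coords[None])
        pp, pw = hbond_timeseries(traj)
        assert np.all(pw == 0)
        assert pp[0] == 14

    def test_partition_sums_to_total(self):
        traj = make_helix_coil_trajectory(HelixCoilParams(
            n_res=15, n_frames=3, unravel_rate=0.2, core_span=(6, 10),
            seed=4, n_waters=30))
        pp, pw = hbond_timeseries(traj)
        solv = traj.topology.is_solvent
        for f in range(traj.n_frames):
            bonds = detect_hbonds(traj.frame(f))
            both_protein = sum(1 for b in bonds
                               if not solv[b.donor] and not solv[b.acceptor])
            mixed = sum(1 for b in bonds if solv[b.donor] != solv[b.acceptor])
            assert pp[f] == both_protein
            assert pw[f] == mixed

    def test_unraveling_reduces_protein_protein_bonds(self):
        first, last = [], []
        for seed in range(6):
            traj = make_helix_coil_trajectory(HelixCoilParams(
                n_res=30, n_frames=15, unravel_rate=0.5, core_span=(14, 17),
                seed=seed))
            pp, _ = hbond_timeseries(traj)
            first.append(pp[0])
            last.append(pp[-1])
        assert np.mean(last) < np.mean(first)
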