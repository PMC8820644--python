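"""Rg, RMSD, hydrogen bonds, Daura clustering, representative conformations
and per-residue deviation maps."""

import numpy as np
import pytest

from redoxscan.conformation import (backbone_indices, backbone_rmsd,
                                    daura_cluster, hydrogen_bond_count,
                                    kabsch_superpose, per_residue_deviation,
                                    radius_of_gyration, representative_frame)
from redoxscan.model import Box, Structure, Trajectory

from conftest import make_atom


def random_rotation(seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(0, 1, (3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def test_rg_point_and_dumbbell():
    assert radius_of_gyration(np.zeros((1, 3)), np.array([10.0])) == 0.0
    coords = np.array([[0, 0, 0], [1.0, 0, 0]])
    assert radius_of_gyration(coords, np.ones(2)) == pytest.approx(0.5)
    # unequal masses shift the COM toward the heavy atom
    rg = radius_of_gyration(coords, np.array([3.0, 1.0]))
    assert rg == pytest.approx(np.sqrt((3 * 0.25 ** 2 + 0.75 ** 2) / 4))


def test_rg_rotation_translation_invariant():
    rng = np.random.default_rng(3)
    coords = rng.normal(0, 1, (20, 3))
    masses = rng.uniform(1, 16, 20)
    rg0 = radius_of_gyration(coords, masses)
    moved = coords @ random_rotation(1).T + np.array([5, -2, 7])
    assert radius_of_gyration(moved, masses) == pytest.approx(rg0, rel=1e-12)


def test_rmsd_identity_and_rigid_motion():
    rng = np.random.default_rng(4)
    a = rng.normal(0, 1, (30, 3))
    assert backbone_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)
    moved = a @ random_rotation(2).T + np.array([1, 2, 3])
    assert backbone_rmsd(moved, a) == pytest.approx(0.0, abs=1e-9)
    assert backbone_rmsd(a, moved) == pytest.approx(backbone_rmsd(moved, a),
                                                    abs=1e-9)


def quaternion_rmsd(a, b):
    """Independent superposition oracle (Horn quaternion method)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(k)[-1]
    msd = (np.sum(a ** 2) + np.sum(b ** 2) - 2 * lam) / len(a)
    return np.sqrt(max(msd, 0.0))


def test_rmsd_matches_quaternion_oracle():
    rng = np.random.default_rng(5)
    for _ in range(10):
        a = rng.normal(0, 1, (25, 3))
        b = a + rng.normal(0, 0.2, (25, 3))
        assert backbone_rmsd(a, b) == pytest.approx(quaternion_rmsd(a, b),
                                                    abs=1e-9)


def test_rmsd_selection_size_mismatch():
    with pytest.raises(ValueError):
        backbone_rmsd(np.zeros((5, 3)), np.zeros((6, 3)))


def test_hbond_linear_geometry_counts_and_bent_does_not():
    # N at origin, H along +x, O acceptor at 0.29 nm along +x: angle 0
    frame = np.array([[0, 0, 0], [0.10, 0, 0], [0.29, 0, 0]])
    assert hydrogen_bond_count(frame, [(0, 1)], [2]) == 1
    # same distance, H-D-A angle 45 deg: rejected at the 30 deg cutoff
    a = np.deg2rad(45)
    bent = np.array([[0, 0, 0], [0.10 * np.cos(a), 0.10 * np.sin(a), 0],
                     [0.29, 0, 0]])
    assert hydrogen_bond_count(bent, [(0, 1)], [2]) == 0
    # beyond the distance cutoff
    far = np.array([[0, 0, 0], [0.10, 0, 0], [0.40, 0, 0]])
    assert hydrogen_bond_count(far, [(0, 1)], [2]) == 0


def test_hbond_matches_triple_loop_brute_force():
    rng = np.random.default_rng(8)
    frame = rng.uniform(0, 1.2, (30, 3))
    donors = [(i, i + 1) for i in range(0, 10, 2)]
    acceptors = list(range(10, 30))
    mine = hydrogen_bond_count(frame, donors, acceptors)
    brute = 0
    for d, h in donors:
        for a in acceptors:
            if a in (d, h):
                continue
            da = frame[a] - frame[d]
            if np.linalg.norm(da) > 0.35:
                continue
            dh = frame[h] - frame[d]
            cosang = (da @ dh) / np.linalg.norm(da) / np.linalg.norm(dh)
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= 30.0:
                brute += 1
    assert mine == brute


def test_daura_identical_frames_single_cluster():
    frames = np.tile(np.random.default_rng(0).normal(0, 1, (12, 3)), (7, 1, 1))
    res = daura_cluster(frames, cutoff=0.2)
    assert res.cluster_sizes == [7]
    assert np.all(res.assignments == 0)


def test_daura_two_rigid_conformers():
    rng = np.random.default_rng(1)
    conf_a = rng.normal(0, 0.5, (15, 3))
    conf_b = conf_a + np.array([0, 0, 0])
    conf_b = conf_a.copy()
    conf_b[:7] += 0.8  # genuinely different shape, RMSD >> cutoff
    frames = np.array([conf_a] * 5 + [conf_b] * 3)
    res = daura_cluster(frames, cutoff=0.2)
    assert res.cluster_sizes == [5, 3]
    assert len(set(res.assignments[:5])) == 1
    assert len(set(res.assignments[5:])) == 1


def test_daura_matches_brute_force_oracle():
    rng = np.random.default_rng(2)
    base = rng.normal(0, 0.5, (10, 3))
    frames = base[None] + rng.normal(0, 0.12, (30, 10, 3))
    cutoff = 0.2
    res = daura_cluster(frames, cutoff=cutoff)
    # independent greedy recomputation from the definition
    n = len(frames)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            mat[i, j] = backbone_rmsd(frames[i], frames[j])
    neigh = mat < cutoff
    np.fill_diagonal(neigh, True)
    remaining = set(range(n))
    expected = np.full(n, -1)
    clusters = []
    while remaining:
        counts = {i: sum(1 for j in remaining if neigh[i, j]) for i in remaining}
        centre = min(sorted(remaining), key=lambda i: (-counts[i], i))
        members = [j for j in sorted(remaining) if neigh[centre, j]]
        clusters.append((len(members), centre, members))
        remaining -= set(members)
    clusters.sort(key=lambda c: (-c[0], c[1]))
    for cid, (_, _, members) in enumerate(clusters):
        expected[members] = cid
    np.testing.assert_array_equal(res.assignments, expected)
    assert res.cluster_sizes == sorted(res.cluster_sizes, reverse=True)


def _two_state_trajectory(n_major=16, n_minor=4, seed=0):
    rng = np.random.default_rng(seed)
    res_atoms = []
    for r in range(8):
        for name in ("N", "CA", "C"):
            res_atoms.append((name, r + 1))
    base = rng.normal(0, 0.4, (len(res_atoms), 3))
    other = base.copy()
    other[:9] += 0.9
    atoms = [make_atom(i, name, "C" if name != "N" else "N",
                       12.011 if name != "N" else 14.007,
                       base[i], "ALA", rid)
             for i, (name, rid) in enumerate(res_atoms)]
    top = Structure(atoms)
    states = [0] * n_major + [1] * n_minor
    rng.shuffle(states)
    frames = np.array([(base if s == 0 else other) + rng.normal(0, 0.01, base.shape)
                       for s in states])
    times = np.arange(len(states), dtype=float) * 10
    return Trajectory(topology=top, frames=frames, times=times), states


def test_representative_frame_recovers_majority_state():
    traj, states = _two_state_trajectory()
    idx = representative_frame(traj, discard_ps=0.0, cutoff=0.2)
    assert states[idx] == 0


def test_representative_frame_discard_window():
    traj, states = _two_state_trajectory()
    idx = representative_frame(traj, discard_ps=100.0, cutoff=0.2)
    assert idx >= 10
    with pytest.raises(ValueError):
        representative_frame(traj, discard_ps=1e6)


def test_per_residue_deviation_identical_is_zero(toy_protein):
    dev = per_residue_deviation(toy_protein, toy_protein, mode="whole")
    np.testing.assert_allclose(dev.deviations, 0.0, atol=1e-12)


def test_per_residue_deviation_hinge_modes():
    rng = np.random.default_rng(7)
    n_res = 20
    atoms = []
    coords = []
    for r in range(n_res):
        ca = np.array([0.4 * r, 0.0, 0.0]) + rng.normal(0, 0.02, 3)
        atoms.append(make_atom(len(atoms), "CA", "C", 12.011, ca, "ALA", r + 1))
        coords.append(ca)
    a = Structure(atoms)
    # rotate the second half (domain 2) about the hinge
    coords = np.array(coords)
    hinge = coords[10]
    rot = random_rotation(3)
    moved = coords.copy()
    moved[10:] = (coords[10:] - hinge) @ rot.T + hinge
    b = a.with_positions(moved)
    whole = per_residue_deviation(a, b, mode="whole")
    per_dom = per_residue_deviation(a, b, mode="per_domain",
                                    domains=[(1, 10), (11, 20)])
    assert np.nanmax(per_dom.deviations) < 1e-6
    assert whole.deviations.max() > 0.3
    # sequence mismatch is an error
    shorter = Structure(atoms[:-1])
    with pytest.raises(ValueError):
        per_residue_deviation(a, shorter, mode="whole")


def test_backbone_indices_skip_probes(toy_protein):
    from redoxscan.synthetic import SimulatorConfig, simulate_probe_diffusion
    traj = simulate_probe_diffusion(toy_protein,
                                    SimulatorConfig(n_frames=2, n_probes=3,
                                                    burn_in_moves=0, seed=0))
    idx = backbone_indices(traj.topology)
    names = {traj.topology.atoms[i].residue_name for i in idx}
    assert "TCEP" not in names
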