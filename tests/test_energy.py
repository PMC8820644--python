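"""Simplified potential, steepest-descent minimizer and the E_fin < E_in
reduction check."""

import numpy as np
import pytest

from redoxscan.energy import (EnergyCheckResult, EnergyError, ForceFieldParams,
                              MinimizationConfig, always_accept_backend,
                              always_reject_backend, default_toy_forcefield,
                              energy_check, potential_energy, reduce_disulfide,
                              scan_distance_energy_criterion, steepest_descent,
                              table_backend)
from redoxscan.model import DisulfideBond, Structure, select_probes
from redoxscan.proximity import ProximityConfig, scan_distance_criterion

from conftest import make_atom

LJ_ONLY = ForceFieldParams(lj={"C": (0.34, 0.40)}, cutoff=1.2)


def carbon_dimer(r):
    return Structure([
        make_atom(0, "C1", "C", 12.011, [0, 0, 0]),
        make_atom(1, "C2", "C", 12.011, [r, 0, 0]),
    ])


def test_lj_minimum_energy_is_minus_epsilon():
    r_min = 2 ** (1 / 6) * 0.34
    e, terms = potential_energy(carbon_dimer(r_min), LJ_ONLY, bonds=[])
    assert e == pytest.approx(-0.40, abs=1e-9)
    assert terms["bond"] == 0.0 and terms["coulomb"] == 0.0


def test_harmonic_bond_zero_at_equilibrium():
    ff = ForceFieldParams(bonds={("C", "C"): (1e5, 0.15)},
                          lj={"C": (0.34, 0.40)})
    e, terms = potential_energy(carbon_dimer(0.15), ff, bonds=[(0, 1)])
    assert terms["bond"] == pytest.approx(0.0, abs=1e-12)
    assert terms["lj"] == 0.0  # 1-2 pair excluded from nonbonded


def test_five_atom_energy_matches_hand_sum():
    ff = ForceFieldParams(
        bonds={("C", "C"): (2e5, 0.15)},
        angles={("*", "C", "*"): (300.0, np.deg2rad(109.5))},
        lj={"C": (0.34, 0.40)},
        charges={"C": 0.1},
        cutoff=1.2)
    rng = np.random.default_rng(2)
    coords = rng.uniform(0, 0.6, (5, 3))
    s = Structure([make_atom(i, f"C{i}", "C", 12.011, coords[i]) for i in range(5)])
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4)]
    e, _ = potential_energy(s, ff, bonds)
    # independent term-by-term sum
    expect = 0.0
    for i, j in bonds:
        r = np.linalg.norm(coords[i] - coords[j])
        expect += 0.5 * 2e5 * (r - 0.15) ** 2
    for i, j, k in ((0, 1, 2), (1, 2, 3), (2, 3, 4)):
        v1, v2 = coords[i] - coords[j], coords[k] - coords[j]
        th = np.arccos(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2))
        expect += 0.5 * 300.0 * (th - np.deg2rad(109.5)) ** 2
    excluded = {(0, 1), (1, 2), (2, 3), (3, 4), (0, 2), (1, 3), (2, 4)}
    for i in range(5):
        for j in range(i + 1, 5):
            if (i, j) in excluded:
                continue
            r = np.linalg.norm(coords[i] - coords[j])
            if r < 1.2:
                sr6 = (0.34 / r) ** 6
                expect += 4 * 0.40 * (sr6 ** 2 - sr6)
                expect += 138.935458 * 0.01 / r
    assert e == pytest.approx(expect, abs=1e-9)


def test_energy_rotation_translation_invariant():
    rng = np.random.default_rng(4)
    coords = rng.uniform(0, 0.8, (6, 3))
    s = Structure([make_atom(i, f"C{i}", "C", 12.011, coords[i]) for i in range(6)])
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)]
    ff = default_toy_forcefield()
    e0, _ = potential_energy(s, ff, bonds)
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
    moved = coords @ rot.T + np.array([1.3, -0.4, 2.2])
    e1, _ = potential_energy(s.with_positions(moved), ff, bonds)
    assert e1 == pytest.approx(e0, rel=1e-8)


def test_minimizer_relaxes_stretched_bond_monotonically():
    ff = ForceFieldParams(bonds={("C", "C"): (2.5e5, 0.15)},
                          lj={"C": (0.34, 0.0)})
    res = steepest_descent(carbon_dimer(0.17), ff, [(0, 1)],
                           MinimizationConfig(fmax_tol=1.0))
    assert res.converged
    r_fin = np.linalg.norm(np.diff(res.final_structure.positions, axis=0))
    assert r_fin == pytest.approx(0.15, abs=1e-4)
    assert res.energy == pytest.approx(0.0, abs=1e-3)
    trace = np.asarray(res.energy_trace)
    assert np.all(np.diff(trace) <= 0)


def test_minimizer_at_minimum_takes_no_steps():
    ff = ForceFieldParams(bonds={("C", "C"): (2.5e5, 0.15)},
                          lj={"C": (0.34, 0.0)})
    res = steepest_descent(carbon_dimer(0.15), ff, [(0, 1)],
                           MinimizationConfig(fmax_tol=10.0))
    assert res.converged and res.n_steps == 0


def test_lj_dimer_minimizes_to_sigma_times_sixth_root_of_two():
    res = steepest_descent(carbon_dimer(1.5 * 0.34), LJ_ONLY, [],
                           MinimizationConfig(step0=0.01, fmax_tol=0.5,
                                              max_steps=2000))
    r_fin = np.linalg.norm(np.diff(res.final_structure.positions, axis=0))
    assert r_fin == pytest.approx(2 ** (1 / 6) * 0.34, abs=1e-3)


def cystine_toy():
    """Two CYS residues with CB-SG-SG-CB arranged at bonding distance."""
    atoms = [
        make_atom(0, "CB", "C", 12.011, [-0.18, 0.1, 0], "CYS", 1),
        make_atom(1, "SG", "S", 32.06, [-0.1025, 0, 0], "CYS", 1),
        make_atom(2, "SG", "S", 32.06, [0.1025, 0, 0], "CYS", 2),
        make_atom(3, "CB", "C", 12.011, [0.18, 0.1, 0], "CYS", 2),
    ]
    s = Structure(atoms)
    bond = DisulfideBond("Cys1-Cys2", (1, 2), (None, None), ((0), (3)),
                         (1, 2), ("A", "A"))
    return s, bond, [(0, 1), (2, 3), (1, 2)]


def test_reduce_disulfide_geometry_and_double_application():
    s, bond, _ = cystine_toy()
    red = reduce_disulfide(s, bond)
    assert red.n_atoms == s.n_atoms + 2
    h1, h2 = red.atoms[-2], red.atoms[-1]
    assert h1.name == "HG" and h2.element == "H"
    d1 = np.linalg.norm(h1.position - s.atoms[1].position)
    d2 = np.linalg.norm(h2.position - s.atoms[2].position)
    assert d1 == pytest.approx(0.134, abs=1e-6)
    assert d2 == pytest.approx(0.134, abs=1e-6)
    # hydrogens point away from the former partner
    assert h1.position[0] < s.atoms[1].position[0]
    assert h2.position[0] > s.atoms[2].position[0]
    with pytest.raises(EnergyError):
        reduce_disulfide(red, bond)


def test_energy_check_boundary_is_strict():
    assert not EnergyCheckResult(E_in=1.0, E_fin=1.0).accepted
    assert EnergyCheckResult(E_in=1.0, E_fin=0.999).accepted
    assert not EnergyCheckResult(E_in=1.0, E_fin=1.001).accepted


def test_energy_check_accepts_strain_relief_and_rejects_relaxed():
    ff = default_toy_forcefield()
    cfg = MinimizationConfig(fmax_tol=20.0, max_steps=300)
    # severely compressed S-S (0.13 nm vs 0.205 eq): cleavage relieves strain
    strained = Structure([
        make_atom(0, "CB", "C", 12.011, [-0.23, 0.12, 0], "CYS", 1),
        make_atom(1, "SG", "S", 32.06, [-0.065, 0, 0], "CYS", 1),
        make_atom(2, "SG", "S", 32.06, [0.065, 0, 0], "CYS", 2),
        make_atom(3, "CB", "C", 12.011, [0.23, 0.12, 0], "CYS", 2),
    ])
    bond = DisulfideBond("Cys1-Cys2", (1, 2), (None, None), (0, 3), (1, 2), ("A", "A"))
    check = energy_check(strained, bond, ff, [(0, 1), (2, 3)], cfg)
    assert check.accepted

    # acceptance decision is a pure function of the event-frame structure
    relaxed, bond2, bonds2 = cystine_toy()
    check2 = energy_check(relaxed, bond2, ff, bonds2, cfg)
    again = energy_check(relaxed, bond2, ff, bonds2, cfg)
    assert (check2.E_in, check2.E_fin) == (again.E_in, again.E_fin)
    assert check2.accepted == again.accepted


def test_distance_energy_scan_backends(two_bond_system):
    _, bonds, with_probes = two_bond_system
    far = np.array([8.0, 2.0, 8.0])
    path = np.tile(far, (12, 1))
    path[3:] = [2.1025, 2.5, 2.0]      # bond 1 contact from frame 3
    path2 = np.tile(far, (12, 1))
    path2[6:] = [6.1025, 6.5, 6.0]     # bond 2 contact from frame 6
    traj = with_probes([path, path2])
    probes = select_probes(traj.topology, {"TCEP"})
    cfg = ProximityConfig()

    accept_all = scan_distance_energy_criterion(
        traj, bonds, probes, cfg, always_accept_backend())
    distance_only = scan_distance_criterion(traj, bonds, probes, cfg)
    assert accept_all.called_bond == distance_only.called_bond
    assert accept_all.event.frame_index == distance_only.event.frame_index

    # bond 1 rejected by injected energies, bond 2 accepted -> later call wins
    picky = table_backend({bonds[0].label: (0.0, 5.0), bonds[1].label: (0.0, -5.0)})
    call = scan_distance_energy_criterion(traj, bonds, probes, cfg, picky,
                                          refractory_ps=1e9)
    assert call.called_bond == bonds[1].label
    assert call.energy_checks_failed >= 1

    reject = scan_distance_energy_criterion(
        traj, bonds, probes, cfg, always_reject_backend(), refractory_ps=1e9)
    assert reject.called_bond is None
    assert reject.energy_checks_failed == 2  # one per (bond, probe) pair


def test_missing_parameter_error_names_term():
    s = carbon_dimer(0.2)
    with pytest.raises(EnergyError, match="bond parameters"):
        potential_energy(s, LJ_ONLY, bonds=[(0, 1)])
    with pytest.raises(EnergyError, match="LJ parameters"):
        potential_energy(Structure([make_atom(0, "X", "P", 30.97, [0, 0, 0])]),
                         LJ_ONLY, bonds=[])
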