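"""The distance+energy lability criterion.

When a probe contact event occurs, the candidate disulfide is broken in the
event-frame structure (each sulfur capped with a hydrogen), both the intact
and the reduced forms are energy-minimised with steepest descent, and the
reduction is accepted only if the minimised reduced energy is strictly below
the minimised intact energy (E_fin < E_in).

The potential is a deliberately simple, self-contained vacuum force field —
harmonic bonds and angles, Lennard-Jones and truncated Coulomb interactions
(1.2 nm cutoff) — exposed behind a pluggable backend contract so externally
computed E_in/E_fin pairs (e.g. from a full MD engine) can be injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .model import Atom, DisulfideBond, ProbeGroup, Structure, Trajectory
from .pbc import min_image_displacement
from .proximity import (ProximityConfig, TrajectoryCall, iter_proximity_events)

COULOMB_KJ_NM = 138.935458  # kJ/mol * nm / e^2
SH_BOND_LENGTH_NM = 0.134


class EnergyError(RuntimeError):
    pass


@dataclass
class ForceFieldParams:
    """Per-class parameters of the simplified potential.

    Classes are element symbols.  ``bond_k`` in kJ/mol/nm^2, ``bond_r0`` nm;
    ``angle_k`` in kJ/mol/rad^2 keyed by (end, centre, end) with a
    ('*', centre, '*') wildcard fallback; LJ sigma nm / epsilon kJ/mol with
    Lorentz-Berthelot mixing; charges (e) looked up by atom name, then
    element, defaulting to 0.
    """

    bonds: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    angles: dict[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)
    lj: dict[str, tuple[float, float]] = field(default_factory=dict)
    charges: dict[str, float] = field(default_factory=dict)
    cutoff: float = 1.2

    def bond_param(self, ea: str, eb: str):
        key = tuple(sorted((ea, eb)))
        if key not in self.bonds:
            raise EnergyError(f"missing bond parameters for class {key}")
        return self.bonds[key]

    def angle_param(self, ea: str, eb: str, ec: str):
        lo, hi = sorted((ea, ec))
        for key in ((lo, eb, hi), ("*", eb, "*")):
            if key in self.angles:
                return self.angles[key]
        raise EnergyError(f"missing angle parameters for class ({ea},{eb},{ec})")

    def lj_param(self, e: str):
        if e not in self.lj:
            raise EnergyError(f"missing LJ parameters for element {e}")
        return self.lj[e]

    def charge(self, atom: Atom) -> float:
        return self.charges.get(atom.name, self.charges.get(atom.element, 0.0))


def default_toy_forcefield() -> ForceFieldParams:
    """Generic parameters covering the backbone/cysteine/hydrogen classes of
    the toy structures; magnitudes are in the range of biomolecular force
    fields but make no claim to chemical accuracy."""
    kb = 2.5e5
    return ForceFieldParams(
        bonds={
            ("C", "C"): (kb, 0.153), ("C", "N"): (kb, 0.147),
            ("C", "S"): (kb, 0.182), ("S", "S"): (kb, 0.205),
            ("H", "S"): (kb, SH_BOND_LENGTH_NM), ("C", "H"): (kb, 0.109),
            ("H", "N"): (kb, 0.101), ("C", "O"): (kb, 0.143),
            ("H", "O"): (kb, 0.097),
        },
        angles={("*", "C", "*"): (450.0, np.deg2rad(110.0)),
                ("*", "N", "*"): (450.0, np.deg2rad(112.0)),
                ("*", "S", "*"): (400.0, np.deg2rad(100.0)),
                ("*", "O", "*"): (400.0, np.deg2rad(108.0))},
        lj={"C": (0.34, 0.40), "N": (0.33, 0.50), "O": (0.30, 0.65),
            "S": (0.36, 1.00), "H": (0.12, 0.06), "P": (0.37, 0.80)},
        charges={},
    )


@dataclass
class MinimizationConfig:
    step0: float = 0.005          # nm
    fmax_tol: float = 50.0        # kJ/mol/nm
    max_steps: int = 400


@dataclass
class MinimizationResult:
    final_structure: Structure
    energy: float
    n_steps: int
    converged: bool
    max_force: float
    energy_trace: list[float] = field(default_factory=list)


@dataclass
class EnergyCheckResult:
    E_in: float
    E_fin: float

    @property
    def accepted(self) -> bool:
        return self.E_fin < self.E_in


EnergyBackend = Callable[[Structure, DisulfideBond], EnergyCheckResult]


def angles_from_bonds(bonds: Sequence[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """Enumerate i-j-k angle triples from the bond graph (j the centre)."""
    neigh: dict[int, list[int]] = {}
    for i, j in bonds:
        neigh.setdefault(i, []).append(j)
        neigh.setdefault(j, []).append(i)
    out = []
    for j, ns in sorted(neigh.items()):
        ns = sorted(ns)
        for a in range(len(ns)):
            for b in range(a + 1, len(ns)):
                out.append((ns[a], j, ns[b]))
    return out


def infer_bonds(s: Structure, scale: float = 1.2) -> list[tuple[int, int]]:
    """Distance-based covalent bond guess (pair within scale * sum of covalent radii)."""
    cov = {"H": 0.031, "C": 0.076, "N": 0.071, "O": 0.066, "S": 0.105, "P": 0.107}
    pos = s.positions
    out = []
    for i in range(s.n_atoms):
        for j in range(i + 1, s.n_atoms):
            ri = cov.get(s.atoms[i].element, 0.08)
            rj = cov.get(s.atoms[j].element, 0.08)
            lengths = None if s.box is None else s.box.lengths
            d = np.linalg.norm(min_image_displacement(pos[i], pos[j], lengths))
            if d <= scale * (ri + rj):
                out.append((i, j))
    return out


def _pair_energy_terms(s: Structure, ff: ForceFieldParams,
                       bonds: Sequence[tuple[int, int]], coords: np.ndarray):
    lengths = None if s.box is None else s.box.lengths
    e_bond = 0.0
    for i, j in bonds:
        k, r0 = ff.bond_param(s.atoms[i].element, s.atoms[j].element)
        r = np.linalg.norm(min_image_displacement(coords[i], coords[j], lengths))
        e_bond += 0.5 * k * (r - r0) ** 2
    e_angle = 0.0
    for i, j, k_ in angles_from_bonds(bonds):
        ka, th0 = ff.angle_param(s.atoms[i].element, s.atoms[j].element,
                                 s.atoms[k_].element)
        v1 = min_image_displacement(coords[i], coords[j], lengths)
        v2 = min_image_displacement(coords[k_], coords[j], lengths)
        cosq = np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0)
        e_angle += 0.5 * ka * (np.arccos(cosq) - th0) ** 2
    # nonbonded: all pairs except 1-2 and 1-3
    excl = {tuple(sorted(b)) for b in bonds}
    for i, j, k_ in angles_from_bonds(bonds):
        excl.add(tuple(sorted((i, k_))))
    n = s.n_atoms
    elems = [a.element for a in s.atoms]
    sig = np.empty(n)
    eps = np.empty(n)
    for i in range(n):
        sig[i], eps[i] = ff.lj_param(elems[i])
    q = np.array([ff.charge(a) for a in s.atoms])
    disp = min_image_displacement(coords[:, None, :], coords[None, :, :], lengths)
    dist = np.linalg.norm(disp, axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    mask = np.array([(int(a), int(b)) not in excl for a, b in zip(iu, ju)])
    iu, ju = iu[mask], ju[mask]
    r = dist[iu, ju]
    within = r < ff.cutoff
    r = r[within]
    iu, ju = iu[within], ju[within]
    sij = 0.5 * (sig[iu] + sig[ju])
    eij = np.sqrt(eps[iu] * eps[ju])
    sr6 = (sij / r) ** 6
    e_lj = float(np.sum(4.0 * eij * (sr6 ** 2 - sr6)))
    e_coul = float(np.sum(COULOMB_KJ_NM * q[iu] * q[ju] / r))
    return {"bond": e_bond, "angle": e_angle, "lj": e_lj, "coulomb": e_coul}


def potential_energy(s: Structure, ff: ForceFieldParams,
                     bonds: Sequence[tuple[int, int]]):
    """Total simplified potential energy (kJ/mol) with a per-term breakdown."""
    terms = _pair_energy_terms(s, ff, bonds, s.positions)
    terms["total"] = sum(terms.values())
    return terms["total"], terms


def _numerical_forces(s: Structure, ff: ForceFieldParams, bonds, coords,
                      h: float = 1e-6) -> np.ndarray:
    """Central-difference forces; adequate and exact-to-quadrature for the
    desk-scale systems this backend minimises."""
    f = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for d in range(3):
            cp = coords.copy(); cp[i, d] += h
            cm = coords.copy(); cm[i, d] -= h
            ep = sum(_pair_energy_terms(s, ff, bonds, cp).values())
            em = sum(_pair_energy_terms(s, ff, bonds, cm).values())
            f[i, d] = -(ep - em) / (2 * h)
    return f


def steepest_descent(s: Structure, ff: ForceFieldParams,
                     bonds: Sequence[tuple[int, int]],
                     cfg: Optional[MinimizationConfig] = None) -> MinimizationResult:
    """Adaptive steepest descent: step halves on an uphill trial and grows
    1.2x on acceptance; converged when the largest atomic force drops below
    the tolerance.  The accepted-energy trace is non-increasing by design."""
    cfg = cfg or MinimizationConfig()
    coords = s.positions.copy()
    e, _ = potential_energy(s.with_positions(coords), ff, bonds)
    if not np.isfinite(e):
        raise EnergyError("non-finite initial energy")
    step = cfg.step0
    trace = [e]
    n_accepted = 0
    forces = _numerical_forces(s, ff, bonds, coords)
    fmax = float(np.max(np.linalg.norm(forces, axis=1)))
    for _ in range(cfg.max_steps):
        if fmax < cfg.fmax_tol:
            break
        trial = coords + step * forces / fmax
        e_trial = sum(_pair_energy_terms(s, ff, bonds, trial).values())
        if e_trial < e:
            coords, e = trial, e_trial
            trace.append(e)
            n_accepted += 1
            step *= 1.2
            forces = _numerical_forces(s, ff, bonds, coords)
            fmax = float(np.max(np.linalg.norm(forces, axis=1)))
        else:
            step *= 0.5
            if step < 1e-8:
                break
    return MinimizationResult(
        final_structure=s.with_positions(coords), energy=float(e),
        n_steps=n_accepted, converged=bool(fmax < cfg.fmax_tol),
        max_force=fmax, energy_trace=trace)


def reduce_disulfide(s: Structure, bond: DisulfideBond) -> Structure:
    """Break an S-S bond: append one capping hydrogen per SG at 0.134 nm along
    the former S-S axis, pointing away from the partner sulfur."""
    i, j = bond.sg_indices
    for sg in (i, j):
        a = s.atoms[sg]
        for other in s.atoms:
            if (other.chain_id == a.chain_id and other.residue_id == a.residue_id
                    and other.name == "HG"):
                raise EnergyError(f"disulfide {bond.label} already reduced")
    pos = s.positions
    lengths = None if s.box is None else s.box.lengths
    axis = min_image_displacement(pos[i], pos[j], lengths)
    axis = axis / np.linalg.norm(axis)
    atoms = [Atom(a.index, a.name, a.element, a.mass, a.residue_name,
                  a.residue_id, a.chain_id, a.position.copy()) for a in s.atoms]
    n = len(atoms)
    for k, (sg, direction) in enumerate(((i, axis), (j, -axis))):
        a = s.atoms[sg]
        atoms.append(Atom(n + k, "HG", "H", 1.008, a.residue_name,
                          a.residue_id, a.chain_id,
                          pos[sg] + SH_BOND_LENGTH_NM * direction))
    return Structure(atoms, box=s.box, title=s.title)


def energy_check(s_event: Structure, bond: DisulfideBond, ff: ForceFieldParams,
                 bonds: Sequence[tuple[int, int]],
                 min_cfg: Optional[MinimizationConfig] = None) -> EnergyCheckResult:
    """Minimise the intact and the reduced event-frame structures and compare."""
    ss = tuple(sorted(bond.sg_indices))
    bonds_in = [tuple(sorted(b)) for b in bonds]
    if ss not in bonds_in:
        bonds_in.append(ss)
    res_in = steepest_descent(s_event, ff, bonds_in, min_cfg)
    reduced = reduce_disulfide(s_event, bond)
    n = s_event.n_atoms
    bonds_fin = [b for b in bonds_in if b != ss]
    bonds_fin += [(bond.sg_indices[0], n), (bond.sg_indices[1], n + 1)]
    res_fin = steepest_descent(reduced, ff, bonds_fin, min_cfg)
    return EnergyCheckResult(E_in=res_in.energy, E_fin=res_fin.energy)


# ---------------------------------------------------------------------------
# energy backends

def always_accept_backend() -> EnergyBackend:
    """Stub backend accepting every event (E_fin - E_in fixed at -1 kJ/mol);
    reduces the distance+energy criterion to the pure distance criterion."""
    return lambda s, bond: EnergyCheckResult(E_in=0.0, E_fin=-1.0)


def always_reject_backend() -> EnergyBackend:
    return lambda s, bond: EnergyCheckResult(E_in=0.0, E_fin=0.0)


def table_backend(energies: dict[str, tuple[float, float]]) -> EnergyBackend:
    """Inject externally computed (E_in, E_fin) pairs keyed by bond label,
    e.g. from an MD-engine replication run."""
    def backend(s: Structure, bond: DisulfideBond) -> EnergyCheckResult:
        if bond.label not in energies:
            raise EnergyError(f"no injected energies for bond {bond.label}")
        e_in, e_fin = energies[bond.label]
        return EnergyCheckResult(E_in=e_in, E_fin=e_fin)
    return backend


def extract_substructure(s: Structure, indices: Sequence[int]):
    """Sub-structure of the given atoms (reindexed) plus old->new index map."""
    index_map = {old: new for new, old in enumerate(indices)}
    atoms = []
    for new, old in enumerate(indices):
        a = s.atoms[old]
        atoms.append(Atom(new, a.name, a.element, a.mass, a.residue_name,
                          a.residue_id, a.chain_id, a.position.copy()))
    return Structure(atoms, box=s.box, title=s.title), index_map


def simple_ff_backend(ff: ForceFieldParams,
                      topology_bonds: Sequence[tuple[int, int]],
                      protein_indices: Optional[Sequence[int]] = None,
                      min_cfg: Optional[MinimizationConfig] = None) -> EnergyBackend:
    """Backend running the simplified-potential E_fin < E_in check, optionally
    restricted to the protein atoms (solvent/probes ignored, vacuum)."""
    def backend(s: Structure, bond: DisulfideBond) -> EnergyCheckResult:
        if protein_indices is not None:
            sub, imap = extract_substructure(s, protein_indices)
            sub_bonds = [(imap[i], imap[j]) for i, j in topology_bonds
                         if i in imap and j in imap]
            sub_bond = DisulfideBond(
                label=bond.label,
                sg_indices=(imap[bond.sg_indices[0]], imap[bond.sg_indices[1]]),
                ca_indices=tuple(imap.get(c) for c in bond.ca_indices),
                cb_indices=tuple(imap.get(c) for c in bond.cb_indices),
                residue_ids=bond.residue_ids, chain_ids=bond.chain_ids)
            return energy_check(sub, sub_bond, ff, sub_bonds, min_cfg)
        return energy_check(s, bond, ff, topology_bonds, min_cfg)
    return backend


def scan_distance_energy_criterion(
        traj: Trajectory, bonds: Sequence[DisulfideBond], probes: ProbeGroup,
        cfg: ProximityConfig, backend: EnergyBackend,
        trajectory_id: str = "traj", refractory_ps: float = 100.0) -> TrajectoryCall:
    """Distance+energy criterion: iterate contact events in time order and call
    the first one whose energy check accepts.  A failed check makes that
    (bond, probe) pair refractory for ``refractory_ps``; scanning continues."""
    blocked: dict[tuple[str, int], float] = {}
    failed = 0
    for ev in iter_proximity_events(traj, bonds, probes, cfg):
        key = (ev.bond, ev.probe_index)
        if ev.time < blocked.get(key, -np.inf):
            continue
        bond_obj = next(b for b in bonds if b.label == ev.bond)
        result = backend(traj.frame_structure(ev.frame_index), bond_obj)
        if result.accepted:
            return TrajectoryCall(trajectory_id=trajectory_id, called_bond=ev.bond,
                                  criterion="distance_energy", event=ev,
                                  energy_checks_failed=failed)
        failed += 1
        blocked[key] = ev.time + refractory_ps
    return TrajectoryCall(trajectory_id=trajectory_id, called_bond=None,
                          criterion="distance_energy", energy_checks_failed=failed)
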