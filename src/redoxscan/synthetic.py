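"""Synthetic fixtures with known ground truth.

Everything the lability criteria consume can be generated here without an MD
engine: toy shell proteins with disulfides at controlled burial, seeded
random-walk probe trajectories with a tunable attractive patch at one bond,
peak-area tables with designed reduction fractions, and 3D conformers of the
real reducing agents (TCEP, DTT) for radius-of-gyration checks.

The probe dynamics are overdamped seeded random walks with hard-core
rejection against the protein and a Metropolis bias toward the patched bond —
a generator of contact statistics, not physical kinetics.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .conformation import radius_of_gyration
from .model import Atom, Box, DisulfideBond, Structure, Trajectory, detect_disulfides
from .pbc import min_image_displacement, mass_weighted_com

_MASS = {"N": 14.007, "C": 12.011, "S": 32.06, "H": 1.008, "O": 15.999, "P": 30.974}
PROBE_MASSES = {"TCEP": 250.19, "DTT": 154.25}
PROBE_RG = {"TCEP": 0.37, "DTT": 0.26}
PROBE_SMILES = {
    "TCEP": "OC(=O)CCP(CCC(=O)O)CCC(=O)O",
    "DTT": "OC(CS)C(O)CS",
}


@dataclass
class DisulfidePlacement:
    exposure: str  # "surface" | "buried"

    def __post_init__(self) -> None:
        if self.exposure not in ("surface", "buried"):
            raise ValueError(f"unknown exposure {self.exposure!r}")


@dataclass
class ToyProteinSpec:
    n_residues: int = 40
    placements: Sequence[DisulfidePlacement] = field(
        default_factory=lambda: (DisulfidePlacement("surface"),
                                 DisulfidePlacement("surface"),
                                 DisulfidePlacement("buried")))
    jitter: float = 0.01  # nm, positional noise on backbone sites


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def _tangent(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    t = np.cross(u, ref)
    return t / np.linalg.norm(t)


def build_toy_protein(spec: Optional[ToyProteinSpec] = None, seed: int = 0) -> Structure:
    """Shell-of-residues toy protein (backbone N/CA/C; cysteines add CB/SG).

    Residues sit on a Fibonacci-sphere shell sized for ~0.55 nm spacing.
    Surface disulfides protrude beyond the shell; a buried disulfide sits at
    the centre inside an occluding inner cage of extra residues, so SASA
    separates the two by construction.  Deterministic for a given seed.
    """
    spec = spec or ToyProteinSpec()
    rng = np.random.default_rng(seed)
    n_shell = spec.n_residues
    surface = [p for p in spec.placements if p.exposure == "surface"]
    buried = [p for p in spec.placements if p.exposure == "buried"]
    if len(buried) > 1:
        raise ValueError("at most one buried disulfide is supported")
    if 2 * len(surface) + 2 > n_shell:
        raise ValueError("too many placements for this residue count")
    radius = np.sqrt(0.3 * n_shell / (4 * np.pi))
    sites = _fibonacci_sphere(n_shell) * radius
    # evenly spread shell sites host the surface cystine pairs
    host_sites = [int(round((k + 1) * n_shell / (len(surface) + 2)))
                  for k in range(len(surface))]

    atoms: list[Atom] = []
    rid = 0

    def add_atom(name: str, element: str, resname: str, pos: np.ndarray) -> None:
        atoms.append(Atom(len(atoms), name, element, _MASS[element],
                          resname, rid, "A", np.asarray(pos, dtype=float)))

    def add_backbone(ca: np.ndarray, t: np.ndarray, resname: str) -> None:
        j = rng.normal(0.0, spec.jitter, (3, 3))
        add_atom("N", "N", resname, ca - 0.145 * t + j[0])
        add_atom("CA", "C", resname, ca + j[1])
        add_atom("C", "C", resname, ca + 0.145 * t + j[2])

    def add_cystine_pair(mid_sg: np.ndarray, axis: np.ndarray,
                         ca_a: np.ndarray, ca_b: np.ndarray, t: np.ndarray) -> None:
        nonlocal rid
        sg_a = mid_sg - 0.1025 * axis
        sg_b = mid_sg + 0.1025 * axis
        for ca, sg in ((ca_a, sg_a), (ca_b, sg_b)):
            rid += 1
            add_backbone(ca, t, "CYS")
            to_sg = sg - ca
            cb = ca + 0.155 * to_sg / np.linalg.norm(to_sg)
            add_atom("CB", "C", "CYS", cb)
            add_atom("SG", "S", "CYS", sg)

    twist = np.deg2rad(25.0)  # tilts the S-S axis out of the local plane so
    for i in range(n_shell):  # the five chi dihedrals are generically nonzero
        if i in host_sites:
            u = sites[i] / np.linalg.norm(sites[i])
            t = _tangent(u)
            w = np.cross(u, t)
            axis = np.cos(twist) * t + np.sin(twist) * w
            mid = u * (radius + 0.33)
            add_cystine_pair(mid, axis, sites[i] - 0.30 * t, sites[i] + 0.30 * t, t)
        else:
            rid += 1
            add_backbone(sites[i], _tangent(sites[i] / np.linalg.norm(sites[i])),
                         "ALA")
    if buried:
        x = np.array([1.0, 0.0, 0.0])
        add_cystine_pair(np.zeros(3), x,
                         np.array([-0.35, 0.12, 0.0]),
                         np.array([0.35, -0.08, 0.10]),
                         np.array([0.0, 1.0, 0.0]))
        cage = _fibonacci_sphere(20) * 0.52
        for k in range(20):
            rid += 1
            u = cage[k] / np.linalg.norm(cage[k])
            add_backbone(cage[k], _tangent(u), "ALA")
    return Structure(atoms, box=None, title=f"toy protein (seed {seed})")


def toy_topology_bonds(s: Structure) -> list[tuple[int, int]]:
    """Covalent bond list for toy proteins: intra-residue backbone and side
    chain bonds, sequential peptide links, and detected S-S bonds."""
    bonds: list[tuple[int, int]] = []
    residues = s.residues()
    for (chain, rid, rname), idxs in residues:
        names = {s.atoms[i].name: i for i in idxs}
        for a, b in (("N", "CA"), ("CA", "C"), ("CA", "CB"), ("CB", "SG")):
            if a in names and b in names:
                bonds.append((names[a], names[b]))
    by_rid = {(key[0], key[1]): idxs for key, idxs in residues}
    for (chain, rid), idxs in by_rid.items():
        nxt = by_rid.get((chain, rid + 1))
        if nxt is None:
            continue
        names = {s.atoms[i].name: i for i in idxs}
        nnames = {s.atoms[i].name: i for i in nxt}
        if "C" in names and "N" in nnames:
            bonds.append((names["C"], nnames["N"]))
    for b in detect_disulfides(s):
        bonds.append(b.sg_indices)
    return [tuple(sorted(b)) for b in bonds]


@dataclass
class SimulatorConfig:
    """Probe-diffusion simulation settings.

    Defaults emulate the study conditions: a cubic box, a 100:1
    probe:protein ratio, 10 ps between saved frames; the trajectory length is
    a desk-scale choice.  ``patch_strength`` is the depth (in kT) of a
    Gaussian attraction well of width ``patch_width`` centred on the patched
    bond's COM.
    """

    box: Box = field(default_factory=lambda: Box.cubic(7.9))
    n_probes: int = 100
    probe_rg: float = 0.37
    step_size: float = 0.15
    n_frames: int = 400
    frame_interval: float = 10.0
    seed: int = 0
    patch_bond: Optional[str] = None
    patch_strength: float = 4.0
    patch_width: float = 0.6
    excluded_radius: float = 0.45
    probe_resname: str = "TCEP"
    moves_per_frame: int = 1
    burn_in_moves: int = 200

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("need at least one probe")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.patch_strength < 0:
            raise ValueError("patch_strength must be >= 0")


def simulate_probe_diffusion(protein: Structure, cfg: SimulatorConfig) -> Trajectory:
    """Seeded random-walk probes around a static, box-centred protein.

    Each saved frame applies ``moves_per_frame`` Gaussian trial moves per
    probe with periodic wrapping; trials within ``excluded_radius`` of any
    protein atom are rejected (hard core), and when a patch bond is set the
    move is additionally Metropolis-filtered against the Gaussian attraction
    well.  Bit-identical for a given seed.
    """
    rng = np.random.default_rng(cfg.seed)
    lengths = cfg.box.lengths
    pcoords = protein.positions
    extent = pcoords.max(axis=0) - pcoords.min(axis=0)
    if np.any(extent + 2 * cfg.excluded_radius >= lengths):
        raise ValueError("box too small for the protein plus excluded volume")
    centred = pcoords - pcoords.mean(axis=0) + lengths / 2.0

    patch_com = None
    if cfg.patch_bond is not None:
        shifted = protein.with_positions(centred)
        bonds = detect_disulfides(shifted)
        match = [b for b in bonds if b.label == cfg.patch_bond]
        if not match:
            raise ValueError(f"patch bond {cfg.patch_bond!r} not found "
                             f"(have {[b.label for b in bonds]})")
        sg = match[0].sg_indices
        patch_com = mass_weighted_com(centred[list(sg)],
                                      protein.masses[list(sg)], cfg.box)

    def clash(pos: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(
            min_image_displacement(pos[:, None, :], centred[None, :, :], lengths),
            axis=-1)
        return d.min(axis=1) < cfg.excluded_radius

    def bias_u(pos: np.ndarray) -> np.ndarray:
        if patch_com is None:
            return np.zeros(len(pos))
        d = np.linalg.norm(min_image_displacement(pos, patch_com, lengths), axis=-1)
        return -cfg.patch_strength * np.exp(-d ** 2 / (2 * cfg.patch_width ** 2))

    # initial placement: uniform over the accessible volume
    probe_pos = np.empty((cfg.n_probes, 3))
    placed = 0
    while placed < cfg.n_probes:
        cand = rng.uniform(0, 1, (cfg.n_probes, 3)) * lengths
        ok = ~clash(cand)
        take = min(int(ok.sum()), cfg.n_probes - placed)
        probe_pos[placed:placed + take] = cand[ok][:take]
        placed += take

    mass = PROBE_MASSES.get(cfg.probe_resname.upper(), 100.0)
    atoms = [Atom(a.index, a.name, a.element, a.mass, a.residue_name,
                  a.residue_id, a.chain_id, centred[a.index])
             for a in protein.atoms]
    n0 = len(atoms)
    max_rid = max(a.residue_id for a in protein.atoms)
    for k in range(cfg.n_probes):
        atoms.append(Atom(n0 + k, "P", "P", mass, cfg.probe_resname,
                          max_rid + 1 + k, "X", probe_pos[k]))
    topology = Structure(atoms, box=cfg.box, title="probe diffusion system")

    u_cur = bias_u(probe_pos)

    def sweep() -> None:
        nonlocal probe_pos, u_cur
        trial = np.mod(probe_pos + rng.normal(0, cfg.step_size,
                                              (cfg.n_probes, 3)), lengths)
        u_new = bias_u(trial)
        metro = rng.uniform(0, 1, cfg.n_probes) < np.exp(
            np.minimum(0.0, u_cur - u_new))
        accept = metro & ~clash(trial)
        probe_pos[accept] = trial[accept]
        u_cur[accept] = u_new[accept]

    # equilibrate the probe distribution under the bias before recording,
    # as production runs follow equilibration
    for _ in range(cfg.burn_in_moves):
        sweep()

    frames = np.empty((cfg.n_frames, len(atoms), 3))
    frames[:, :n0, :] = centred[None, :, :]
    frames[0, n0:, :] = probe_pos
    for f in range(1, cfg.n_frames):
        for _ in range(cfg.moves_per_frame):
            sweep()
        frames[f, n0:, :] = probe_pos
    times = np.arange(cfg.n_frames) * cfg.frame_interval
    return Trajectory(topology=topology, frames=frames, times=times,
                      box_per_frame=[cfg.box] * cfg.n_frames)


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-trajectory seeds below 2**31."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def simulate_experiment(protein: Structure, cfg: SimulatorConfig,
                        n_trajectories: int = 20,
                        seed: Optional[int] = None) -> list[Trajectory]:
    """Independent replicate trajectories (the >= 20 of the study design)."""
    from dataclasses import replace
    base = cfg.seed if seed is None else seed
    return [simulate_probe_diffusion(protein, replace(cfg, seed=s))
            for s in child_seeds(base, n_trajectories)]


def synthetic_peak_table(fractions: dict[str, float], seed: int = 0,
                         n_replicates: int = 9, noise_sd: float = 0.05,
                         n_controls: int = 4,
                         control_fraction: float = 0.02) -> pd.DataFrame:
    """Peak-area table with designed per-cysteine reduction fractions.

    Areas are drawn as base x fraction x lognormal(0, noise_sd); the control
    sample uses ``control_fraction`` for every cysteine.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def noise() -> float:
        return float(np.exp(rng.normal(0.0, noise_sd)))

    for rep in range(1, n_replicates + 1):
        for c in range(1, n_controls + 1):
            base = 1.0e6 * (1 + 0.1 * c)
            for sample in ("control", "treated", "fully_reduced"):
                rows.append({"peptide_id": f"ctrl{c}", "cysteine_label": "",
                             "is_control": True, "sample": sample,
                             "replicate_id": rep,
                             "precursor_area": base * noise()})
        for label, frac in fractions.items():
            base = 5.0e5
            for sample, f in (("control", control_fraction), ("treated", frac),
                              ("fully_reduced", 1.0)):
                rows.append({"peptide_id": f"pep_{label}", "cysteine_label": label,
                             "is_control": False, "sample": sample,
                             "replicate_id": rep,
                             "precursor_area": base * f * noise()})
    return pd.DataFrame(rows)


def known_answer_bundle(seed: int, out_dir: str, n_trajectories: int = 20,
                        spec: Optional[ToyProteinSpec] = None,
                        cfg: Optional[SimulatorConfig] = None,
                        write_trajectories: bool = True) -> dict:
    """Write the canonical ground-truth fixture set.

    Toy protein (two surface + one buried disulfide), ``n_trajectories``
    probe trajectories with the attraction patch on the first surface bond,
    a peak-area table whose designed reduction fraction is highest for the
    patched bond, and a JSON manifest of the ground truth.
    """
    from .io import write_structure, write_trajectory

    os.makedirs(out_dir, exist_ok=True)
    protein = build_toy_protein(spec, seed=seed)
    bonds = detect_disulfides(protein)
    surface_labels = [b.label for b in bonds
                      if protein.atoms[b.sg_indices[0]].position @
                      protein.atoms[b.sg_indices[0]].position > 0.25]
    patched = surface_labels[0]
    cfg = cfg or SimulatorConfig(patch_bond=patched, seed=seed)
    if cfg.patch_bond is None:
        from dataclasses import replace
        cfg = replace(cfg, patch_bond=patched)

    top_path = os.path.join(out_dir, "topology.pdb")
    traj_paths = []
    trajectories = simulate_experiment(protein, cfg, n_trajectories, seed=seed)
    write_structure(trajectories[0].topology, top_path, format="PDB")
    if write_trajectories:
        for i, traj in enumerate(trajectories):
            p = os.path.join(out_dir, f"traj_{i:02d}.xtc")
            write_trajectory(traj, p, format="XTC")
            traj_paths.append(p)

    fractions = {b.label: (0.8 if b.label == cfg.patch_bond else 0.05)
                 for b in bonds}
    ms = synthetic_peak_table(fractions, seed=seed)
    ms_path = os.path.join(out_dir, "peak_areas.csv")
    ms.to_csv(ms_path, index=False)

    manifest = {
        "seed": seed,
        "patched_bond": cfg.patch_bond,
        "bonds": [b.label for b in bonds],
        "designed_reduction_fractions": fractions,
        "n_trajectories": n_trajectories,
        "probe_resname": cfg.probe_resname,
        "topology": os.path.basename(top_path),
        "trajectories": [os.path.basename(p) for p in traj_paths],
        "peak_table": os.path.basename(ms_path),
        "expected_ranking_first": cfg.patch_bond,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def generate_probe_conformer(name: str = "TCEP", seed: int = 0) -> Structure:
    """3D conformer of a real reducing agent (distance-geometry embedding plus
    MMFF relaxation), as a Structure in nm with per-atom masses."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    key = name.upper()
    smiles = PROBE_SMILES.get(key, name)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse probe {name!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1) or 1
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"conformer embedding failed for {name!r}")
    AllChem.MMFFOptimizeMolecule(mol)
    conf = mol.GetConformer()
    atoms = []
    for i, atom in enumerate(mol.GetAtoms()):
        p = conf.GetAtomPosition(i)
        atoms.append(Atom(i, f"{atom.GetSymbol()}{i+1}", atom.GetSymbol().upper()
                          if len(atom.GetSymbol()) > 1 else atom.GetSymbol(),
                          atom.GetMass(), key[:4], 1, "A",
                          np.array([p.x, p.y, p.z]) * 0.1))
    return Structure(atoms, box=None, title=f"{key} conformer (seed {seed})")


def probe_radius_of_gyration(name: str = "TCEP", seed: int = 0) -> float:
    """Mass-weighted Rg (nm) of a generated conformer of TCEP or DTT."""
    s = generate_probe_conformer(name, seed)
    return radius_of_gyration(s.positions, s.masses)
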