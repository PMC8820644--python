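"""Structure and trajectory I/O.

Reading and writing of PDB/GRO structures and multi-model-PDB/XTC/DCD/TRR
trajectories is delegated to MDAnalysis; this module converts between its
Angstrom-based universes and the nm-based :class:`~redoxscan.model.Structure`
and :class:`~redoxscan.model.Trajectory` containers.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from typing import Optional

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .model import Atom, Box, Structure, Trajectory, element_from_name, mass_of_element

_NM_PER_ANGSTROM = 0.1

_FORMAT_ALIASES = {
    "PDB": "PDB", "GRO": "GRO", "MULTIPDB": "PDB",
    "XTC": "XTC", "DCD": "DCD", "TRR": "TRR",
}


def _check_orthorhombic(dimensions) -> Optional[Box]:
    if dimensions is None:
        return None
    dims = np.asarray(dimensions, dtype=float)
    if np.allclose(dims[:3], 0):
        return None
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise ValueError(
            f"triclinic box (angles {dims[3:]}) not supported; only orthorhombic boxes")
    return Box(dims[:3] * _NM_PER_ANGSTROM)


def _universe_to_structure(u: "mda.Universe", mass_overrides=None, title: str = "") -> Structure:
    ag = u.atoms
    n = len(ag)
    try:
        elements = [str(e).capitalize() for e in ag.elements]
        if any(not e.strip() for e in elements):
            raise mda.exceptions.NoDataError("blank element fields")
    except Exception:
        elements = None
    names = ag.names
    if elements is None:
        warnings.warn("no element records; inferring elements from atom names")
        elements = [element_from_name(str(nm)) for nm in names]
    resids = ag.resids
    resnames = ag.resnames
    try:
        chains = ag.chainIDs
    except Exception:
        try:
            chains = ag.segids
        except Exception:
            chains = [""] * n
    coords = ag.positions * _NM_PER_ANGSTROM
    atoms = [
        Atom(index=i, name=str(names[i]), element=elements[i],
             mass=mass_of_element(elements[i], mass_overrides),
             residue_name=str(resnames[i]), residue_id=int(resids[i]),
             chain_id=str(chains[i]).strip(), position=coords[i])
        for i in range(n)
    ]
    return Structure(atoms, box=_check_orthorhombic(u.dimensions), title=title)


def read_structure(path: str, format: Optional[str] = None,
                   mass_overrides: Optional[dict[str, float]] = None) -> Structure:
    """Read a PDB or GRO file into a Structure (coordinates converted to nm)."""
    fmt = _FORMAT_ALIASES.get(format.upper()) if format else None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path, format=fmt) if fmt else mda.Universe(path)
    except Exception as exc:  # normalise parser failures
        raise ValueError(f"cannot parse structure file {path!r}: {exc}") from exc
    return _universe_to_structure(u, mass_overrides, title=os.path.basename(path))


def structure_to_universe(s: Structure) -> "mda.Universe":
    """Build an in-memory MDAnalysis universe mirroring a Structure (positions in A)."""
    res_keys = s.residues()
    res_index_of: dict[tuple, int] = {key: i for i, (key, _) in enumerate(res_keys)}
    atom_resindex = np.array(
        [res_index_of[(a.chain_id, a.residue_id, a.residue_name)] for a in s.atoms])
    n_res = len(res_keys)
    u = mda.Universe.empty(
        n_atoms=s.n_atoms, n_residues=n_res, n_segments=1,
        atom_resindex=atom_resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in s.atoms])
    u.add_TopologyAttr("elements", [a.element for a in s.atoms])
    u.add_TopologyAttr("masses", [a.mass for a in s.atoms])
    u.add_TopologyAttr("resnames", [key[2] for key, _ in res_keys])
    u.add_TopologyAttr("resids", [key[1] for key, _ in res_keys])
    u.add_TopologyAttr("chainIDs", [a.chain_id or "A" for a in s.atoms])
    u.add_TopologyAttr("segids", ["SYS"])
    u.add_TopologyAttr("occupancies", np.ones(s.n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(s.n_atoms))
    u.atoms.positions = s.positions / _NM_PER_ANGSTROM
    if s.box is not None:
        u.dimensions = np.concatenate([s.box.lengths / _NM_PER_ANGSTROM, [90, 90, 90]])
    return u


def write_structure(s: Structure, path: str, format: Optional[str] = None) -> None:
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).upper()
    u = structure_to_universe(s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=s.n_atoms,
                        format=_FORMAT_ALIASES.get(fmt, fmt)) as w:
            w.write(u.atoms)


def read_trajectory(path: str, topology: Structure,
                    format: Optional[str] = None) -> Trajectory:
    """Read a multi-model PDB / XTC / DCD / TRR trajectory over a known topology."""
    fmt = _FORMAT_ALIASES.get(format.upper()) if format else None
    with tempfile.TemporaryDirectory() as tmp:
        top_path = os.path.join(tmp, "topology.pdb")
        write_structure(topology, top_path, format="PDB")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u = (mda.Universe(top_path, path, format=fmt) if fmt
                     else mda.Universe(top_path, path))
        except Exception as exc:
            raise ValueError(f"cannot read trajectory {path!r}: {exc}") from exc
        if len(u.atoms) != topology.n_atoms:
            raise ValueError(
                f"trajectory atom count {len(u.atoms)} != topology {topology.n_atoms}")
        frames, times, boxes = [], [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for ts in u.trajectory:
                frames.append(u.atoms.positions * _NM_PER_ANGSTROM)
                times.append(float(ts.time))
                box = _check_orthorhombic(ts.dimensions)
                boxes.append(box if box is not None else topology.box)
    if not frames:
        raise ValueError(f"trajectory {path!r} contains zero frames")
    times_arr = np.asarray(times, dtype=float)
    if len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0):
        times_arr = np.arange(len(frames), dtype=float)
    return Trajectory(topology=topology, frames=np.asarray(frames),
                      times=times_arr, box_per_frame=boxes)


def write_trajectory(traj: Trajectory, path: str, format: Optional[str] = None) -> None:
    """Write frames as multi-model PDB or XTC/DCD/TRR."""
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).upper()
    fmt = _FORMAT_ALIASES.get(fmt, fmt)
    u = structure_to_universe(traj.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=traj.topology.n_atoms,
                        format=fmt, multiframe=True) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.frames[i] / _NM_PER_ANGSTROM
                box = traj.box_per_frame[i]
                if box is not None:
                    u.dimensions = np.concatenate(
                        [box.lengths / _NM_PER_ANGSTROM, [90, 90, 90]])
                u.trajectory.ts.time = traj.times[i]
                u.trajectory.ts.frame = i
                w.write(u.atoms)
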