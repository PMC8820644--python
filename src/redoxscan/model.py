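"""Core structural data model.

All coordinates are stored in nanometres; masses in atomic mass units.
Angstrom-based formats (PDB) are converted at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .pbc import min_image_distance

#: Atomic masses (amu) for the elements this toolkit encounters.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06, "CL": 35.45,
    "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845, "CU": 63.546,
    "ZN": 65.38, "SE": 78.971, "BR": 79.904, "I": 126.904,
}

_TWO_LETTER = {"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CU", "SE"}


class ProbeKind(str, Enum):
    TCEP = "TCEP"
    DTT = "DTT"
    CUSTOM = "custom"


def element_from_name(name: str) -> str:
    """Guess an element symbol from a PDB-style atom name.

    Digits and primes are stripped; a leading two-letter symbol is honoured
    only for the common hetero elements (CL, NA, ...), so 'CA' stays carbon
    (the alpha-carbon) as in standard protein naming.
    """
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    if stripped[:2] in _TWO_LETTER:
        return stripped[:2].capitalize()
    return stripped[0]


def mass_of_element(element: str, overrides: Optional[dict[str, float]] = None) -> float:
    key = element.upper()
    if overrides and element in overrides:
        return overrides[element]
    if overrides and key in {k.upper() for k in overrides}:
        for k, v in overrides.items():
            if k.upper() == key:
                return v
    if key not in ELEMENT_MASSES:
        raise KeyError(
            f"unknown element {element!r}; supply a mass override map to read it"
        )
    return ELEMENT_MASSES[key]


@dataclass
class Atom:
    """A single atom: identity, residue membership and position (nm)."""

    index: int
    name: str
    element: str
    mass: float
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.index}")
        if self.mass <= 0:
            raise ValueError(f"non-positive mass for atom {self.index}")


@dataclass
class Box:
    """Orthorhombic periodic box with edge lengths in nm."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.shape != (3,):
            raise ValueError("box lengths must be a 3-vector")
        if not np.all(self.lengths > 0):
            raise ValueError("box lengths must be positive")

    @classmethod
    def cubic(cls, side: float) -> "Box":
        return cls(np.full(3, float(side)))


class Structure:
    """An ordered collection of atoms with an optional periodic box."""

    def __init__(self, atoms: Sequence[Atom], box: Optional[Box] = None, title: str = ""):
        self.atoms = list(atoms)
        for i, a in enumerate(self.atoms):
            if a.index != i:
                raise ValueError("atom indices must be contiguous from 0")
        self.box = box
        self.title = title
        self._positions: Optional[np.ndarray] = None
        self._masses: Optional[np.ndarray] = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        if self._positions is None:
            self._positions = np.array([a.position for a in self.atoms], dtype=float)
        return self._positions

    @positions.setter
    def positions(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for a, xyz in zip(self.atoms, coords):
            a.position = xyz.copy()
        self._positions = coords.copy()

    @property
    def masses(self) -> np.ndarray:
        if self._masses is None:
            self._masses = np.array([a.mass for a in self.atoms], dtype=float)
        return self._masses

    def with_positions(self, coords: np.ndarray) -> "Structure":
        """A copy of this structure carrying the given coordinates."""
        coords = np.asarray(coords, dtype=float)
        atoms = [
            Atom(a.index, a.name, a.element, a.mass, a.residue_name,
                 a.residue_id, a.chain_id, xyz.copy())
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms, box=self.box, title=self.title)

    def residues(self) -> list[tuple[tuple[str, int, str], list[int]]]:
        """Group atom indices by (chain_id, residue_id, residue_name), file order."""
        out: list[tuple[tuple[str, int, str], list[int]]] = []
        seen: dict[tuple[str, int, str], list[int]] = {}
        for a in self.atoms:
            key = (a.chain_id, a.residue_id, a.residue_name)
            if key not in seen:
                seen[key] = []
                out.append((key, seen[key]))
            seen[key].append(a.index)
        return out

    def find_atom(self, chain_id: str, residue_id: int, name: str) -> Optional[int]:
        for a in self.atoms:
            if a.chain_id == chain_id and a.residue_id == residue_id and a.name == name:
                return a.index
        return None

    def metadata(self) -> dict:
        """JSON-serializable summary (no coordinates)."""
        return {
            "title": self.title,
            "n_atoms": self.n_atoms,
            "box_nm": None if self.box is None else self.box.lengths.tolist(),
            "n_residues": len(self.residues()),
        }


@dataclass
class Trajectory:
    """Frames of coordinates (nm) over a fixed topology."""

    topology: Structure
    frames: np.ndarray          # (n_frames, n_atoms, 3) nm
    times: np.ndarray           # ps
    box_per_frame: list[Optional[Box]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError("every frame must have exactly n_atoms coordinates")
        if len(self.times) != len(self.frames):
            raise ValueError("times/frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not self.box_per_frame:
            self.box_per_frame = [self.topology.box] * self.n_frames

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_structure(self, i: int) -> Structure:
        s = self.topology.with_positions(self.frames[i])
        s.box = self.box_per_frame[i]
        return s


@dataclass
class DisulfideBond:
    """A cystine pair; the unit every lability criterion scores."""

    label: str
    sg_indices: tuple[int, int]
    ca_indices: tuple[Optional[int], Optional[int]]
    cb_indices: tuple[Optional[int], Optional[int]]
    residue_ids: tuple[int, int] = (0, 0)
    chain_ids: tuple[str, str] = ("", "")


@dataclass
class ProbeGroup:
    """Reducing-agent molecules, one atom-index set per molecule."""

    probe_kind: ProbeKind
    molecules: list[list[int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for mol in self.molecules:
            if not mol:
                raise ValueError("empty probe molecule")
            if seen.intersection(mol):
                raise ValueError("probe molecules must be disjoint")
            seen.update(mol)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)


_CYS_NAMES = {"CYS", "CYX", "CYS2"}


def detect_disulfides(s: Structure, sg_cutoff: float = 0.25) -> list[DisulfideBond]:
    """Pair cysteine SG atoms whose minimum-image distance is within ``sg_cutoff`` nm.

    Greedy nearest pairing (shortest SG-SG distances first, each SG used once);
    result sorted by the first residue id. An SG within the cutoff of two
    partners triggers a warning and keeps its nearest partner.
    """
    cys_sg: list[tuple[tuple[str, int], int]] = []
    for (chain, rid, rname), idxs in s.residues():
        if rname.upper() in _CYS_NAMES:
            for i in idxs:
                if s.atoms[i].name == "SG":
                    cys_sg.append(((chain, rid), i))
    pairs: list[tuple[float, int, int]] = []
    for a in range(len(cys_sg)):
        for b in range(a + 1, len(cys_sg)):
            ia, ib = cys_sg[a][1], cys_sg[b][1]
            d = min_image_distance(s.atoms[ia].position, s.atoms[ib].position,
                                   None if s.box is None else s.box.lengths)
            if d <= sg_cutoff:
                pairs.append((d, a, b))
    pairs.sort()
    partner_count: dict[int, int] = {}
    for _, a, b in pairs:
        partner_count[a] = partner_count.get(a, 0) + 1
        partner_count[b] = partner_count.get(b, 0) + 1
    for k, n in partner_count.items():
        if n > 1:
            chain, rid = cys_sg[k][0]
            warnings.warn(
                f"SG of Cys{rid} ({chain}) is within {sg_cutoff} nm of {n} partners; "
                "keeping the nearest", stacklevel=2)
    used: set[int] = set()
    bonds: list[DisulfideBond] = []
    for _, a, b in pairs:
        if a in used or b in used:
            continue
        used.update((a, b))
        (ch_a, rid_a), sg_a = cys_sg[a]
        (ch_b, rid_b), sg_b = cys_sg[b]
        if (rid_b, ch_b) < (rid_a, ch_a):
            (ch_a, rid_a, sg_a), (ch_b, rid_b, sg_b) = (ch_b, rid_b, sg_b), (ch_a, rid_a, sg_a)
        bonds.append(DisulfideBond(
            label=f"Cys{rid_a}-Cys{rid_b}",
            sg_indices=(sg_a, sg_b),
            ca_indices=(s.find_atom(ch_a, rid_a, "CA"), s.find_atom(ch_b, rid_b, "CA")),
            cb_indices=(s.find_atom(ch_a, rid_a, "CB"), s.find_atom(ch_b, rid_b, "CB")),
            residue_ids=(rid_a, rid_b),
            chain_ids=(ch_a, ch_b),
        ))
    bonds.sort(key=lambda b: (b.residue_ids[0], b.residue_ids[1], b.chain_ids))
    return bonds


def select_probes(s: Structure, residue_names: Iterable[str]) -> ProbeGroup:
    """One probe molecule per residue instance whose name matches.

    The probe kind is inferred when every matched residue name maps to a known
    reducing agent (TCEP/DTT); anything else is ``custom``.
    """
    wanted = {n.upper() for n in residue_names}
    molecules: list[list[int]] = []
    matched_names: set[str] = set()
    for (chain, rid, rname), idxs in s.residues():
        if rname.upper() in wanted:
            molecules.append(list(idxs))
            matched_names.add(rname.upper())
    if matched_names == {"TCEP"}:
        kind = ProbeKind.TCEP
    elif matched_names == {"DTT"}:
        kind = ProbeKind.DTT
    else:
        kind = ProbeKind.CUSTOM
    return ProbeGroup(probe_kind=kind, molecules=molecules)
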