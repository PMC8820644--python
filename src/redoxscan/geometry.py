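"""Static disulfide geometry: solvent accessibility, Ca-Ca distance, the five
chi dihedrals of a cystine and its 20-class conformation label.

Distances and areas are reported in Angstrom / Angstrom^2, matching how these
parameters are conventionally tabulated; internal coordinates stay in nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model import DisulfideBond, Structure, detect_disulfides

_A_PER_NM = 10.0


def _load_json(name: str) -> dict:
    with resources.files("redoxscan.data").joinpath(name).open() as fh:
        return json.load(fh)


_CLASS_TABLE: Optional[dict[str, str]] = None
_VDW: Optional[dict[str, float]] = None


def conformation_class_table() -> dict[str, str]:
    """Sign-vector (chi1 chi2 chi3 chi2' chi1') -> class-label mapping, shipped
    as an auditable data table."""
    global _CLASS_TABLE
    if _CLASS_TABLE is None:
        _CLASS_TABLE = _load_json("disulfide_classes.json")["classes"]
    return _CLASS_TABLE


def vdw_radius(element: str, overrides: Optional[dict[str, float]] = None) -> float:
    global _VDW
    if _VDW is None:
        _VDW = _load_json("vdw_radii.json")
    if overrides:
        for k, v in overrides.items():
            if k.upper() == element.upper():
                return v
    key = element.upper()
    if key not in _VDW:
        raise KeyError(f"no van der Waals radius for element {element!r}; "
                       "pass radius overrides")
    return _VDW[key]


@dataclass
class DihedralSet:
    chi1: float
    chi2: float
    chi3: float
    chi2p: float
    chi1p: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.chi1, self.chi2, self.chi3, self.chi2p, self.chi1p)


@dataclass
class ConformationClass:
    label: str
    sign_vector: tuple[str, str, str, str, str]


@dataclass
class GeometryRecord:
    bond: str
    sasa: float          # A^2, both SG atoms
    ca_distance: float   # A
    dihedrals: DihedralSet
    conformation: ConformationClass


def calpha_distance(s: Structure, bond: DisulfideBond) -> float:
    """Ca-Ca separation of the two cysteines in Angstrom (no PBC: single molecule)."""
    ia, ib = bond.ca_indices
    if ia is None or ib is None:
        raise ValueError(f"bond {bond.label} is missing a CA atom")
    return float(np.linalg.norm(s.positions[ia] - s.positions[ib])) * _A_PER_NM


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees, IUPAC convention, in (-180, 180])."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = -np.degrees(np.arctan2(y, x))
    return float(180.0 if np.isclose(ang, -180.0) else ang)


def chi_dihedrals(s: Structure, bond: DisulfideBond) -> DihedralSet:
    """chi1 = N-CA-CB-SG, chi2 = CA-CB-SG-SG', chi3 = CB-SG-SG'-CB', and the
    mirrored chi2', chi1' on the partner cysteine."""
    pos = s.positions

    def atom(cys: int, name: str) -> np.ndarray:
        rid = bond.residue_ids[cys]
        chain = bond.chain_ids[cys]
        idx = s.find_atom(chain, rid, name)
        if idx is None:
            raise ValueError(f"bond {bond.label}: missing atom {name} on Cys{rid}")
        return pos[idx]

    n0, ca0, cb0, sg0 = (atom(0, nm) for nm in ("N", "CA", "CB", "SG"))
    n1, ca1, cb1, sg1 = (atom(1, nm) for nm in ("N", "CA", "CB", "SG"))
    return DihedralSet(
        chi1=dihedral_angle(n0, ca0, cb0, sg0),
        chi2=dihedral_angle(ca0, cb0, sg0, sg1),
        chi3=dihedral_angle(cb0, sg0, sg1, cb1),
        chi2p=dihedral_angle(ca1, cb1, sg1, sg0),
        chi1p=dihedral_angle(n1, ca1, cb1, sg1),
    )


def classify_conformation(d: DihedralSet) -> ConformationClass:
    """Map the five dihedral signs to one of the 20 disulfide conformation
    classes (RH/LH from chi3; Spiral/Hook/Staple and the -, +, +/- prefixes
    from the remaining signs, via the shipped mapping table)."""
    values = d.as_tuple()
    if any(v == 0.0 for v in values):
        return ConformationClass(label="unclassifiable",
                                 sign_vector=tuple("0" if v == 0 else
                                                   ("-" if v < 0 else "+")
                                                   for v in values))
    signs = tuple("-" if v < 0 else "+" for v in values)
    label = conformation_class_table()["".join(signs)]
    return ConformationClass(label=label, sign_vector=signs)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def shrake_rupley_sasa(s: Structure, probe_radius: float = 1.4,
                       n_points: int = 960,
                       radius_overrides: Optional[dict[str, float]] = None
                       ) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2) by sphere-point sampling.

    Each atom's solvent sphere (vdW radius + probe) is sampled with a golden
    spiral; points occluded by any neighbour's solvent sphere are discarded and
    the surviving fraction scales the sphere area.
    """
    n = s.n_atoms
    coords = s.positions * _A_PER_NM
    radii = np.array([vdw_radius(a.element, radius_overrides) for a in s.atoms])
    ext = radii + probe_radius
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_ext = ext.max()
    areas = np.zeros(n)
    for i in range(n):
        neigh = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext)
                 if j != i and np.linalg.norm(coords[j] - coords[i]) < ext[i] + ext[j]]
        surface = coords[i] + ext[i] * pts
        free = np.ones(n_points, dtype=bool)
        for j in neigh:
            free &= np.linalg.norm(surface - coords[j], axis=1) >= ext[j]
            if not free.any():
                break
        areas[i] = free.mean() * 4.0 * np.pi * ext[i] ** 2
    return areas


def disulfide_sasa(s: Structure, bond: DisulfideBond,
                   per_atom_sasa: Optional[np.ndarray] = None,
                   whole_cystine: bool = False, **sasa_kw) -> float:
    """Accessibility of a disulfide (A^2): sum of the two SG atoms' SASA by
    default, or of every atom of both cysteines in whole-cystine mode."""
    if per_atom_sasa is None:
        per_atom_sasa = shrake_rupley_sasa(s, **sasa_kw)
    if whole_cystine:
        idx = [a.index for a in s.atoms
               if (a.chain_id, a.residue_id) in set(zip(bond.chain_ids,
                                                        bond.residue_ids))]
    else:
        idx = list(bond.sg_indices)
    return float(per_atom_sasa[idx].sum())


def geometry_table(s: Structure, bonds: Optional[Sequence[DisulfideBond]] = None,
                   n_points: int = 960) -> list[GeometryRecord]:
    """One record per disulfide: SASA, Ca-Ca distance, dihedrals, conformation."""
    if bonds is None:
        bonds = detect_disulfides(s)
    if not bonds:
        return []
    per_atom = shrake_rupley_sasa(s, n_points=n_points)
    records = []
    for b in bonds:
        dih = chi_dihedrals(s, b)
        records.append(GeometryRecord(
            bond=b.label,
            sasa=disulfide_sasa(s, b, per_atom_sasa=per_atom),
            ca_distance=calpha_distance(s, b),
            dihedrals=dih,
            conformation=classify_conformation(dih),
        ))
    return records


def geometry_records_to_rows(records: Sequence[GeometryRecord]) -> list[dict]:
    return [{
        "bond": r.bond, "sasa_A2": r.sasa, "ca_dist_A": r.ca_distance,
        "chi1": r.dihedrals.chi1, "chi2": r.dihedrals.chi2,
        "chi3": r.dihedrals.chi3, "chi2p": r.dihedrals.chi2p,
        "chi1p": r.dihedrals.chi1p, "conformation": r.conformation.label,
    } for r in records]
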