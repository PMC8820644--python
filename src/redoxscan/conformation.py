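"""Trajectory-level conformational analytics.

Time series of radius of gyration, intramolecular hydrogen bonds, solvent
accessible surface area and backbone RMSD; greedy neighbour-count (Daura)
clustering of frames under a pairwise backbone-RMSD cutoff; representative
(most-sampled) conformations; and per-residue deviation maps between two
representative structures after whole-structure or per-domain superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import shrake_rupley_sasa
from .model import Structure, Trajectory

BACKBONE_NAMES = ("N", "CA", "C")


@dataclass
class TimeSeriesReport:
    times: np.ndarray
    rg: np.ndarray
    hb_count: np.ndarray
    sasa: np.ndarray               # nm^2
    rmsd_to_reference: np.ndarray  # nm


@dataclass
class ClusterResult:
    assignments: np.ndarray        # frame -> cluster id (0 = largest)
    cluster_sizes: list[int]
    centroid_frames: list[int]
    cutoff: float
    selection: tuple[str, ...] = BACKBONE_NAMES


@dataclass
class ResidueDeviationMap:
    residue_ids: list[int]
    deviations: np.ndarray         # nm, per residue
    alignment_mode: str = "whole"
    domains: list[tuple[int, int]] = field(default_factory=list)


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted RMS distance of the atoms from their centre of mass (nm)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    com = (coords * masses[:, None]).sum(axis=0) / total
    return float(np.sqrt((masses * ((coords - com) ** 2).sum(axis=1)).sum() / total))


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid superposition (SVD/Kabsch).  Returns the transformed
    mobile coordinates and the (rotation, translation) pair."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError("selection size mismatch")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (mobile - mc) @ rot.T + tc
    return moved, (rot, tc - rot @ mc)


def backbone_rmsd(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """RMSD (nm) after optimal rigid superposition; symmetric in its arguments."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    moved, _ = kabsch_superpose(a, b)
    return float(np.sqrt(((moved - b) ** 2).sum(axis=1).mean()))


def backbone_indices(s: Structure, names: Sequence[str] = BACKBONE_NAMES,
                     protein_only: bool = True) -> np.ndarray:
    wanted = set(names)
    skip = {"TCEP", "DTT", "SOL", "HOH", "WAT", "NA", "CL"}
    return np.array([a.index for a in s.atoms
                     if a.name in wanted
                     and (not protein_only or a.residue_name.upper() not in skip)],
                    dtype=int)


def hydrogen_bond_count(frame: np.ndarray,
                        donor_h_pairs: Sequence[tuple[int, int]],
                        acceptors: Sequence[int],
                        d_cut: float = 0.35, angle_cut: float = 30.0) -> int:
    """Geometric hydrogen-bond count: donor-acceptor distance <= d_cut (nm)
    and H-D-A angle (at the donor) <= angle_cut degrees."""
    frame = np.asarray(frame, dtype=float)
    acceptors = np.asarray(list(acceptors), dtype=int)
    if len(donor_h_pairs) == 0 or acceptors.size == 0:
        return 0
    count = 0
    acc_pos = frame[acceptors]
    for d_idx, h_idx in donor_h_pairs:
        da = acc_pos - frame[d_idx]
        dist = np.linalg.norm(da, axis=1)
        ok = (dist <= d_cut) & (acceptors != d_idx) & (acceptors != h_idx)
        if not ok.any():
            continue
        dh = frame[h_idx] - frame[d_idx]
        dh = dh / np.linalg.norm(dh)
        cosang = (da[ok] @ dh) / dist[ok]
        angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        count += int((angles <= angle_cut).sum())
    return count


def pairwise_rmsd_matrix(frames: np.ndarray) -> np.ndarray:
    n = len(frames)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = backbone_rmsd(frames[i], frames[j])
    return mat


def daura_cluster(frames: np.ndarray, cutoff: float = 0.2,
                  selection: Sequence[str] = BACKBONE_NAMES) -> ClusterResult:
    """Greedy neighbour-count clustering: the frame with the most neighbours
    (pairwise RMSD < cutoff) seeds a cluster, it and its neighbours are
    removed, and the procedure repeats.  Ties break on the lowest frame index,
    making the assignment deterministic.
    """
    frames = np.asarray(frames, dtype=float)
    n = len(frames)
    if n == 0:
        raise ValueError("need at least one frame")
    mat = pairwise_rmsd_matrix(frames)
    neighbours = mat < cutoff
    np.fill_diagonal(neighbours, True)
    remaining = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    centroids: list[int] = []
    sizes: list[int] = []
    cid = 0
    while remaining.any():
        counts = (neighbours & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        centre = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(neighbours[centre] & remaining)[0]
        assignments[members] = cid
        centroids.append(centre)
        sizes.append(len(members))
        remaining[members] = False
        cid += 1
    order = sorted(range(cid), key=lambda c: (-sizes[c], centroids[c]))
    relabel = {old: new for new, old in enumerate(order)}
    assignments = np.array([relabel[a] for a in assignments])
    return ClusterResult(
        assignments=assignments,
        cluster_sizes=[sizes[c] for c in order],
        centroid_frames=[centroids[c] for c in order],
        cutoff=cutoff, selection=tuple(selection))


def representative_frame(traj: Trajectory, discard_ps: float = 0.0,
                         cutoff: float = 0.2,
                         selection: Sequence[str] = BACKBONE_NAMES) -> int:
    """Centroid of the largest cluster over the equilibrated window (frames
    after the first ``discard_ps``); returns an index into the full trajectory."""
    keep = np.nonzero(traj.times - traj.times[0] >= discard_ps)[0]
    if keep.size == 0:
        raise ValueError("discard window longer than the trajectory")
    sel = backbone_indices(traj.topology, selection)
    sub = traj.frames[keep][:, sel, :]
    result = daura_cluster(sub, cutoff=cutoff, selection=selection)
    return int(keep[result.centroid_frames[0]])


def _ca_by_residue(s: Structure) -> tuple[list[int], np.ndarray]:
    rids, coords = [], []
    for (chain, rid, rname), idxs in s.residues():
        for i in idxs:
            if s.atoms[i].name == "CA":
                rids.append(rid)
                coords.append(s.positions[i])
                break
    return rids, np.asarray(coords)


def per_residue_deviation(rep_a: Structure, rep_b: Structure,
                          mode: str = "whole",
                          domains: Optional[Sequence[tuple[int, int]]] = None
                          ) -> ResidueDeviationMap:
    """Per-residue Ca displacement (nm) between two structures after rigid
    superposition on the whole molecule or independently per domain range."""
    rids_a, ca_a = _ca_by_residue(rep_a)
    rids_b, ca_b = _ca_by_residue(rep_b)
    if rids_a != rids_b:
        raise ValueError("residue sequences do not match")
    if mode == "whole":
        moved, _ = kabsch_superpose(ca_a, ca_b)
        dev = np.linalg.norm(moved - ca_b, axis=1)
        used_domains: list[tuple[int, int]] = []
    elif mode == "per_domain":
        if not domains:
            raise ValueError("per_domain mode needs domain residue ranges")
        dev = np.full(len(rids_a), np.nan)
        rid_arr = np.asarray(rids_a)
        for lo, hi in domains:
            mask = (rid_arr >= lo) & (rid_arr <= hi)
            if mask.sum() < 3:
                continue
            moved, _ = kabsch_superpose(ca_a[mask], ca_b[mask])
            dev[mask] = np.linalg.norm(moved - ca_b[mask], axis=1)
        used_domains = [tuple(d) for d in domains]
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")
    return ResidueDeviationMap(residue_ids=rids_a, deviations=dev,
                               alignment_mode=mode, domains=used_domains)


def time_series(traj: Trajectory, reference: Optional[Structure] = None,
                donor_h_pairs: Sequence[tuple[int, int]] = (),
                acceptors: Sequence[int] = (),
                sasa_points: int = 120, sasa_stride: int = 1,
                hb_d_cut: float = 0.35, hb_angle_cut: float = 30.0
                ) -> TimeSeriesReport:
    """Rg / hydrogen-bond / SASA / backbone-RMSD series over a trajectory.

    SASA uses a reduced default quadrature (its per-frame cost dominates);
    pass ``sasa_points=960`` for table-quality values.
    """
    top = traj.topology
    masses = top.masses
    sel = backbone_indices(top)
    ref = reference if reference is not None else traj.frame_structure(0)
    ref_bb = ref.positions[backbone_indices(ref)] if reference is not None \
        else traj.frames[0][sel]
    rg = np.array([radius_of_gyration(f, masses) for f in traj.frames])
    hb = np.array([hydrogen_bond_count(f, donor_h_pairs, acceptors,
                                       hb_d_cut, hb_angle_cut)
                   for f in traj.frames])
    rmsd = np.array([backbone_rmsd(f[sel], ref_bb) for f in traj.frames])
    sasa = np.empty(traj.n_frames)
    last = None
    for i in range(traj.n_frames):
        if i % sasa_stride == 0 or last is None:
            per_atom = shrake_rupley_sasa(traj.frame_structure(i),
                                          n_points=sasa_points)
            last = per_atom.sum() / 100.0  # A^2 -> nm^2
        sasa[i] = last
    return TimeSeriesReport(times=traj.times.copy(), rg=rg, hb_count=hb,
                            sasa=sasa, rmsd_to_reference=rmsd)
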