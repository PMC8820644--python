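"""Probe-disulfide proximity statistics and the distance-based lability criterion.

A disulfide is called "reduced" in a trajectory as soon as the centre of mass
of a reducing-agent molecule (TCEP by default, cutoff 0.8 nm; DTT 0.6 nm)
comes within the contact cutoff of the disulfide COM.  Per-bond contact
statistics (mean/min distance, hard count within the cutoff, smooth
coordination number) summarise each trajectory; calls from an ensemble of
independent trajectories aggregate into per-bond reduction probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .model import Box, DisulfideBond, ProbeGroup, ProbeKind, Structure, Trajectory
from .pbc import mass_weighted_com, min_image_displacement

DEFAULT_CUTOFFS_NM = {ProbeKind.TCEP: 0.8, ProbeKind.DTT: 0.6}


@dataclass
class SwitchingParams:
    """Rational switching function parameters: s(r) = (1-(r/r0)^n)/(1-(r/r0)^m)."""

    r0: float = 3.0
    n: int = 6
    m: int = 12

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not (0 < self.n < self.m):
            raise ValueError("exponents must satisfy 0 < n < m")


class BondComMode(str, Enum):
    SG_ONLY = "SG_only"
    CYSTINE_RESIDUES = "cystine_residues"


@dataclass
class ProximityConfig:
    contact_cutoff: float = 0.8
    bond_com_mode: BondComMode = BondComMode.SG_ONLY
    frame_stride: int = 1
    switching: SwitchingParams = field(default_factory=SwitchingParams)

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be >= 1")

    @classmethod
    def for_probe(cls, kind: ProbeKind, **kw) -> "ProximityConfig":
        cutoff = kw.pop("contact_cutoff", DEFAULT_CUTOFFS_NM.get(kind, 0.8))
        return cls(contact_cutoff=cutoff, **kw)


@dataclass
class DistanceStats:
    bond: str
    per_frame_mean: np.ndarray
    per_frame_min: np.ndarray
    per_frame_count_within: np.ndarray
    per_frame_cn_soft: np.ndarray
    summary: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class ProximityEvent:
    frame_index: int
    time: float
    bond: str
    probe_index: int
    distance: float


@dataclass
class TrajectoryCall:
    trajectory_id: str
    called_bond: Optional[str]
    criterion: str
    event: Optional[ProximityEvent] = None
    energy_checks_failed: int = 0

    def __post_init__(self) -> None:
        if (self.called_bond is None) != (self.event is None):
            raise ValueError("called_bond and event must be both set or both absent")


@dataclass
class LabilityReport:
    per_bond_probability: dict[str, float]
    n_trajectories: int
    no_call_fraction: float
    criterion: str = "distance"

    def __post_init__(self) -> None:
        total = sum(self.per_bond_probability.values()) + self.no_call_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("probabilities and no-call fraction must sum to 1")


def switching_value(r, p: SwitchingParams):
    """Eq-2 style rational switching function, with the removable singularity
    at r = r0 evaluated as its limit n/m.  Vectorised over r."""
    r = np.asarray(r, dtype=float)
    x = r / p.r0
    num = 1.0 - x ** p.n
    den = 1.0 - x ** p.m
    limit = p.n / p.m
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(den) < 1e-12, limit, num / np.where(den == 0, 1.0, den))
    return float(out) if out.ndim == 0 else out


def coordination_number(groupA_coms, groupB_coms, p: SwitchingParams,
                        box: Optional[Box] = None) -> float:
    """Smooth count of B entities around A entities: double sum of the
    switching function over all minimum-image A-B distances."""
    a = np.atleast_2d(np.asarray(groupA_coms, dtype=float))
    b = np.atleast_2d(np.asarray(groupB_coms, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("coordination number needs non-empty groups")
    lengths = None if box is None else getattr(box, "lengths", box)
    d = np.linalg.norm(
        min_image_displacement(a[:, None, :], b[None, :, :], lengths), axis=-1)
    return float(np.sum(switching_value(d, p)))


def bond_com(structure_or_frame, bond: DisulfideBond, masses: np.ndarray,
             box: Optional[Box], mode: BondComMode = BondComMode.SG_ONLY,
             residue_indices: Optional[Sequence[int]] = None) -> np.ndarray:
    """COM of a disulfide: the two SG atoms (default) or both whole residues."""
    coords = structure_or_frame.positions if isinstance(structure_or_frame, Structure) \
        else np.asarray(structure_or_frame)
    if mode is BondComMode.SG_ONLY:
        idx = list(bond.sg_indices)
    else:
        if residue_indices is None:
            raise ValueError("cystine_residues mode needs residue atom indices")
        idx = list(residue_indices)
    return mass_weighted_com(coords[idx], masses[idx], box)


def _bond_atom_indices(traj: Trajectory, bonds: Sequence[DisulfideBond],
                       mode: BondComMode) -> list[list[int]]:
    if mode is BondComMode.SG_ONLY:
        return [list(b.sg_indices) for b in bonds]
    by_res: dict[tuple[str, int], list[int]] = {}
    for (chain, rid, _), idxs in traj.topology.residues():
        by_res[(chain, rid)] = idxs
    out = []
    for b in bonds:
        idx: list[int] = []
        for ch, rid in zip(b.chain_ids, b.residue_ids):
            idx.extend(by_res[(ch, rid)])
        out.append(idx)
    return out


def _probe_bond_distances(traj: Trajectory, bonds: Sequence[DisulfideBond],
                          probes: ProbeGroup, cfg: ProximityConfig):
    """Distance tensor (n_used_frames, n_probes, n_bonds) of probe-COM to
    bond-COM minimum-image distances, plus the frame indices used."""
    if probes.n_molecules == 0:
        raise ValueError("probe group is empty")
    masses = traj.topology.masses
    frame_ids = list(range(0, traj.n_frames, cfg.frame_stride))
    bond_idx = _bond_atom_indices(traj, bonds, cfg.bond_com_mode)
    singleton = all(len(m) == 1 for m in probes.molecules)
    probe_first = np.array([m[0] for m in probes.molecules])
    boxes = [traj.box_per_frame[fi] for fi in frame_ids]
    same_box = all(
        (b is None and boxes[0] is None)
        or (b is not None and boxes[0] is not None
            and np.array_equal(b.lengths, boxes[0].lengths)) for b in boxes)
    if (singleton and same_box and cfg.bond_com_mode is BondComMode.SG_ONLY):
        # vectorised fast path: per-frame SG-pair COMs and probe positions
        lengths = None if boxes[0] is None else boxes[0].lengths
        sub = traj.frames[frame_ids]                  # (F, n_atoms, 3)
        pcoms = sub[:, probe_first, :]                # (F, P, 3)
        bcoms = np.empty((len(frame_ids), len(bonds), 3))
        for j, b in enumerate(bonds):
            i1, i2 = b.sg_indices
            m1, m2 = masses[i1], masses[i2]
            disp = min_image_displacement(sub[:, i2, :], sub[:, i1, :], lengths)
            bcoms[:, j, :] = sub[:, i1, :] + (m2 / (m1 + m2)) * disp
        d = np.linalg.norm(
            min_image_displacement(pcoms[:, :, None, :], bcoms[:, None, :, :],
                                   lengths), axis=-1)
        return d, frame_ids
    dists = np.empty((len(frame_ids), probes.n_molecules, len(bonds)))
    for k, fi in enumerate(frame_ids):
        frame = traj.frames[fi]
        box = traj.box_per_frame[fi]
        lengths = None if box is None else box.lengths
        if singleton:
            pcoms = frame[probe_first]
        else:
            pcoms = np.array([
                mass_weighted_com(frame[m], masses[m], box) for m in probes.molecules])
        bcoms = np.array([
            mass_weighted_com(frame[idx], masses[idx], box) for idx in bond_idx])
        dists[k] = np.linalg.norm(
            min_image_displacement(pcoms[:, None, :], bcoms[None, :, :], lengths),
            axis=-1)
    return dists, frame_ids


def distance_stats(traj: Trajectory, bonds: Sequence[DisulfideBond],
                   probes: ProbeGroup, cfg: ProximityConfig) -> list[DistanceStats]:
    """Per-frame mean/min probe distance, hard contact count and smooth CN for
    each disulfide, with five-number (boxplot) summaries."""
    dists, _ = _probe_bond_distances(traj, bonds, probes, cfg)
    out = []
    for j, b in enumerate(bonds):
        d = dists[:, :, j]
        series = {
            "mean": d.mean(axis=1),
            "min": d.min(axis=1),
            "count_within": (d < cfg.contact_cutoff).sum(axis=1).astype(float),
            "cn_soft": switching_value(d, cfg.switching).sum(axis=1),
        }
        summary = {
            name: {
                "min": float(np.min(v)),
                "q1": float(np.percentile(v, 25)),
                "median": float(np.median(v)),
                "q3": float(np.percentile(v, 75)),
                "max": float(np.max(v)),
            } for name, v in series.items()
        }
        out.append(DistanceStats(
            bond=b.label,
            per_frame_mean=series["mean"],
            per_frame_min=series["min"],
            per_frame_count_within=series["count_within"].astype(int),
            per_frame_cn_soft=series["cn_soft"],
            summary=summary,
        ))
    return out


def iter_proximity_events(traj: Trajectory, bonds: Sequence[DisulfideBond],
                          probes: ProbeGroup, cfg: ProximityConfig):
    """Yield contact events (distance < cutoff) in time order; within a frame
    ordered by smallest distance, then bond order, then probe index."""
    dists, frame_ids = _probe_bond_distances(traj, bonds, probes, cfg)
    hit_frames = np.nonzero((dists < cfg.contact_cutoff).any(axis=(1, 2)))[0]
    for k in hit_frames:
        fi = frame_ids[k]
        pi, bi = np.nonzero(dists[k] < cfg.contact_cutoff)
        order = sorted(range(len(pi)),
                       key=lambda q: (dists[k, pi[q], bi[q]], bi[q], pi[q]))
        for q in order:
            yield ProximityEvent(
                frame_index=fi, time=float(traj.times[fi]),
                bond=bonds[bi[q]].label, probe_index=int(pi[q]),
                distance=float(dists[k, pi[q], bi[q]]))


def scan_distance_criterion(traj: Trajectory, bonds: Sequence[DisulfideBond],
                            probes: ProbeGroup, cfg: ProximityConfig,
                            trajectory_id: str = "traj") -> TrajectoryCall:
    """First-passage distance criterion: the earliest contact event calls the
    bond (one call per trajectory); no contact means no call."""
    for ev in iter_proximity_events(traj, bonds, probes, cfg):
        return TrajectoryCall(trajectory_id=trajectory_id, called_bond=ev.bond,
                              criterion="distance", event=ev)
    return TrajectoryCall(trajectory_id=trajectory_id, called_bond=None,
                          criterion="distance")


def aggregate_lability(calls: Sequence[TrajectoryCall]) -> LabilityReport:
    """Per-bond reduction probability = fraction of trajectories calling it."""
    if not calls:
        raise ValueError("need at least one trajectory call")
    criteria = {c.criterion for c in calls}
    if len(criteria) > 1:
        raise ValueError(f"cannot aggregate mixed criteria {sorted(criteria)}")
    n = len(calls)
    per_bond: dict[str, float] = {}
    n_none = 0
    for c in calls:
        if c.called_bond is None:
            n_none += 1
        else:
            per_bond[c.called_bond] = per_bond.get(c.called_bond, 0.0) + 1.0
    per_bond = {k: v / n for k, v in sorted(per_bond.items())}
    return LabilityReport(per_bond_probability=per_bond, n_trajectories=n,
                          no_call_fraction=n_none / n,
                          criterion=calls[0].criterion)
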