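"""Workflow assembly: validated run configuration, the multi-trajectory scan,
and the combined report, shared by the CLI and by library callers."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .energy import (EnergyBackend, always_accept_backend, always_reject_backend,
                     default_toy_forcefield, simple_ff_backend,
                     scan_distance_energy_criterion)
from .geometry import geometry_records_to_rows, geometry_table
from .io import read_structure, read_trajectory
from .model import Structure, detect_disulfides, select_probes
from .msquant import read_peak_table, summarize_table
from .proximity import (ProximityConfig, aggregate_lability,
                        distance_stats, scan_distance_criterion)

log = logging.getLogger("redoxscan")


class RunConfig(BaseModel):
    """Schema-validated scan configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    topology: str
    trajectories: list[str] = Field(default_factory=list)
    criterion: str = "distance"             # distance | distance_energy
    contact_cutoff: float = 0.8
    probe_residues: list[str] = Field(default_factory=lambda: ["TCEP"])
    energy_backend: str = "always_accept"   # always_accept | always_reject | simple_ff
    refractory_ps: float = 100.0
    frame_stride: int = 1
    sg_cutoff: float = 0.25
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(cfg.model_dump_json().encode()).hexdigest()[:12]


def _make_backend(name: str, topology: Structure,
                  probe_residues: Sequence[str]) -> EnergyBackend:
    if name == "always_accept":
        return always_accept_backend()
    if name == "always_reject":
        return always_reject_backend()
    if name == "simple_ff":
        from .synthetic import toy_topology_bonds
        probe_set = {r.upper() for r in probe_residues}
        protein_idx = [a.index for a in topology.atoms
                       if a.residue_name.upper() not in probe_set]
        return simple_ff_backend(default_toy_forcefield(),
                                 toy_topology_bonds(topology),
                                 protein_indices=protein_idx)
    raise ValueError(f"unknown energy backend {name!r}")


def run_scan(cfg: RunConfig, write_outputs: bool = True) -> dict:
    """Apply the chosen lability criterion to every trajectory and aggregate.

    Returns the report dict; optionally writes report.json, calls.json and a
    Fig-3-style per-bond contact summary CSV into the output directory.
    """
    logging.basicConfig(level=cfg.log_level)
    log.info("redoxscan %s | config %s | seed %d",
             __version__, config_hash(cfg), cfg.seed)
    if not cfg.trajectories:
        raise ValueError("at least one trajectory is required")
    topology = read_structure(cfg.topology)
    bonds = detect_disulfides(topology, sg_cutoff=cfg.sg_cutoff)
    if not bonds:
        raise ValueError("no disulfide bonds detected in the topology")
    prox = ProximityConfig(contact_cutoff=cfg.contact_cutoff,
                           frame_stride=cfg.frame_stride)
    calls = []
    stats_rows = []
    for i, path in enumerate(cfg.trajectories):
        traj = read_trajectory(path, topology)
        probes = select_probes(traj.topology, cfg.probe_residues)
        if probes.n_molecules == 0:
            raise ValueError(f"no probe residues {cfg.probe_residues} in {path}")
        tid = os.path.basename(path)
        if cfg.criterion == "distance":
            call = scan_distance_criterion(traj, bonds, probes, prox, tid)
        elif cfg.criterion in ("distance_energy", "distance+energy"):
            backend = _make_backend(cfg.energy_backend, topology,
                                    cfg.probe_residues)
            call = scan_distance_energy_criterion(
                traj, bonds, probes, prox, backend, tid,
                refractory_ps=cfg.refractory_ps)
        else:
            raise ValueError(f"unknown criterion {cfg.criterion!r}")
        calls.append(call)
        for st in distance_stats(traj, bonds, probes, prox):
            for stat_name, s in st.summary.items():
                stats_rows.append({"trajectory": tid, "bond": st.bond,
                                   "statistic": stat_name, **s})
        log.info("%s -> %s", tid, call.called_bond or "no call")
    report = aggregate_lability(calls)
    result = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "criterion": report.criterion,
        "n_trajectories": report.n_trajectories,
        "per_bond_probability": report.per_bond_probability,
        "no_call_fraction": report.no_call_fraction,
        "calls": [{"trajectory_id": c.trajectory_id, "called_bond": c.called_bond,
                   "energy_checks_failed": c.energy_checks_failed,
                   "event": None if c.event is None else {
                       "frame_index": c.event.frame_index, "time_ps": c.event.time,
                       "probe_index": c.event.probe_index,
                       "distance_nm": c.event.distance}}
                  for c in calls],
    }
    if write_outputs:
        os.makedirs(cfg.output_dir, exist_ok=True)
        with open(os.path.join(cfg.output_dir, "report.json"), "w") as fh:
            json.dump(result, fh, indent=1, sort_keys=True)
        import pandas as pd
        pd.DataFrame(stats_rows).to_csv(
            os.path.join(cfg.output_dir, "contact_summary.csv"), index=False)
    return result


class ReportConfig(BaseModel):
    """Configuration for the combined geometry/conformation/MS report."""

    model_config = ConfigDict(extra="forbid")

    structure: Optional[str] = None          # geometry section input
    topology: Optional[str] = None           # conformation section inputs
    trajectory: Optional[str] = None
    reference: Optional[str] = None
    discard_ps: float = 0.0
    cluster_cutoff: float = 0.2
    peak_table: Optional[str] = None         # ms section input
    output: str = "report.json"
    seed: int = 0


def run_report(cfg: ReportConfig, write_outputs: bool = True) -> dict:
    """Bundle geometry records, conformational time-series summaries and MS
    reduction estimates into a single deterministic JSON document."""
    from .conformation import daura_cluster, backbone_indices, time_series

    out: dict = {"version": __version__, "seed": cfg.seed}
    if cfg.structure:
        s = read_structure(cfg.structure)
        out["geometry"] = geometry_records_to_rows(geometry_table(s))
    if cfg.topology and cfg.trajectory:
        topology = read_structure(cfg.topology)
        traj = read_trajectory(cfg.trajectory, topology)
        ref = read_structure(cfg.reference) if cfg.reference else None
        ts = time_series(traj, reference=ref)
        sel = backbone_indices(topology)
        cluster = daura_cluster(traj.frames[:, sel, :], cutoff=cfg.cluster_cutoff)
        out["conformation"] = {
            "times_ps": ts.times.tolist(),
            "rg_nm": ts.rg.tolist(),
            "hb_count": ts.hb_count.tolist(),
            "sasa_nm2": ts.sasa.tolist(),
            "rmsd_nm": ts.rmsd_to_reference.tolist(),
            "cluster_sizes": cluster.cluster_sizes,
            "centroid_frames": cluster.centroid_frames,
        }
    if cfg.peak_table:
        table = read_peak_table(cfg.peak_table)
        out["ms_quant"] = summarize_table(table).to_dict(orient="records")
    if write_outputs:
        with open(cfg.output, "w") as fh:
            json.dump(out, fh, indent=1, sort_keys=True)
    return out
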