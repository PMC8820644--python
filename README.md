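# redoxscan

Proximity-based identification of **redox-labile disulfide bonds** from
molecular-dynamics trajectories that contain a chemical reducing probe
(TCEP or DTT), plus the companion analyses used to characterise and validate
such bonds: static disulfide geometry profiling, conformational-change
analytics, and quantitative mass-spectrometry reduction statistics.

## Who this is for

Structural bioinformaticians and protein engineers who want to know *which*
disulfide bond in a protein is most likely to be reduced — for example to
anticipate redox-mediated conformational switching in coagulation factors —
without committing to wet-lab screens first.  The package analyses
probe-containing trajectories from any MD engine (PDB/GRO topologies;
multi-model PDB, XTC, DCD or TRR trajectories) and ships a seeded synthetic
probe-diffusion simulator so the entire pipeline is exercisable and testable
without an MD engine.

## The method

A disulfide is scored by the proximity of reducing-probe molecules to its
centre of mass (COM):

- **Distance criterion.**  Scanning frames in time order, a bond is called
  *reduced* as soon as a probe COM comes within a cutoff of the disulfide
  COM — 0.8 nm for TCEP, 0.6 nm for the smaller DTT.  One call per
  trajectory (first passage).
- **Distance+energy criterion.**  The contact event must additionally be
  energetically favourable: the event-frame structure is taken, the S–S bond
  broken (each sulfur capped with hydrogen), both forms are energy-minimised
  with steepest descent, and the call stands only if `E_fin < E_in`
  (strictly).  Energy backends are pluggable; a self-contained simplified
  potential is included, and externally computed energy pairs can be
  injected.
- **Ensemble aggregation.**  Over an ensemble of ≥20 independent
  trajectories, the per-bond reduction probability is the fraction of
  trajectories calling that bond.

Supporting statistics: the smooth coordination number
`CN = Σ_ij (1-(r_ij/r0)^n) / (1-(r_ij/r0)^m)` (defaults r0 = 3 nm, n = 6,
m = 12), mass-weighted radius of gyration `Rg = sqrt(Σ m_i|R_i-R_COM|² / Σ m_i)`,
Shrake–Rupley SASA, Kabsch-superposed backbone RMSD, Daura (GROMOS)
conformational clustering at 0.2 nm on N-Cα-C atoms, the five χ dihedrals of
a cystine with the 20-class conformation labels (−RHStaple, −/+RHHook, …),
and the control-peptide-normalised MS statistic

    % reduction = mean_i [ (A_cys,s / A_ctrl_i,s) / (A_cys,100% / A_ctrl_i,100%) ] × 100.

## Worked example

Generate a ground-truth bundle (toy protein with two surface disulfides and
one buried one; 100 probe molecules biased toward one surface bond) and scan
it:

```bash
redoxscan simulate --out bundle --seed 17 --n-trajectories 6 --n-frames 100
redoxscan scan --topology bundle/topology.pdb --out results bundle/traj_*.xtc
```

which prints the per-bond reduction probabilities:

```
{
 "Cys11-Cys12": 1.0
}
```

Cys11-Cys12 is the bond the simulator's attraction patch was placed on — the
distance criterion calls it in all six trajectories, while the other surface
bond and the buried bond Cys43-Cys44 are never called.  `results/report.json`
carries the calls and probabilities; `results/contact_summary.csv` holds the
per-bond boxplot statistics (mean/min distance, contacts within the cutoff,
smooth CN).  Static geometry:

```bash
redoxscan geometry bundle/topology.pdb --out geometry.csv
```

tabulates per-bond SASA (Å²), Cα–Cα distance (Å), χ1…χ1′ and the
conformation class, e.g.

```
bond, sasa_A2, ca_dist_A, conformation
Cys11-Cys12, 77.7, 5.81, +/-LHSpiral
Cys22-Cys23, 98.1, 6.27, -LHSpiral
Cys43-Cys44, 0.0, 7.32, -RHStaple
```

— the buried bond shows SASA = 0 while the surface bonds are fully exposed.

## Layout

- `redoxscan.model` / `io` / `pbc` — structures, trajectories, standard-format
  I/O (via MDAnalysis), minimum-image geometry, disulfide detection.
- `redoxscan.proximity` — contact statistics, distance criterion, aggregation.
- `redoxscan.energy` — simplified potential, steepest descent, `E_fin < E_in`
  check, distance+energy criterion, pluggable backends.
- `redoxscan.geometry` — SASA, Cα–Cα, χ dihedrals, 20-class conformations.
- `redoxscan.conformation` — Rg/H-bond/SASA/RMSD series, Daura clustering,
  representative frames, per-residue deviation maps.
- `redoxscan.msquant` — peak-area tables and % reduction estimates.
- `redoxscan.synthetic` — toy proteins, probe-diffusion simulator, ground-truth
  bundles, probe conformers.
- `redoxscan.pipeline` / `cli` — validated configs and the `redoxscan`
  command (scan, geometry, conformation, msquant, simulate, report).

See `docs/methods.md` for model assumptions, parameter defaults and known
limitations.
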