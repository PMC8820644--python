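# Methods notes

## Scope and model

`redoxscan` operationalises a proximity-based definition of disulfide
lability.  The physical picture: a reducing agent can only attack an S–S
bond it can reach, so the rate at which probe molecules visit a small
neighbourhood of the bond — and whether breaking the bond is energetically
downhill there — separates labile (allosteric) disulfides from structural
ones.  The package does not run molecular dynamics; it consumes trajectories
(from any engine, or from its own synthetic generator) and applies the
criteria and statistics below.

Internal units are nm, ps, amu and kJ/mol.  Å-based formats (PDB) are
converted at the I/O boundary, and the static-geometry table reports Å/Å²
because disulfide structural parameters are conventionally tabulated that
way.

## Criteria

**Distance criterion.**  Frames are scanned in time order; the first
(frame, bond, probe) triple with probe-COM-to-bond-COM distance below the
contact cutoff calls the bond, ties within a frame breaking on smallest
distance, then bond order, then probe index.  The cutoff defaults to 0.8 nm
for TCEP and 0.6 nm for DTT, reflecting their sizes (Rg ≈ 0.37 vs
≈ 0.26 nm).  One call at most per trajectory: conceptually the simulation
stops at the reduction event.  Events are resolved at saved-frame
resolution — an engine integrating between frames may see the crossing
earlier; this is irreducible for any post-hoc trajectory analysis.

**Bond COM.**  The disulfide COM defaults to the mass-weighted COM of the
two SG atoms (`SG_only`); a `cystine_residues` mode (all atoms of both
cysteines) exists for sensitivity analysis.  Probe COM is the mass-weighted
COM of the whole probe molecule.  Both use minimum-image unwrapping with a
reference-atom strategy (each atom shifted by whole box vectors to sit
nearest the first atom of the group), the behaviour of common trajectory
tools.  Orthorhombic boxes only; triclinic input is rejected.

**Distance+energy criterion.**  Each contact event triggers an energy
check on the event-frame structure: minimise the intact form (E_in), break
the S–S bond, minimise again (E_fin), accept only if E_fin < E_in strictly.
Bond breaking removes the S–S bonded term and caps each SG with a hydrogen
at 0.134 nm along the former S–S axis pointing away from the partner (no
re-protonation logic).  A failed check makes that (bond, probe) pair
refractory for 100 ps by default (whether the same contact should be
re-tested is genuinely open; the refractory window is configurable and a
very large value disables re-testing).

**Energy backend.**  Reproducing a full biomolecular force field is outside
this package's remit, so the default backend is a deliberately simple
vacuum potential — harmonic bonds and angles, Lennard-Jones with
Lorentz–Berthelot mixing, and Coulomb truncated at 1.2 nm — minimised by
adaptive steepest descent (step halves on an uphill trial, grows 1.2× on
acceptance; forces by central differences, adequate at the system sizes
this backend is meant for).  The criterion's *logic* is exact; its
*energetics* are approximate, so the backend contract is pluggable:
`always_accept` reduces the criterion to the distance criterion,
`table_backend` injects externally computed (E_in, E_fin) pairs from an MD
engine for replication studies, and `simple_ff_backend` restricts the check
to protein atoms (solvent and probes are ignored — a documented deviation
from engine-level minimisation, which includes them).

**Aggregation.**  Per-bond probability = fraction of trajectories calling
the bond; the no-call fraction completes the distribution to 1.  At least
20 trajectories is the intended design; mixing criteria in one aggregate is
an error.  Whether one trajectory may call several bonds is open; this
implementation takes one call per trajectory (first passage), which makes
the probabilities a proper distribution.

## Static geometry

Cα–Cα distance (Å, no PBC — a single molecule), the five cystine dihedrals
χ1 = N-Cα-Cβ-SG, χ2 = Cα-Cβ-SG-SG′, χ3 = Cβ-SG-SG′-Cβ′ and their primed
mirrors (IUPAC sign convention, degrees), and the 20-class conformation
label.  The sign→label mapping ships as an auditable JSON table
(`data/disulfide_classes.json`): χ3's sign gives RH/LH; each end is
"staple-like" when its χ2 sign opposes χ3; two staple-like ends → Staple,
none → Spiral, one → Hook; χ1/χ1′ signs give the −, + or mixed prefix.  For
mixed-prefix Hooks the staple-like end is listed first (so −/+ and +/− are
distinct classes); for the symmetric Spiral/Staple families the mixed
prefix canonicalises to "+/−".  Reading the bond from either end yields the
same label, and negating all five angles maps every class onto its mirror.
Exactly 20 classes cover the 32 sign vectors.

SASA is Shrake–Rupley with a 1.4 Å probe and 960 golden-spiral points per
atom by default; van der Waals radii ship as data with override hooks.
Per-bond SASA is the sum over the two SG atoms (whole-cystine mode
available).  The source tabulations we compare against do not specify their
exact atom set or probe parameters, so per-bond SASA is validated by
ranking and thresholds (e.g. ">30 Å² and Cα–Cα < 5 Å"), not exact equality.

## Conformational analytics

Rg (mass-weighted), intramolecular hydrogen bonds (geometric criterion:
D–A ≤ 0.35 nm and H-D-A angle ≤ 30°, a standard trajectory-tool default —
the analysed studies name no criterion), SASA and backbone RMSD (N-Cα-C,
Kabsch superposition) as time series; Daura clustering (greedy
neighbour-count at 0.2 nm pairwise backbone RMSD, deterministic index
tie-break); the representative conformation is the centroid of the largest
cluster after discarding an initial window.  Conformational difference
between two representatives is reported as per-residue Cα displacement
after whole-structure or per-domain superposition — a substitute for
visualisation-specific similarity colourings (Q-parameter/STAMP), whose
exact formula is not published; thresholds are therefore left to the user.
SASA time series default to a reduced quadrature (120 points) because the
per-frame cost dominates; use 960 for table-quality values.

## MS quantitation

The % reduction statistic is a ratio of ratios — cysteine-peptide area
normalised by each control peptide, in the sample versus the fully reduced
reference — averaged over control peptides, which cancels any common
scaling of a sample's areas.  Biological and technical replicates are
pooled for the mean ± sample SD (the source protocol reports a single
mean ± SD per cysteine without specifying the hierarchy).  Values above
100 % are reported with a warning, never clipped.  Residue-numbering
offsets (e.g. a +19 signal peptide in MS numbering) are handled by an
explicit offset column in the peptide↔cysteine map.  Baseline reduction in
the untreated control is *not* subtracted from treated values; raw
percentages are reported.

## Synthetic generator

The generator exists to give every criterion a known answer:

- **Toy proteins** place residues (backbone N/Cα/C; cysteines add Cβ/SG) on
  a Fibonacci-sphere shell sized for ~0.55 nm spacing.  Surface cystines
  protrude beyond the shell; a buried cystine sits at the centre inside an
  occluding inner cage, making the SASA contrast (< 5 Å² vs > 30 Å²) true
  by construction.
- **Probe dynamics** are overdamped seeded random walks: Gaussian trial
  moves (0.15 nm) with periodic wrapping, hard-core rejection within
  0.45 nm of any protein atom, and — when a patch bond is set — a
  Metropolis filter against a Gaussian attraction well (depth
  `patch_strength` = 4 kT, width 0.6 nm) centred on that bond's COM.  A
  burn-in of 200 sweeps precedes recording so production frames sample the
  stationary distribution, mirroring equilibration-then-production
  practice.  This is a generator of *contact statistics*, not kinetics: no
  probe-probe interactions, no hydrodynamics, no thermodynamically
  meaningful binding constants, and the protein is static.
- **Defaults are the study conditions** where those are stated: 100 probes
  per protein (the 100:1 ratio), cubic box (7.9 nm), 10 ps between frames,
  ≥ 20 independent trajectories.  Trajectory length (400 frames) is a
  desk-scale choice: long enough that unbiased probes traverse the box many
  times, short enough that a 20-trajectory experiment runs in well under a
  minute.  The recovery studies in the test suite use 150-frame / 150-sweep
  runs, sized so that a 50-repetition × 20-trajectory experiment completes
  in minutes; the patched bond's identity, not trajectory length, drives
  the outcome there.
- **MS tables** draw areas as base × designed-fraction × lognormal noise
  (5 % default), with four control peptides.

What passing these tests shows: the criteria, estimators and aggregation
recover designed ground truth under idealised sampling.  What they do not
show: force-field realism, probe chemistry (phosphine vs thiol attack), or
kinetics of real reduction — for those, feed engine-generated trajectories
through the same pipeline.

## Numerical choices

- Switching function: the removable singularity at r = r0 evaluates to its
  limit n/m; values within 1e-12 of the pole use the limit.
- Disulfide detection: SG–SG minimum-image distance ≤ 0.25 nm (covers the
  ~2.05 Å bond), greedy nearest pairing, deterministic ordering by residue
  id; an SG within the cutoff of two partners warns and keeps the nearest.
- Steepest descent: converged when the largest per-atom force norm drops
  below tolerance (default 50 kJ/mol/nm); the accepted-energy trace is
  non-increasing by construction.
- Daura clustering breaks neighbour-count ties on the lowest frame index,
  so permuting frame order relabels clusters identically.
- GRO files carry 3 decimals (0.001 nm); round-trip tests use that as the
  format precision.  XTC precision is 0.001 nm likewise.
- All randomness flows from integer seeds through `numpy` Generators;
  per-trajectory seeds derive from a `SeedSequence` and stay below 2³¹.

## Known limitations

- The default energy backend is a toy potential; distance+energy results
  with it demonstrate the criterion's machinery, not chemistry.  Use the
  injected-energy backend with engine-minimised energies for real systems.
- Probe molecules in the synthetic generator are single beads; the
  `cystine_residues` COM mode and multi-atom probe COMs are exercised via
  file-based fixtures rather than the bead simulator.
- Hydrogen-bond counting needs explicit donor-H mappings; structures
  without hydrogens yield zero counts rather than inferred positions.
- Replicating published per-bond reduction probabilities (e.g. 96.7 %/100 %
  for CD44 with TCEP, 70.0 %/81.8 % for FVIII light chains) requires
  regenerating multi-microsecond explicit-solvent MD ensembles; the
  pipeline accepts such trajectories unchanged but cannot produce them.
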