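# Methods

`lnpsim` simulates the self-assembly of tripalmitin lipid nanoparticles
(LNPs) in coarse-grained (CG) water, optionally with Tween 20
surfactant, and computes the structural observables used to
characterize such particles.  This note records the model, the
numerical choices, and what the desk-scale tests do and do not
demonstrate.

## Coarse-grain model

The model follows the Martini building-block philosophy: ~4 heavy atoms
(plus hydrogens) per interaction bead, each bead weighing 72 amu
regardless of type.  Five bead types are used:

| type | character | role here |
|------|-----------|-----------|
| C1   | apolar    | alkyl tails, glycerol linker, ring carbons |
| Na   | intermediate polarity (H-bond acceptor) | ester groups, ring oxygens |
| P3   | polar     | PEG-like surfactant arms |
| P4   | polar     | CG water, 4 real waters per bead |
| AF   | antifreeze water | 1 per 10 P4; enlarged σ against P4 disrupts artificial crystallization |

**Tripalmitin** (155 atoms → 19 beads): three palmitate tails of four C1
beads each, three Na ester beads, and a four-C1 glycerol/linker region
(chain GL1–GL2–GL3, each carrying one ester, with GL4 on GL2).  The
bond graph is a tree.  **Tween 20** (198 atoms → 30 beads): a
fine-mapped five-bead sorbitan ring (2 Na + 3 C1, one heavy atom per
bead), four PEG-like P3 arms of 5, 5, 5 and 6 beads, and a lauric tail
(1 Na ester + 3 C1) continuing the long arm.  The exact per-arm bead
assignment of the PEG arms is a documented convention; only the total
census (30 beads; types ⊆ {P3, Na, C1}) is fixed by the mapping.

The ring is held near-rigid by stiff harmonic bonds on the pentagon
edges (r0 = 0.32 nm, k = 6000 kJ/mol/nm²) plus harmonic distance
restraints on the five chords (k = 2000), rather than holonomic
constraints — a simpler integrator contract whose stability at the
20 fs step is verified by test (mean ring bond lengths stay within 5%
of their reference after 10⁴ thermostatted steps in water).

**Parameter table.** The published Martini interaction matrix is not
reproduced verbatim; the package ships a *Martini-2.0-like* default
table (`lnpsim/data/martini_like.yaml`): σ = 0.47 nm for regular pairs,
σ = 0.43 nm between ring beads, ε graded 2.0–5.0 kJ/mol by polarity,
AF–P4 σ = 0.57 nm.  The table is validated on load (symmetry over all
15 pairs, positive parameters, and the hydrophobic ordering
ε(C1,P4) < ε(C1,C1), ε(C1,P4) < ε(P4,P4) required for hydrophobic
collapse).  Users reproducing a specific published parameterization
substitute their own YAML.  Dihedrals are omitted: the two molecules'
chains are governed by bonds (r0 = 0.47 nm, k = 1250 kJ/mol/nm²) and
cosine-harmonic angles (θ0 = 180°, kθ = 25 kJ/mol), with the ring
restraints standing in for ring dihedrals.

## Dynamics

Units are GROMACS-style (nm, ps, amu, kJ/mol), under which
1 amu·nm²/ps² = 1 kJ/mol exactly.  The protocol: Δt = 20 fs, periodic
cubic box, Lennard-Jones truncated at 1.4 nm with a C¹ polynomial
switching function from 1.0 nm applied to the potential,

    S(r) = (rc² − r²)² (rc² + 2r² − 3r_on²) / (rc² − r_on²)³,

forces being the exact analytic gradient of V·S (verified against an
all-pairs numpy oracle to 10⁻⁹ relative).  Following the standard
Martini topology convention (nrexcl = 1), only pairs carrying an
explicit bonded term — chain bonds, ring edges, ring restraints — are
excluded from LJ.  Second neighbours keep their LJ hard core: the
printed topologies carry no angle term on several 1-3 paths (branch
points, esters), and excluding those pairs as well would leave them
with no interaction at all, letting chains fold onto themselves.  Temperature is held at 310 K by a
BAOAB-split Langevin integrator (γ = 1 ps⁻¹ by default; the friction is
not printed in the source protocol) whose Ornstein–Uhlenbeck substep is
exact, so γ = 0 reduces the scheme to velocity Verlet; NVE drift over
10⁴ steps is below 0.5% of the mean kinetic energy.  At Δt = 20 fs the
full-step kinetic temperature of strongly interacting CG water sits
~1.5% below the target (≈305 K) — a time-step discretization effect
that vanishes on a force-free system, where the exact OU update gives
310 K.

Pressure is controlled at 1 atm by a Monte-Carlo isotropic
volume-rescaling barostat (uniform ΔV proposals with adaptive width,
NPT Metropolis acceptance, attempted every 40 steps).  Its contract is
the mean pressure, not piston dynamics; structural observables are the
comparison surface.  Instantaneous pressure is virial-based
(minimum-image pair virials plus the kinetic term).

Neighbour search uses a Verlet list over cutoff + 0.3 nm skin, rebuilt
when any bead has moved half the skin; the list builder is a
counting-sorted cell grid with half-cutoff cells (all-pairs fallback
for small boxes).  All kernels are single-threaded and deterministic:
identical state, config and seed reproduce a trajectory bit-for-bit on
one platform.

All times are nominal (step × Δt).  CG dynamics are effectively faster
than atomistic dynamics — a common speed-up estimate for this class of
model is ×4 — but no correction is applied anywhere; reported times are
nominal, matching the convention of the source study.

## System construction

Presets `s1`–`s5` carry the five study compositions verbatim (64–392
lipids, 0–221 surfactants, their P4/AF counts and equilibrium box
sides).  Note the S1 row lists 4176 P4 with 462 AF (ratio ≈ 9.04);
`water_composition` implements the stated 1-per-10 rule (4176 → 418)
and the discrepancy is simply carried in the preset as published.

The builder places solutes as a *compact central array* — molecule
bounding box plus a 0.5 nm gap — inside the solvation box, following
the study protocol of a molecule array inside a much larger water box.
(An array spread across the whole box seeds a metastable aggregate that
percolates through the periodic boundaries at small box sizes.)  Each
molecule uses a compact folded reference conformation (beads on a
0.46 nm grid; strained bonds are relaxed by minimization).  The
remainder is filled with a jittered water lattice (stratified site
selection keeps octant densities within 5%), AF beads are randomly
interspersed at the composition ratio, and Maxwell–Boltzmann velocities
are drawn.  When the nominal box cannot hold both the array and the
requested water, the initial box is enlarged (up to 60%) and the
barostat relaxes it back to the liquid density.  The placement contract — no bead pair
closer than 0.3 nm under the minimum image — is guaranteed by
construction and checked by brute force in the tests.  Energy
minimization is steepest descent with an adaptive trust radius
(backtracking on energy increase); it never raises the energy and is
deterministic.

**Desk-scale preset.** The full study systems need hundreds of
nanoseconds on cluster hardware.  The desk preset is sized for one CPU
core: 16 lipids, 1090 P4 + 109 AF, initial box 5.8 nm, 2×10⁵ steps
(4 ns nominal).  Sixteen lipids form a droplet ~4.1 nm across, and the
box leaves at least the LJ cutoff of water between the droplet and its
periodic images — the binding constraint on the preset's size.  (A
24-lipid droplet is ~4.7 nm across; giving it the same clearance makes
the system ~2900 beads and pushes the protocol well past a practical
single-core budget, and shrinking its box instead produces an aggregate
that interacts with its own images — a qualitatively wrong
representation of the dilute study conditions.)  Self-assembly
completes well inside the 4 ns window, as in the source protocol where
a 216-lipid system assembles in ~4 ns.

## Observables

* **Radius of gyration** — mass-weighted RMS distance from the centre
  of mass of the selection.
* **Principal radii / asphericity** — square roots of the
  gyration-tensor eigenvalues, sorted R1 ≥ R2 ≥ R3 (so
  Rg² = R1² + R2² + R3²), and Δ = (3/2) Σ(Ri − Rm)²/(R1+R2+R3)² with
  Rm the mean radius: 0 for a sphere, exactly 1 for a collinear rod.
  Degenerate (collinear/planar) selections give zero eigenvalues, not
  errors; eigenvalues are clipped at zero before the square root.
* **Lipid number density** — 3N/(4π Rg³), displayed at two decimals as
  in the study's result tables; full precision retained internally.
* **Aggregates** — two molecules are connected when any inter-molecular
  bead pair is within the contact cutoff (default 0.6 nm, just above
  the bead σ; the choice is a convention) under the minimum image;
  clusters are connected components (union-find, verified against a
  brute-force oracle).  Before any shape analysis the aggregate is made
  whole: each molecule's bond graph is unwrapped first, then molecules
  are shifted by box vectors along a BFS of the contact graph.
* **Interior water** — the box is voxelized (0.35 nm default); voxels
  whose cube can reach within one bead radius (0.264 nm, the LJ contact
  radius σ·2^(1/6)/2) of a lipid bead are blocked; a face-connected
  flood fill from the box boundaries (after recentring the aggregate,
  which also makes the counts invariant under box translation) marks
  the exterior; water beads in unreached open voxels are interior, and
  water in blocked voxels inherits the label of the nearest open voxel
  so the droplet's first solvation shell is not miscounted.  This is an
  operational convention — the source study states no algorithm — so
  full-scale agreement with its printed interior-water counts is a soft
  check, not a gate.  Exchange events are persistent label flips: a
  flip counts only if the new label survives a debounce window
  (default 3 frames).
* **Surface coverage** — surfactant beads within a radial shell of the
  aggregate COM are binned into exactly-equal-area angular patches
  (equal slices in cos θ × equal φ sectors; the band count is the
  divisor of n_patches closest to √(n/2)).  Covered fraction = patches
  with ≥ 1 bead; the coefficient of variation of patch counts
  summarizes inhomogeneity.  A surfactant-free system yields an empty,
  flagged map.

## Experiment protocol

`run_experiment` builds, minimizes, integrates, detects the equilibrium
window, and reports.  The window rule (the study monitors energy and
box size qualitatively): take the trailing half of the logged series
and accept it when linear fits of total energy and box side both have
slopes indistinguishable from zero at 95% confidence; otherwise the
report is flagged `equilibrated=False`.  Incomplete assembly (largest
cluster < lipid count) flags the report but never suppresses the
analyses.  Reports carry the frame window, the seed, a config hash and
the code version; identical presets and seeds give identical reports.

## What the desk tests show — and what they do not

The desk-scale runs demonstrate the *mechanism*: spontaneous
hydrophobic collapse of all lipids into a single, near-spherical
(Δ ≈ 10⁻²–10⁻³) liquid droplet with a well-defined density, under the
stated thermostat/barostat protocol.  They are not quantitative
reproductions of the full-scale study values: a 16-lipid droplet has a
large surface-to-volume ratio, its density metric 3N/(4πRg³) carries a
finite-size bias, and the shipped parameter table is Martini-*like*
rather than the published matrix.  The full-scale equilibrium
quantities (Rg = 2.5/3.7/4.6 nm, Δ ~ 10⁻³–10⁻⁴, the S3 interior-water
droplet of 170 P4 + 18 AF, and the S5 core/total Rg of 3.9/4.9 nm)
require multi-hundred-nanosecond runs and are covered by the
property-based suite plus an optional long-run test, not by desk runs.

## Known limitations

* No electrostatics (all species here are nonionic), no dihedrals, no
  constraint solver, no polarizable water, no triclinic boxes.
* The parameter table is a documented stand-in with published-magnitude
  values; absolute densities differ at the tens-of-percent level from
  runs with the exact published matrix (the 1.0–1.4 nm switching
  protocol also integrates more attraction than the shorter truncation
  the original bead calibration assumed).
* Kinetic temperature at Δt = 20 fs sits ~1.5% under target (above).
* The trailing-half equilibrium detector is conservative on short runs:
  slow compaction after assembly often leaves `equilibrated=False` on
  desk-scale windows even when shape observables have stabilized.
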