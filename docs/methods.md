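# Methods

## Scope and model

`gfdyn` analyses trajectories of two-chain protein complexes — the design
case is a glycoprotein hormone bound to the high-affinity fragment of its
receptor — and summarises them with four descriptor families plus an
end-point free-energy decomposition:

1. **RMSD/shift classification.** Backbone RMSD per frame after optimal
   rigid superposition (Kabsch, proper rotations only), and a per-residue
   "settled shift": frames after the equilibration skip are superposed on
   the whole-complex backbone, time-averaged, and each residue's shift is
   the maximum backbone-atom displacement between that mean structure and
   the reference. Residues with shift > 1.5 A are *shifted*; residues with
   any heavy atom within 4.5 A of the partner in the reference are
   *contact*; the cross of the two flags gives the four interface-map
   classes. The mean (not per-frame maximum) is used deliberately: the
   quantity of interest is a persistent conformational change, not a
   transient excursion. The superposition fit set is the complex backbone
   so that a local shift cannot drag the reference frame toward itself.

2. **RMSF and flexibility bands.** Alpha-carbon RMSF about the window-mean
   structure, with the superposition target iterated twice
   (mean → superpose → re-mean); the default analysis window discards the
   first 12.5% of frames, the analog of skipping 5 ns of a 40 ns run.
   Flexibility bands are right-closed intervals on RMSF:
   <=1 A blue, (1,2] cyan, (2,3] green, (3,4] yellow, (4,5] brown,
   >5 A red. Glycoform difference profiles flag |delta RMSF| > 0.50 A;
   bound-vs-free comparisons use 1.0 A.

3. **Salt-bridge persistence.** Bridges are seeded in the reference
   structure as cation-nitrogen (Lys NZ; Arg NE/NH1/NH2) to
   anion-oxygen (Asp OD1/OD2; Glu OE1/OE2) contacts across the interface
   with minimum N-O distance < 4.0 A. Histidine is excluded by default
   because its charge state is protonation-dependent; a flag includes it.
   Along the trajectory the minimum N-O distance over all atom pairs of a
   bridge is sampled every `stride` frames (default: one sample per 2 ps,
   the analog of sampling every 1000th 2 fs integration step); the summary
   statistics are the median sampled distance and the occupancy, the
   fraction of samples strictly below 3.5 A, reported as a percentage to
   one decimal. Both statistics use the same strided samples.

4. **SASA.** Shrake-Rupley with a deterministic golden-spiral point set
   (default 960 points, probe 1.4 A, Bondi-style element radii shipped as
   package data), so results are bit-reproducible. Per-residue sums cover
   heavy atoms; pseudo-glycan/water residues occlude the surface but are
   excluded from profiles. Trajectory averages skip the equilibration
   fraction and stride the remaining frames. Difference profiles highlight
   residues with |delta SASA| strictly greater than 40 A^2 (an area cutoff).

## MM-GBSA decomposition

For each snapshot the ledger is

    GBTOT = E_int + E_ele + E_vdw + GBSOL,    GBSOL = G_pol + G_nonpol

- `E_int`: harmonic bonds `k_b (r - r0)^2` and angles `k_a (theta - theta0)^2`
  plus cosine dihedrals `V [1 + cos(n phi - phase)]`.
- `E_ele`, `E_vdw`: gas-phase Coulomb (`k_e = 332.0636 kcal A / (mol e^2)`)
  and Lennard-Jones 12-6 with Lorentz-Berthelot combining, no cutoff.
  1-2 and 1-3 pairs are excluded; 1-4 pairs scaled by 1/1.2
  (electrostatic) and 1/2 (LJ). The scaling factors are a convention
  choice and configurable.
- `G_pol`: pairwise Generalized-Born,
  `-k_e/2 (1/eps_in - 1/eps_out) sum_ij q_i q_j / f_GB` with
  `f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / 4 R_i R_j))`, self terms included.
  Effective Born radii come from HCT pairwise descreening (default) or
  OBC-II tanh rescaling with a 0.09 A offset. The HCT variant is
  formulated without a radius offset so an isolated ion reduces exactly to
  the Born equation — the closed-form anchor the test suite asserts.
  Radii driven non-positive by descreening are clamped to a 0.1 A floor.
  Dielectrics default to 1 (interior) and 80 (solvent); no added salt.
- `G_nonpol = gamma SASA + beta` with `gamma = 0.00542 kcal/(mol A^2)` and
  `beta = 0.92 kcal/mol`, using the same Shrake-Rupley engine.
- Conformational entropy (`-T dS`) is not modelled; requesting it is a
  configuration error rather than a silent zero.

Snapshots are taken every `snapshot_interval` of simulated time (default
1 ns; a 40 ns-equivalent trajectory yields exactly 40 snapshots) and each
component is reported as mean (sd). Two reporting modes exist because
absolute complex energies and complex-minus-parts differences answer
different questions: `absolute` (default for the glycoform comparison
report, matching the published reporting convention of five-digit
kcal/mol totals) and `binding`, the single-trajectory approximation in
which receptor and ligand coordinates are cut from the complex frames.
In binding mode intra-molecular bonded terms cancel exactly
(`delta E_int = 0`), which the suite asserts. The ledger identities hold
exactly per snapshot and for means (linearity).

Only Generalized-Born solvation is provided; a Poisson-Boltzmann solver is
out of scope. No GB variant can be matched numerically to any particular
legacy MD package without its exact radii set, so correctness is claimed
through closed-form limits (Born ion, distant-ion separability, Coulomb
screening) and property tests (rigid invariance, dielectric monotonicity),
not through cross-package numbers.

## Synthetic data: what it emulates and what it does not

The generator builds a two-chain toy complex (four-atom backbone residues
on two parallel axes 12 A apart, Lys/Asp side-chain tips at planted
interface bridges, optional inert occluder spheres standing in for
glycans) with a complete force-field table whose bonded reference values
are taken from the built geometry, so the reference structure carries zero
internal strain. Trajectories are i.i.d. Gaussian jitter around the
reference with three planted, exactly recoverable signals:

- a per-residue fluctuation sigma (per coordinate), giving the closed-form
  RMSF target `sqrt(3) sigma`;
- an optional persistent displacement of a residue region from a given
  frame onward (the abrupt conformational-shift analog), recoverable by a
  change-point on the RMSD series;
- two-state Markov open/closed dynamics per planted bridge with stationary
  closed fraction equal to the requested occupancy. The default switching
  rate of 0.8 per frame keeps sample autocorrelation low enough that the
  occupancy estimator's error stays near the i.i.d. binomial width.
  Bridge tip atoms follow the two-state geometry exactly — jitter is not
  added on top — so planted occupancies are recovered to sampling error
  rather than being blurred by geometric noise.

Because frames are independent given the event schedule, the generator
reproduces *marginal* statistics (RMSF amplitudes, occupancies, SASA
averages) but no kinetics: no autocorrelation in positions, no barrier
crossing, no solvent. Occasional steric clashes between jittered atoms
produce heavy-tailed Lennard-Jones spikes in absolute snapshot energies;
this is inherent to non-dynamical sampling and harmless for every
statistic the pipeline reports. Passing tests therefore demonstrate the
correctness of the descriptors and energy kernels, not the realism of any
molecular-dynamics engine.

The five-system analog suite mirrors the published design matrix: one
bare baseline, two systems with small occlusion (one sphere at two or
four sites — calibrated to stay under the 40 A^2 SASA cutoff, as small
glycans should), and two with large occlusion (three spheres at two or
four sites — over the cutoff), the 2-large system additionally carrying
the conformational-shift event. Planted bridge occupancies across the
baseline/2-large/4-large systems follow the published persistence table's
pattern (one invariant bridge, one mildly weakened, two strongly weakened
in the fully occluded system).

## Numerical choices

- Kabsch superposition rejects reflections (determinant correction) and
  raises on rank-deficient covariance rather than returning an arbitrary
  rotation.
- The median of an even-length distance series is the mean of the central
  pair; occupancy uses strict inequality at the cutoff, matching the
  "distance less than cutoff" definition.
- Band intervals are right-closed, so an RMSF of exactly 2.0 A is cyan.
- Shrake-Rupley burial tests use squared distances against squared
  expanded radii; the dot set is the deterministic golden spiral, so SASA
  is reproducible bit-for-bit at fixed `n_points`.
- Angle energies guard `arccos` with clipping; collinear dihedral atoms
  raise rather than returning NaN.
- Snapshot frames are the k-th, 2k-th, ... frames where `k` rounds
  `snapshot_interval / frame_spacing`.
- Averages are printed to 3 decimals (profiles) and 2 decimals with
  "mean (sd)" formatting (energy tables); table ledger validation allows a
  0.02 kcal/mol residual to absorb printed rounding.
- Standard deviations of energy differences assume independent systems
  (`sqrt(sa^2 + sb^2)`); no significance test is attached, as none is
  defined for the comparison.

## Problem sizes

RMSF amplitude recovery is checked on a 30+34-residue complex: fitting
each frame to the mean removes six rigid degrees of freedom, which
deflates the estimator by roughly `sqrt(1 - 6/3N)`, so a larger N keeps
that bias (~1.5% at N = 64) well inside the 5% recovery band instead of
consuming most of it.  Other default test and acceptance runs use toy
complexes of 12+14 residues
(~110 atoms, ~1000 A^2 interface) with 80-2000 frames, 20 000 strided
samples for occupancy recovery, and 40-snapshot energy summaries on a
40 ns-equivalent trajectory (400 frames at 100 ps spacing). These sizes
make every stage's ground truth exactly checkable while keeping a full
five-system pipeline run under a minute on one CPU.

## Known limitations

- No mmCIF or binary trajectory formats; no protonation logic; hydrogens
  are carried if present but never generated.
- The residue-shift classifier assumes the complex does not dissociate;
  a fully detached chain would make the whole-complex fit meaningless.
- GB radii/scales are taken from the parameter file as given; no
  element-based fallback is attempted.
- The occupancy estimator's confidence statement assumes the generator's
  switching rate; strongly persistent real bridges (occupancy near 0 or 1)
  have asymmetric errors the binomial width understates.
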