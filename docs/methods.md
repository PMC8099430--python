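# Methods

## Problem and model

xlwalk addresses a recurring situation in integrative structural biology: a
large receptor assembly is known at (pseudo-)atomic resolution, a binding
partner is mostly disordered or unresolved, and the main experimental
information about the partner's location is a set of chemical crosslinks
(XL-MS) between residue pairs. The package models the partner as a string of
coarse-grained beads tethered to the rigid receptor, scores configurations
against the crosslinks and basic stereochemistry, samples good-scoring
configurations with annealed Monte Carlo, and summarizes the resulting
ensemble with clustering and localization probability densities. The target
application scale is a receptor of a few hundred residues' worth of particles
and a flexible chain of ~100–250 residues, i.e. the scale of a
spindle-pole-body receptor peptide walking on a γ-tubulin small complex.

### Representation

A molecule is a list of residue segments. Rigid segments take one Cα particle
per resolved residue from a PDB/mmCIF chain and move as one body (or are
fixed, the default for the receptor, which defines the lab frame). Flexible
segments become beads of `residues_per_bead` residues; the bead radius is the
volume-equivalent sphere radius `r = (3 n v_res / 4π)^(1/3)` with
`v_res = 132.3 Å³` per residue (r = 3.16 Å for a 1-residue bead). The default
flexible resolution is one residue per bead for chains up to a few hundred
residues — the finest resolution at which the restraints act, at negligible
cost at this system size. A global `(molecule, copy, residue) → particle` map
drives restraints and selections.

### Scoring

All terms are flat-bottom harmonic penalties in score units per Å²:

* **Crosslink**: for each unique link, the *ambiguous minimum* Cα/bead
  distance `d_min` over all chain-copy combinations is compared with the
  per-linker cap `L` (defaults: DSS 35 Å, EDC 25 Å Cα–Cα, the customary
  linker-arm plus side-chain allowances); the penalty is
  `k_xl·max(0, d_min−L)²`. The minimum (not a soft-max) matches the
  convention that a link satisfied by either copy is satisfied, and keeps
  satisfaction auditable link by link.
* **Excluded volume**: `k_ev·max(0, r_i+r_j−d_ij)²` over unordered pairs that
  are not within one rigid body and not sequence-adjacent. Pairs in which
  both particles belong to the *fixed* scaffold are also excluded: they carry
  no sampled degree of freedom, and for synthetic receptors (pseudo-atom
  grids, not real chains) they would contribute a meaningless constant.
* **Connectivity**: for consecutive chain particles spanning `g` residues
  center-to-center, `k_conn·max(0, d−(r_i+r_j+c·g))²` with `c = 3.8 Å` (the
  Cα virtual bond). This includes bead-to-rigid anchor bonds; bonds internal
  to the fixed scaffold are skipped for the same reason as above.

Defaults `k_xl = k_ev = k_conn = 1` and unit weights. Setting a cap to
infinity disables a link; all terms are continuous and piecewise smooth, and
invariant under global rigid motion.

### Sampling

Metropolis Monte Carlo with a geometric annealing ladder (T = 5 → 1 in 10
stages by default; temperature is in score units). Movers are individual
beads (Gaussian translation, σ = 2 Å) and mobile rigid bodies (σ = 1 Å
translation plus σ = 5° rotation about the centroid). One MC *step* attempts
one randomly chosen move per mover — the random-scan sweep convention of
integrative-modeling samplers — so run length is measured in sweeps and is
independent of system size. The inner loop is a numba-compiled kernel that
evaluates only the local energy of the proposed move (the terms touching the
moved particles); snapshot scores are recomputed with the full vectorized
scorer, so recorded breakdowns are exact. On the default benchmark the chain
equilibrates in ≈1,500 sweeps; the default 20,000 sweeps leave a wide
post-convergence tail.

Each run draws from an independent stream seeded by
`SeedSequence([master_seed, run_index])`; identical seed and configuration
give bit-identical trajectories, and pooled results do not depend on the
order runs execute. The Metropolis implementation is validated against
numerical quadrature of the Boltzmann density on a one-bead, one-restraint
system (histogram agreement within 3σ counting error).

**Good-scoring criterion**: a snapshot qualifies when at least 90% of
crosslinks are within `L + tol` (tol = 0) and the excluded-volume and
connectivity scores are each below 0.5 score units per mobile particle —
about T/2 per soft degree of freedom at the final temperature, i.e. ordinary
thermal fluctuation rather than structural violation.

### Ensemble analysis

Models are compared by RMSD over a particle selection without superposition
(the receptor fixes the frame). Clustering is deterministic greedy centroid
clustering: the model with the most neighbors within the threshold seeds the
first cluster and claims them, then the procedure repeats; ties break to the
lowest model index.

The clustering threshold deserves care. Flat-bottom crosslink restraints are
zero-force within the cap, so two models whose beads differ by less than
~L are equally consistent with the data; good-scoring ensembles here have an
intrinsic spread of tens of Å, and a threshold far below that scale shreds a
structurally unimodal ensemble into singletons. The benchmark pipeline
therefore clusters at the **sampling precision**: the smallest threshold at
which two independent halves of the run pool populate every sizeable cluster
proportionally (chi-square p > 0.05 or Cramér's V < 0.10, with ≥80% of models
in clusters of ≥5) — the standard exhaustiveness protocol for this model
class. `cluster_models` itself takes an explicit threshold (default 10 Å) for
use at atomic precision.

Localization densities rasterize each selected particle as a solid sphere of
its radius on a voxel grid (default 3 Å voxels, counts accumulated across
models); maps are contoured relative to their own maximum (default 2.5%) and
written as MRC mode-2 with exact float32 round trip. Molecular maps for
difference mapping use a sum of normalized Gaussians with σ = resolution /
2.355; the model map is amplitude-fitted by least squares before voxelwise
subtraction, so the difference is invariant to overall model scaling.
Map sharpening, B-factor correction and low-pass filtering are out of scope.

### State comparison

Superposition is least-squares with proper rotation enforced; screw
decomposition reports twist in (0°, 180°], rise along the axis, and the axis
point minimizing perpendicular translation, with an exact
transform-reconstruction round trip. Helical pitch is `rise·360/twist`.
Center-of-mass shifts are unweighted over Cα positions by default
(mass-weighting is an option) after aligning on a caller-specified selection.
SASA is Shrake–Rupley with a deterministic golden-spiral point set (960
points, probe 1.4 Å, heavy atoms with NACCESS-style united radii); buried
area is reported both-sides, `SASA(A)+SASA(B)−SASA(A∪B)`, with per-side
halves recoverable from the report, because published interface totals do not
always state the convention. Against a dedicated reference implementation,
sphere-sampling SASA should be expected to differ by up to ~10% on real
interfaces; the isolated-sphere closed form reproduces to <1%.
Microtubule-register displacement superposes ring subunit positions onto
reference lattice sites using a caller-chosen subset of correspondences and
reports per-subunit displacements; the reference lattice is supplied as
coordinates, not generated from symmetry.

## Synthetic benchmark

The generator emulates the study design end to end. The receptor is two
rigid blocks of 150 pseudo-Cα atoms on a 3.8 Å grid, centered 31 Å from the
z axis and related by the open-state helical transform (twist 54.5°, rise
21.2 Å) — so the state-comparison code can recover the generating screw
exactly. The ligand ground truth is a 150-residue self-avoiding walk at 3.8 Å
steps that stays 6.5–10 Å from receptor atom centers (surface-hugging and
sterically clean at bead resolution). Crosslink tables contain 30 true DSS
links sampled from pairs within 0.8× the linker cap (at most one per ligand
residue, so restraints spread along the chain) and 2 decoys beyond 1.5× the
cap, each row with q ≤ 0.01 and ≥2 PSMs unless filter-violating rows are
injected deliberately. All toy data pass through the same PDB/CSV readers and
writers as real data.

The benchmark (4 runs × 20k sweeps, ≈2 minutes on one CPU) reports the
dominant-cluster occupancy at the sampling precision, the ensemble crosslink
satisfaction of the top cluster, and the fraction of ground-truth path points
inside the 2.5%-of-max contour of the top cluster's localization density.

What the toy does *not* emulate: real linker chemistry and reactivity bias,
peptide detectability, residue-type-specific crosslinkable sites, receptor
flexibility, and density-restrained docking. Passing the benchmark shows the
pipeline recovers a known answer from ideal-but-noisy restraints at realistic
information density; it does not certify accuracy on real XL-MS tables, where
threshold choices and mapping offsets dominate.

## Numerical choices and degenerate inputs

* Ambiguity argmin ties break to the lowest copy index; clustering ties to
  the lowest model index; both make reruns reproducible.
* Crosslinks with both endpoints unresolved are reported `unmappable` and
  excluded from the satisfaction denominator (counted separately).
* Superposition requires ≥3 non-collinear points; screw decomposition raises
  below 10⁻³ degrees of rotation; contouring an all-zero map raises; a
  contour fraction of 0 warns.
* The sampler aborts with a diagnostic snapshot if a non-finite energy change
  appears.
* MRC files store the grid origin (center of voxel 0,0,0) in the ORIGIN
  header words; values round-trip bit-exactly as float32.

## Known limitations

* The crosslink score is a distance-cap penalty, not a Bayesian likelihood;
  no noise model or weight inference.
* No density cross-correlation restraint; densities are outputs, not inputs.
* Rigid bodies have no internal flexibility; no replica exchange or
  gradient-based refinement.
* SASA uses fixed per-element radii; no per-residue united-atom table.
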