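# xlwalk

Crosslink-restrained coarse-grained integrative modeling of
receptor-tethered flexible proteins, with a toolbox for quantitative
comparison of conformational states of the same assembly.

## The problem

Large assemblies are often solved while their regulatory partners remain
invisible: a receptor peptide that tethers a complex to its cellular anchor
may be disordered, proteolytically trimmed, or simply unresolved in the map.
Crosslinking mass spectrometry (XL-MS) fills the gap with sparse distance
information — residue pairs joined by a chemical linker (amine–amine DSS,
carboxyl–amine EDC), each implying a maximum Cα–Cα span. xlwalk turns such
tables into ensembles of spatial models: the resolved assembly is kept rigid,
the unresolved chain becomes a string of beads, and Monte Carlo sampling finds
the configurations that satisfy the crosslinks and basic stereochemistry. The
intended users are structural biologists triaging XL-MS data against cryo-EM
or crystallographic models — the motivating case being a γ-tubulin small
complex (γTuSC) with its spindle-pole-body receptor peptide walking along its
surface.

## The model

A flexible chain of beads (radius `r = (3·n·v_res/4π)^{1/3}`, one residue per
bead by default) is tethered to fixed rigid bodies and scored with
flat-bottom harmonic restraints:

* crosslinks: `E_xl = Σ_l k·max(0, d_min(l) − L_linker)²`, where `d_min` is
  the minimum endpoint distance over all chain copies ("satisfied by either
  copy counts") and `L` is the per-linker Cα–Cα cap (DSS 35 Å, EDC 25 Å);
* excluded volume: `k·max(0, r_i + r_j − d_ij)²` over non-bonded pairs;
* connectivity: `k·max(0, d − (r_i + r_j + 3.8·g))²` between consecutive
  particles spanning `g` residues.

Annealed Metropolis sampling (T = 5 → 1, geometric; one step = one attempted
move per mover) generates the pool; good-scoring models (≥90% links
satisfied, stereochemistry at thermal levels) are clustered at the *sampling
precision* — the smallest RMSD threshold at which two independent halves of
the pool agree — and summarized as localization probability densities
(MRC), contoured relative to each map's maximum. Satisfaction statistics,
screw/helical parameters (`pitch = rise·360/twist`), center-of-mass shifts,
Shrake–Rupley buried interface areas and lattice-register displacements
quantify the results and the conformational states they connect.

Everything is testable without downloads: a synthetic generator builds a
screw-symmetric toy receptor, a ground-truth surface path, and crosslink
tables with controlled decoys and PSM metadata.

## Worked example

Simulate a benchmark system, run the pipeline, and inspect the headline
numbers:

```python
from xlwalk.synthetic import run_toy_pipeline

res = run_toy_pipeline(seed=1)   # 4 runs x 20,000 sweeps, ~2 min
print(f"good-scoring models   {res['n_good']}")
print(f"sampling precision    {res['rmsd_threshold']:.1f} A")
print(f"top-cluster occupancy {res['top_cluster_occupancy']:.3f}")
print(f"crosslink satisfaction {res['satisfaction_fraction']:.3f}")
print(f"path recovery         {res['recovery']:.3f}")
```

Output:

```
good-scoring models   313
sampling precision    42.9 A
top-cluster occupancy 0.997
crosslink satisfaction 1.000
path recovery         0.907
```

Reading: of 804 recorded snapshots, 313 satisfy the good-scoring criteria;
at the 42.9 Å sampling precision they form essentially a single cluster
(99.7% occupancy) whose ensemble satisfies all 32 crosslinks, and 90.7% of
the ground-truth path lies inside the 2.5%-of-maximum contour of the
cluster's localization density. The wide precision is expected physics:
flat-bottom 35 Å restraints are zero-force inside the cap, so the data
genuinely cannot pin beads more tightly.

The same steps are available from the shell:

```sh
xlwalk simulate --seed 7 --out toy/          # receptor.pdb, crosslinks.csv, ...
xlwalk xlinks filter toy/crosslinks.csv      # q <= 0.01 and >= 2 PSMs
xlwalk compare screw toy/receptor.pdb --sel-a A --sel-b B
# twist 54.50 deg  rise 21.20 A  pitch 140.0 A/turn  6.61 subunits/turn ...
```

State-comparison commands (`xlwalk compare com|interface|mtreg|site`) operate
on any PDB/mmCIF pair with `chain:start-end` selections.

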