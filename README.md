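# mlklswitch

Quantitative analysis of the MLKL pseudokinase activation switch and of
necroptosis-driven skin injury.

MLKL is the terminal executioner of necroptosis: phosphorylation of its
activation loop (S345 in mouse) — and, additionally, ubiquitylation at K219 —
flips the pseudokinase domain from an inactive to an active conformation,
releasing the N-terminal four-helix bundle (4HB) that ruptures the plasma
membrane.  This package implements the two quantitative pipelines used to
study that switch:

1. **Trajectory ensemble analysis.**  From replicate ensembles of structural
   snapshots (multi-model PDB, one file per replicate) it computes the angle
   between the activation-loop helix and the adjacent helix, the angle
   between the 4HB and pseudokinase domains, the occupancy of the
   pseudoactive-site K219::Q343 hydrogen bond, and the fluctuations (RMSF)
   of the 4HB domain relative to the pseudokinase domain — plus pooled
   histograms over all replicates, per-time mean ± SD envelopes, and a
   permutation test that treats each replicate's time-averaged metric as a
   single exchangeable observation:

       T = |mean(A) − mean(B)|,   p = #(T_perm ≥ T_obs) / #permutations

   with exhaustive enumeration whenever C(n₁+n₂, n₁) ≤ 10⁶ (the 10-vs-10
   design has 184,756 distinct assignments).

2. **Histological Lesion Score (HLS).**  Skin sections are overlaid with a
   grid of equal fields of view (0.04 mm², 800 µm perimeter), each scored
   0–4 for lesion severity, and

       HLS = Σ_s s · (% FOVs in severity class s)  ∈ [0, 400],

   with exact two-sided Mann–Whitney comparison between animal groups
   (mid-rank ties, enumeration for n₁+n₂ ≤ 20).

A fully seeded synthetic-data generator produces toy two-domain trajectory
ensembles with known angle distributions and H-bond probability, and FOV
severity grids with known class proportions, so every estimator can be
validated against ground truth at desk scale.  See `docs/methods.md` for
definitions and assumptions.

## Worked example

The composite pipeline on synthetic data (two constructs, 10 replicates of
200 frames each, plus a lesion-score demo):

```sh
$ mlklswitch run --seed 1 --out-dir demo_run --n-replicates 10 --n-frames 200
run: WT: occupancy 0.147, pooled mean angle 64.93 deg
run: S345phos: occupancy 0.019, pooled mean angle 79.94 deg
run: permutation test WT vs S345phos: p = 1.083e-05
run: HLS AE vs vehicle: U = 9.0, p = 0.1
run: manifest -> demo_run/manifest.json
```

Reading the output: the wild-type-like construct keeps the K219::Q343
hydrogen bond in 14.7 % of frames (generator truth 14 %) with its
activation-loop helix near 65°, while the phospho-mimicking construct loses
the bond (1.9 %) and reorients the helix to ~80°.  The replicate-mean
permutation test (exhaustive, 184,756 assignments) puts the loop-helix
difference at p ≈ 1.1 × 10⁻⁵ — 2/184,756, the two extreme relabellings.  In
the lesion demo, three severely ulcerated specimens against three mildly
affected ones are fully separated, so U = 9 (the maximum for 3 × 3) and the
exact two-sided p is 2/20 = 0.1 — the smallest p an exact rank test can
produce at that group size.

`demo_run/` then contains tidy per-frame metric tables, histogram and
grand-mean CSVs, `permtest.json`, per-specimen `hls.csv`, and
`manifest.json` with input checksums and seeds.  The same stages are
available individually (`simulate`, `metrics`, `hist`, `permtest`, `hls`)
and as library functions; `examples/demo_config.yaml` documents every
configuration key.

As a library:

```python
from mlklswitch import (DomainAnnotation, angle_series, hbond_occupancy,
                        generate_trajectory_ensemble, TrajectoryGenParams)

ens = generate_trajectory_ensemble(TrajectoryGenParams(seed=1))
ann = DomainAnnotation()                       # pseudokinase 179-464, etc.
print(angle_series(ens, ann, "helix_helix").pooled().mean())
print(hbond_occupancy(ens, ann).pooled)
```

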