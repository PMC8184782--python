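# Methods

`mlklswitch` quantifies the conformational switch of the MLKL pseudokinase
from replicate ensembles of structural snapshots, and the severity of
necroptosis-driven skin injury from gridded histology scores.  This note
records the definitions, defaults and design choices behind both tracks,
and what the synthetic-data tests do and do not demonstrate.

## Trajectory ensemble model

An ensemble is a set of independent replicate simulations of one construct
(WT, S345phos, K219ub_S345phos), each a sequence of frames at fixed time
spacing (default 10 ps) sharing a single atom ordering.  Four observables
are computed per construct:

**Activation-loop helix angle.**  The angle between the axis of the
activation-loop helix (default residues 343–352, containing Q343 and S345)
and the axis of the adjacent helix (default residues 228–240, containing
T235).  A helix axis is the first principal axis of the Cα trace after a
4-residue running-mean smoothing — one α-helical turn (3.6 residues) — which
cancels the radial spiral component; without smoothing, the principal axis
of a short helix with a partial final turn deviates from the screw axis by
several degrees.  Axes are oriented N→C and the angle is reported unfolded
in [0, 180]°: the two orientations of a helix are physically distinct, so no
folding to [0, 90]° is applied.

**Interdomain (4HB vs pseudokinase) angle.**  The angle between the first
principal axes of the 4HB Cα set (default residues 1–130) and the
pseudokinase Cα set (default 179–464, the pseudokinase-domain construct
boundary).  A principal axis has an arbitrary sign, so each axis is
sign-fixed against the corresponding axis of a reference structure (the
crystal structure where available, otherwise the first frame of the first
replicate).  Axes are unweighted (every Cα counts equally); mass-weighting
changes nothing for a Cα-only selection and is intentionally omitted.

**K219::Q343 hydrogen-bond occupancy.**  A frame counts as bonded when the
donor–acceptor heavy-atom distance (K219 NZ → Q343 OE1 by default) is at
most 3.5 Å, and — only when an explicit hydrogen covalently attached to the
donor is present (within 1.25 Å) — the best D–H–A angle is at least 135°.
The distance-only fallback makes the criterion usable on Cα-level or
stripped trajectories.  Both thresholds are configuration keys; 3.5 Å/135°
are the common practice defaults.  Occupancy is reported pooled (bonded
frames / all frames over all replicates, the primary estimate) and per
replicate; with equal-length replicates the mean of per-replicate fractions
coincides with the pooled value.

**Relative 4HB fluctuations.**  Every frame of a replicate is superposed on
a reference built from the pseudokinase Cα selection — frames are first
aligned to frame one and averaged (one alignment pass; a two-pass mean
refit is available) — and the per-atom RMSF of the 4HB selection about its
aligned mean is computed.  The summary is the mean RMSF over 4HB atoms, one
value per replicate.  Superposition uses a least-squares rigid fit
(proper rotation enforced); the residual is recomputed directly from the
fitted transform because the eigenvalue-route residual loses half its
digits near zero.

**Pooling and summaries.**  Histograms pool all frames of all replicates of
a construct before binning (default bin width 2°, edges aligned to
multiples of the width so binning is ordering-independent; the last bin is
right-closed so counts always sum to the frame total).  Time-resolved
summaries show the across-replicate mean and n−1 SD at each time point.
Per-replicate grand means (time averages) are the exchangeable units passed
to inference.

## Inference

**Replicate-mean permutation test.**  Frames within a simulation are
autocorrelated; replicates started from independent random velocities are
the exchangeable units.  The test therefore compares two constructs through
their per-replicate mean values with the statistic |mean(A) − mean(B)|,
against the group-relabelling null.  When the number of distinct
relabellings C(n₁+n₂, n₁) is at most 10⁶ — which covers the 10-vs-10
design, 184,756 assignments — all of them are enumerated and
p = #(null ≥ observed)/total; the identity labelling is one of them, so
p ≥ 1/total.  Otherwise relabellings are sampled uniformly with replacement
(default 1,000,000 draws, seed mandatory) and p = (#(null ≥ observed)+1)/(N+1).
Statistics analytically tied with the observed value are counted on the
"at least as extreme" side, guarded by a 1-ulp-scale tolerance so float
summation order cannot drop exact ties.

**Exact Mann–Whitney.**  For group sizes with n₁+n₂ ≤ 20 the two-sided
p-value is exact: pooled observations receive mid-ranks, all C(n₁+n₂, n₁)
assignments of ranks to the first group are enumerated, and p is the
proportion whose U deviates from the null centre n₁n₂/2 at least as far as
the observed U.  Mid-ranks make tied data exchangeable under the
enumeration without any separate correction.  Larger samples fall back to
the tie-corrected normal approximation.

## Histological Lesion Score

Each specimen's section is divided into equal square fields of view (FOV);
the published grid uses 0.04 mm² FOVs (200 µm side, 800 µm perimeter).
Each FOV carries one severity score 0–4 (0 regular epidermis; 1 epidermal
thickening; 2 erosion with intact stratum basale; 3 ulcer including the
stratum basale; 4 ulceration with dermal/hypodermal fibrosis).  When a FOV
shows more than one lesion class the maximum severity present is recorded —
the scoring sheet assigns a single class per FOV, and taking the maximum is
the conservative convention adopted here.  The specimen score is

    HLS = Σ_s s · (% of FOVs in class s),    s ∈ {0, …, 4},

ranging 0 (all regular) to 400 (100 % deep ulceration).  Proportions are
held as exact rationals internally, so the mixture identity
HLS(G₁∪G₂) = (n₁·HLS₁ + n₂·HLS₂)/(n₁+n₂) holds exactly; this is what makes
pooling the two sections scored per mouse well-defined (FOVs are pooled
before proportions; per-section grids remain available).  Groups are
compared with the exact two-sided Mann–Whitney test on per-specimen HLS.

## Synthetic data

The generator emulates the statistical structure the estimators assume, at
desk scale.  The toy protein is built from ideal α-helix Cα traces
(1.5 Å rise, 100° twist, 2.3 Å radius) in crystal-structure numbering: a
rigid pseudokinase body inside 179–464, a rigid two-helix 4HB stand-in, a
brace helix, the activation-loop helix (343–352) reorienting per frame
against the static adjacent helix (228–240), and an NZ/OE1 pseudo-atom pair
placed at exactly 2.8 Å (bonded) or 6.0 Å (broken).  Each orientable piece
is pre-rotated so the axis *as measured by the pipeline's estimator* is
exactly +z; configured angles then hold by construction.  Per frame, loop
and domain angles are drawn from reflected normals on [0, 180]
(independently by default; an AR(1) option reintroduces the frame
autocorrelation real trajectories have, for exercising the premise that
replicates, not frames, are exchangeable), the bond state is Bernoulli, and
isotropic Gaussian noise (default 0.1 Å) is added to all atoms except the
pseudo-atom pair, whose placement stays exact so the configured probability
is recovered without misclassification bias.  Ubiquitylated constructs add
a chain-B stand-in moiety, excluded from all chain-A selections.

Defaults mirror the study design: 10 replicates, 10 ps spacing, and the
wild-type H-bond scenario probability 0.14.  1000 frames per replicate is
the desk-scale stand-in for the 1 µs production runs (100,000 stored
snapshots); analyses accept any frame count.  Loop angle 65° ± 5° and
domain angle 60° ± 10° are arbitrary-but-fixed recoverable truths, not
fitted to any published ensemble.

What passing tests show: the estimators recover known generating parameters
(pooled angle means within 1°, occupancy within binomial error, RMSF
matching the isotropic closed form σ√3·√((n−1)/n)), the statistics match
brute-force enumerations, and the permutation test holds its nominal
type-I error when replicates truly are exchangeable.  What they do not
show: anything about force-field accuracy, conformational sampling, or the
real MLKL ensembles — the generator has no physics, no correlated domain
motion unless asked for, and Gaussian rather than heavy-tailed noise.
Published ensemble-level numbers (e.g. wild-type occupancy, construct
comparisons) are therefore scenario inputs here, not reproduced results.

## Numerical choices and degenerate inputs

- Superposition requires ≥3 non-collinear points; reflection is excluded by
  construction (proper rotation).  Rank deficiency raises instead of
  silently returning a mirror fit.
- Helix axes require ≥4 Cα; traces of 4–6 Cα skip the smoothing (too few
  points) and use the raw principal axis.
- Angle computation clamps the cosine into [−1, 1] before arccos.
- Frames with a missing selected atom abort the run: silently dropping
  frames would bias occupancy and pooled histograms.
- Exhaustive enumeration caches the assignment-index matrix per group
  shape, making repeated 10-vs-10 tests (e.g. the 1000-dataset calibration)
  cheap.
- Severity grids with proportions that are not exact multiples of 1/n
  allocate the floor counts deterministically and assign the remainder by a
  seeded draw weighted by the fractional parts — documented rounding, never
  an error.
- All generator randomness flows from one integer seed through spawned
  per-replicate streams; identical seed and parameters give byte-identical
  output files.

## Known limitations

- The activation-loop-helix and adjacent-helix residue ranges and the 4HB
  boundary are implementer assumptions (no published definition); they are
  configuration keys and must be revisited for real trajectories.
- The domain-axis construction (principal axes of Cα sets, sign-fixed
  against a reference) is one reasonable geometric definition among
  several; alternative definitions can be substituted at the module surface.
- The Q343 acceptor defaults to OE1; the amide NE2/OE1 assignment is
  ambiguous in practice and swappable by configuration.
- The exact Mann–Whitney enumeration is limited to n₁+n₂ ≤ 20; beyond that
  the tie-corrected normal approximation is used.
- PDB is the only core trajectory format; binary formats (DCD/XTC/NetCDF)
  would enter as adapters producing the same frame objects.
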