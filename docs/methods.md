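# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `ubrec`.

## Structural model

Structures are flat atom lists grouped by chain, in Angstrom, keeping the
author residue numbering of the source PDB.  Default reading hygiene drops
waters and hydrogens and keeps the highest-occupancy alternative location
per atom (ties resolve to the first record); all three behaviours are
configurable.  Multi-model (NMR) files contribute only their first model,
matching common interface-area practice.  Parsing is delegated to gemmi;
unit cell and space group come from CRYST1, and symmetry operators are
looked up from the space-group name in gemmi's tables, since deposited
files carry the name rather than explicit operators.

Orthogonalization uses the standard PDB convention (a along x, b in the
xy plane); the fractionalization matrix is its inverse, and round-trips
hold to 1e-9 relative.

### Symmetry mates

`expand_symmetry` applies every space-group operator followed by the
integer lattice translations whose images can possibly approach the input
(bounding-box arithmetic with a conservative per-axis fractional margin),
and keeps each image with at least one atom within the contact cutoff
(default 5 Å, closed boundary) of the input.  Crystallographic operators
are orthogonal in the Cartesian basis, so images are exact isometries.
Note that in P1 a contact at lattice shift +n always has a mirrored
contact at −n; lattice neighbours therefore come in ± pairs, and callers
that want one pose per physical contact should deduplicate by |shift|.

## Superposition

Residue correspondences pair Cα atoms either by equal residue number or by
global sequence alignment (BLOSUM62, gap open 10, extend 0.5, via
Biopython's PairwiseAligner); the alignment parameters are recorded in the
superposition metadata.  The Kabsch step is the SVD solution of the
orthogonal Procrustes problem with the usual determinant correction that
excludes reflections; collinear point sets are rejected.  By default all
aligned pairs are used with no outlier rejection; an optional iterative
trim (discard pairs deviating more than 2 SD, at most 5 cycles) reports a
core RMSD, because published RMSD values rarely state whether flexible
termini were excluded — reports emit both modes.

`transplant` superposes an anchor subunit of a mobile complex onto the
matching subunit of a target and applies the resulting rigid transform to
the whole complex, carrying a conjugated Ub along; isometry is exact.

## Surface areas

SASA is Shrake–Rupley on a deterministic golden-spiral point set (no RNG):
a sphere of radius r_vdw + probe around each atom is sampled at n points
(default 960; probe 1.4 Å) and a point is accessible unless inside a
neighbour's expanded sphere.  Radii are element-based (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80, Se 1.90, H 1.20 Å); unknown elements get 1.8 Å
with a logged warning so stray ions do not abort a run.  Against an
isolated sphere the implementation is exact to well under 1 %, and the
two-sphere case matches the closed-form spherical-cap solution to <1 %;
an independent Shrake–Rupley implementation (biotite) agrees to ~0.1 % on
random clouds.

Buried interface area runs three SASA computations with identical
parameters (A, B, A∪B) and reports the half-sum convention
½[SASA(A)+SASA(B)−SASA(A∪B)] along with both per-side losses and
per-residue contributions.  The half-sum (per-complex) convention is the
one under which small UBD:Ub interfaces land in the ~400 Å² range quoted
for such complexes; per-side numbers let a reader apply the 2× convention
instead.  Covalent links across the two groups (an isopeptide bond) are
implicitly severed because each group is evaluated as an independent body
— buried area describes the non-covalent contact surface.

`burial_by_neighbours` reports SASA(chain alone) − SASA(chain in context),
a per-side quantity, which is what "subunit X buries N Å²" statements
refer to, plus each pairwise interface.  Residue exposure is the residue's
contextual SASA over a fixed Gly-X-Gly maximum-exposure reference table
(theoretical values), classified exposed at ≥ 0.25.

## Clash detection

Candidate pairs come from a KD-tree query (closed boundary, verified
identical to the quadratic scan in tests); a pair clashes when
r_i + r_j − d exceeds the tolerance (default 0.4 Å, the conventional
steric allowance).  Only heavy atoms participate (hydrogens are dropped at
read time).  The verdict is "incompatible" at ≥ 5 clashing pairs or any
single overlap > 1.5 Å — a documented, configurable operationalisation of
a judgment that is usually made visually; both thresholds are carried in
the report.

## Hydrophobic patch scan

The scan is a deliberate simplification of template-based surface
matching: no geometric hashing, no docking, no refinement.  For every
residue with relative SASA ≥ 0.2, the solvent-exposed area of hydrophobic
atoms (side-chain C/S of A,V,L,I,M,F,W,P,C) within 8 Å of its side-chain
centroid is summed; 8 Å spans the ~400 Å² patches typical of UBD:Ub
interfaces.  Each patch also carries a hydrophobic/polar/charged
composition vector (fractions of exposed area, summing to 1).  Template
similarity is the cosine similarity of composition vectors weighted by the
min/max total-area ratio — in [0, 1], symmetric, and 0 for a purely
hydrophobic versus purely charged pair.  Scores are rank-ordered;
no physical binding energy is implied.

## Binding model

`SingleSiteBinding` fits R([A]) = R_max·[A]/(K_d+[A]) by damped least
squares (scipy trf) with three K_d starts bracketing the tested range
(0.1×, 1×, 10× the top concentration), requiring ≥ 4 distinct
concentrations.  Uncertainty comes from a seeded residual bootstrap
(500 resamples by default) plus asymptotic SEs from the Jacobian.
Classification is "no-binding" when any of: fitted R_max < 3× the
dof-corrected residual SD; R_max below 2× its asymptotic SE (the plateau
is not resolved from zero); or K_d > 10× the highest tested concentration
(the curve never bends in the observed window).  The last two rules matter
because a pure-noise series can transiently mimic a weak binder.  The fit
is scale-equivariant (scaling responses scales R_max, leaves K_d) and
responses can be re-emitted scaled to R_max = 100 for overlay plots.

## Growth model and efficiency

Plate time-lapse stacks are integrated per spot over a 20×20-pixel oval
ROI (pixels whose centers satisfy the ellipse inequality); the per-frame
background estimate is the median of all pixels outside every ROI, times
the ROI pixel count — uniform offsets cancel exactly.  ROIs clipped by the
image edge are an error rather than a silent truncation.

`LogisticGrowth` fits D(t) = K/(1+e^(−r(t−t₅₀))) with three starts.  A
spot is NSG (no significant growth) when the fit fails, the fitted rise
over the observed window is below 3× the residual SD, below 5 % of the
signal scale (this catches exactly flat noiseless series, where both rise
and noise are ~0), or any parameter is non-positive.  Growth efficiency is
the curve slope at half-maximum density divided by the time of half
maximum; the logistic slope at t₅₀ is rK/4 in closed form, so
efficiency = (rK/4)/t₅₀ (units AU/h² — it scales with the density units,
which is why panels consume wild-type-normalised relative efficiencies).
An alternative "plateau" definition, K/t₅₀, is also emitted, since both
phrasings circulate for this statistic; the slope form is primary because
it is the more precise of the two.

Panels normalise K_a = 1/K_d and efficiency to the wild-type construct and
correlate them with Pearson's r (two-sided p).  No-binding constructs are
excluded from the correlation with a logged note (a config flag can
instead include them at a floor K_a); NSG spots are always excluded.

## Synthetic data: what it emulates, what it does not

All generators take a single seed and use one `numpy.random.default_rng`
(PCG64) stream per call; identical parameters and seed give bit-identical
output, and every generator returns a machine-readable ground-truth dict.

- **Toy complexes**: two chains of carbon-like pseudo-atoms on a jittered
  8 Å grid, chain B a rigid transform of chain A, with an optional planted
  number of unique van der Waals overlaps (overlap = tolerance + 0.3 Å).
  A single rigid transform cannot simultaneously be arbitrary and produce
  an arbitrary clash count, so planted-clash atoms are repositioned
  individually and the ground truth records which atom indices still obey
  the transform; transform-recovery consumers use those indices.  A P1
  cell with 40 Å margin supports symmetry tests.  These toys have no
  backbone geometry, B-factors or occupancy structure.
- **Binding series**: Langmuir responses at 8 log-spaced concentrations
  spanning 0.1–3× K_d, with per-point Gaussian noise of stated CV plus an
  optional absolute noise floor (RU).  The floor is what dominates a
  non-binding construct; a purely proportional noise model would give a
  tiny-R_max construct an unrealistically perfect curve.  Defaults (K_d
  270 μM, R_max 50 RU, CV 5 %) sit in the weak-affinity regime typical of
  UBD:Ub interactions.  No drift, no kinetic (on/off) structure.
- **Growth stacks**: Gaussian blobs whose integrated intensity follows a
  per-spot logistic curve, sampled every 0.5 h over 72 h (a 30-min scanner
  cadence over three days), over a uniform background with optional pixel
  noise.  Scenario presets cover wild-type-like growth (K 2000 AU,
  r 0.35 /h, t₅₀ 24 h), reduced mutant growth, NSG and no-binding
  controls.  No scanner optics, vignetting or spot morphology.
- **Construct panels**: six constructs with K_d log-spaced 150–1500 μM and
  growth plateau scaled proportionally to K_a, giving a planted monotone
  efficiency–affinity relation.  Binding is generated in triplicate and
  fitted on the replicate mean, mirroring standard SPR practice; this is
  what makes the panel correlation (r ≈ 0.97–0.999 across seeds) sharp at
  5 % noise.

Passing tests on these inputs demonstrates the correctness of the
geometry, the estimators and the pipeline plumbing — not the biological
accuracy of any particular deposited structure, which still requires
running the same commands on real coordinate files.

## Numerical choices

- Sphere sampling: golden-spiral points; deterministic, so SASA is
  reproducible bit-for-bit at fixed n.  960 vs 4000 points moves toy
  interfaces by < 3 %.
- Optimizers: scipy `least_squares` (trf) with multi-start (3 starts) for
  both fits; non-convergence is flagged (no-binding / NSG), never silent.
- Degenerate inputs: collinear point sets, zero-edge cells, empty
  selections, overlapping interface groups, zero-variance correlation
  inputs and clipped ROIs all raise typed errors.
- Problem sizes in the recovery studies (100 binding series, 200 growth
  curves, 50 neighbour-search fixtures of 200+200 atoms) were chosen to
  make the Monte-Carlo summaries stable to well under their tolerance
  bands while keeping a full run in seconds.

## Known limitations

- Interface areas use the accessible (not molecular/solvent-excluded)
  surface; no shape-complementarity or electrostatics scoring.
- The patch scan is rank-based only; it neither docks nor scores poses.
- The binding model is equilibrium single-site; kinetic SPR analysis and
  drift correction are out of scope.
- Logistic rate r has ~3 % intrinsic sampling SD at the default noise and
  cadence, so single-curve r estimates should be treated as ±5–10 %;
  plateau K and t₅₀ are much tighter.
- Efficiency is unit-bearing (AU/h²); only wild-type-normalised relative
  efficiencies are comparable across experiments.
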