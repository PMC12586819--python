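# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `nodulefab`, and what the synthetic test conditions do and
do not demonstrate about real data.

## HU classes and segmentation

A part-solid nodule is modelled as four density classes tiling
(−750, +∞) HU: core (> 0), gg1 (−300, 0], gg2 (−500, −300],
gg3 [−750, −500]; anything below −750 HU is treated as background (aerated
lung). The published band notation leaves interval closure open; the closure
used here makes 0 HU and −750 HU assignable and the bands disjoint, with the
boundary HU 0 assigned to gg1 (a voxel *at* zero is not "above zero", so it
cannot be core). HU is clamped to [−1024, 3071] on load (12-bit CT
convention) so sentinel values cannot pollute statistics.

Resampling uses trilinear interpolation for intensities and nearest-neighbor
for labels — the standard choice for continuous vs categorical data. The
output grid conserves the physical extent (`shape × spacing`) and aligns
voxel-cell boundaries, so a constant volume stays constant and an affine HU
ramp is reproduced to well under 1 HU away from the clamped edges.

Class meshes come from marching cubes on the binary class mask at iso-level
0.5 with no smoothing: deterministic and volume-faithful (a digitized ball
of radius 30 voxels recovers its analytic volume to ~1%, a cuboid exactly up
to corner chamfers). ROI statistics use voxel centers inside a sphere, or a
slice-confined disc when a thickness is given (mirroring per-slice circular
ROIs in image viewers); the SD is the population SD.

## Lattice geometry

A lattice cube is the union of three orthogonal families of square-section
beams on a common cubic grid, beam section *t × t*, period *p = t + g*. A
point is material when at least two of its three coordinates lie in a beam
band, giving the fill fraction *f = 3r² − 2r³* (*r = t/p*) by
inclusion–exclusion over independent per-axis bands. The generated geometry
and the closed form are pinned to each other two independent ways: the
box-cell mesh volume is computed exactly, and a ray-parity voxelization of
the emitted triangles agrees with *f* to < 0.02 for every default design.

One subtlety makes that exactness possible for arbitrary cube sides: a cube
that is not an integer number of periods clips its outermost beams, which
can shift the realised fill by several points. The band pattern is therefore
phase-shifted (per spec, solved by bisection) so the clipped per-axis
coverage equals the nominal duty cycle *t·side/p*; by the product structure
of the two-of-three rule the enclosed volume then equals *f·side³* exactly.
Beams are clipped flush at the cube boundary so the faces are closed and
printable.

The default design grid is {340, 510, 680} µm thicknesses × {680, 850,
1020, 1360, 1700, 2040} µm voids = 18 samples. Five void values are fixed by
the study conditions; the sixth is not printed anywhere, and 1360 µm
(16 × 85) is used as the interpolated member. Both lists live in
`data/defaults.yaml`, not in code, precisely because this is an assumption a
user may need to change.

## Partial-volume density model

`HU(f) = hu_air + f·(hu_material − hu_air)` with `hu_air` fixed at −1000:
partial-volume averaging acts on linear attenuation, and HU is affine in
attenuation, so mixing is linear in volume fraction. `hu_material` is an
*effective* parameter of the printed-and-scanned system, not a resin
datasheet value. The default is least-squares fitted through the two
measured extremes of the printed calibration cubes — −141 HU at the densest
design (680/680, f = 0.5) and −915 HU at the sparsest (340/2040,
f ≈ 0.0554) — giving ≈ +716 HU. That is far above what a 1.17 g/cm³ resin
would read in bulk; the gap plausibly reflects residual resin trapped in
the lattice voids and scanner-side effects, and is exactly why the model is
declared ideal and calibrated empirically: deviations surface in the fit
residuals and are never silently corrected. `fit_material_hu` refuses
calibration tables with a single distinct fill fraction (rank-deficient).

### Design selection

For a target HU band the selector picks the design whose predicted HU is
nearest the band midpoint, after removing

* visibility exclusions — designs whose lattice shows on CT:
  t = 340 from g ≥ 1700 µm (hard kernel) and t = 680 from g ≥ 1020 µm (both
  kernels) are measured anchors; t = 510 is assigned the conservative
  neighbouring threshold g ≥ 1020 µm, since nothing was reported for it and
  the workflow's priority is avoiding any visible pattern;
* defect exclusions — designs observed to print badly: inhomogeneous
  material at (340, 680) and (510, 680), air gaps at (340, 850).

Ties break toward larger beam thickness (coarser beams print more
reliably). Under the default calibration this reproduces the validated
band-to-design mapping — gg3 → 340/1020, gg2 → 510/850, gg1 → 680/680 —
and the mapping is insensitive to the calibration: it is stable for any
effective material HU between roughly +640 and +850. All rules live in
config; passing empty rule lists recovers unconstrained nearest-HU
selection.

## Boolean mesh kernel

No exact mesh-Boolean library is bundled, and none is needed for the
rectilinear half of the problem: lattice cubes and box primitives carry an
exact *box-cell* representation (per-axis cell edges + a material bitmask),
on which volume, intersection, union, difference, per-voxel occupancy
fractions, and the watertight boundary mesh are all computed exactly.
Booleans between two box-cell meshes are therefore exact (self-intersection
idempotent to 1e−6 and beyond; disjoint unions additive by concatenation).

General watertight meshes (e.g. marching-cubes band surfaces) fall back to a
voxel-remesh: inside/outside logic is composed per voxel center on a fine
shared grid (ray-parity point classification, with sample columns nudged by
an irrational sub-pitch offset so rays through mesh vertices/edges have
measure zero) and one surface is re-extracted with marching cubes. Such
results are flagged `voxel-remesh` in their provenance and are held to the
same volume oracle as the exact path: assembled nodules agree with an
independent voxel oracle at a different, offset resolution to < 2% (measured
~0.2% at the default 0.05 mm pitch). Assembly is deterministic — identical
inputs give byte-identical binary STL.

Band meshes from disjoint HU classes can still graze after marching cubes;
overlaps are resolved by the union itself (no double counting). Bands absent
from a particular nodule are skipped with a manifest entry, not an error.
STL carries no units; millimetres are the declared convention.

## Virtual CT and visibility

The simulator is a desk-scale stand-in for a scanner: occupancy →
partial-volume HU → isotropic Gaussian PSF (default σ = 0.6 mm, the order of
clinical CT resolution) → optional i.i.d. Gaussian noise (seeded). There is
no beam hardening, scatter, dose dependence, or reconstruction-kernel
modelling; consequences: absolute HU accuracy on real scanners is only as
good as the empirical calibration, and kernel-dependent visibility can only
be encoded as rules, not simulated.

The visibility score is the ROI coefficient of spatial variation of
(HU + 1000) plus the normalised spectral amplitude at the lattice frequency
1/p (mean over axes, from axis-projected profiles); a design is "visible"
above a configured threshold (default 0.2). The ROI must span ≥ 3 periods
per axis so the spectral bin exists. An unblurred lattice scores ≳ 1;
blurring with σ = 2p attenuates the fundamental by exp(−2π²σ²/p²) ≈ 0 and
the score drops two orders of magnitude, so the threshold sits in a wide
gap. At fixed σ the score grows with the void size, matching the observed
behaviour that coarse-void designs show their grid.

## Observer-study statistics

Positive class = 3D-printed nodule. Rates are percentages rounded half-up
to 0.1 (table convention); a class-conditional rate whose class is absent is
reported as undefined, never 0. From the published counts the overall table
gives accuracy 53.5, TPR 52.5, TNR 55.5, FNR 47.5, FPR 44.5; the
senior/resident tables give 45.4/57.6 and 57.1/43.3 for the asserted
entries. Two published entries do not recompute from their own counts
(resident accuracy prints 56.8 vs computed 56.9; resident TPR prints 56.8
vs computed 56.7) and are deliberately not asserted anywhere.

Bootstrap CIs are percentile intervals over B resamples; the resampling
unit (response, reader, case) is an explicit argument because clustered
responses widen honest intervals — reader- and case-level resampling is
provided rather than hidden behind a default. Degenerate resamples (a class
missing) are redrawn up to a cap, then an error. Calibration: over 200
seeded simulations of Bernoulli(0.6) accuracy at n = 300 with B = 500, the
95% CI covers the truth 92–96% of the time (B this large is needed for
stable percentile tails; at B = 200 coverage dips toward the high 80s).

Conger's κ is implemented as the exact multi-rater generalisation of
Cohen's κ: observed agreement is the mean pairwise agreement over items;
chance agreement is the mean over rater pairs of the inner product of the
two raters' category marginals. It reduces to Cohen's κ for two raters
(verified on random tables to 1e−12) and a 17-reader guessing simulation
gives |κ| < 0.05 — the near-zero regime the blinded study reported. The
published κ itself needs per-rater data that was never released, so it is
validated by these properties instead of a number.

The χ² goodness-of-fit takes the null proportion explicitly (default 0.5 =
guessing) because the published statistic (136.13 overall) cannot be
reconstructed from the printed counts under chance or independence nulls —
the test construction is underdetermined. What *is* reproducible from the
counts is asserted: χ²(573 correct, 498 incorrect | 0.5) = 5.2521 and the
senior split 2.6698.

## Synthetic data

The nodule generator emulates the geometry the workflow is designed for:
concentric spherical core + three shells at band means +150 / −150 / −400 /
−625 HU (inside both their class intervals and the HU ranges measured on
patient nodules), background −1000 HU, optional Gaussian noise and an
optional low-order lobulation of the outline. It does **not** emulate
irregular patient morphology beyond that perturbation, lung parenchyma
texture, breathing/cardiac artefacts, or scanner reconstruction — so
passing tests show the *pipeline* is correct and self-consistent, not that
segmentation of clinical scans is robust.

The response generator fixes the study design (17 readers = 5 senior + 12
residents, 21 acquisitions = 14 printed + 7 patient, 3 presentations = 1071
responses) and draws calls per reader group from configurable
sensitivity/specificity (defaults at the two groups' near-chance operating
points); confidence is drawn from a distribution mildly peaked at levels
2–3, reflecting the overall low reported confidence. Everything is seeded
and byte-reproducible; the published contingency tables ship as fixtures
with their structural identities (senior + resident = overall cellwise,
totals 1071/315/756) asserted at construction.

## Problem sizes

Tests and the acceptance script run the geometry checks on lattice cubes of
3 periods (≥ 85 ray-parity samples per period, 257³ grids), virtual-CT
consistency on 40³-voxel cubes per design, assembly on a 1.2 mm core +
2.4 mm band sphere pair at 0.05 mm pitch with a 0.034 mm oracle grid, and
the statistical calibrations at 100–200 simulations × B = 200–500
replicates. These sizes were chosen so every check sits well inside its
tolerance while the whole suite stays fast; the underlying code paths are
size-independent.

## Known limitations

* The effective material HU is calibrated from two printed extremes; with a
  full measured design-grid table (the supported CSV schema) the fit would
  be better constrained and residuals diagnostic.
* Visibility is rule-based per beam thickness; kernel- and
  algorithm-specific thresholds are representable in config but only two
  anchors are known.
* The voxel-remesh Boolean path converges in volume but does not preserve
  sharp lattice edges below the grid pitch; for print-ready output the
  lattice side of every intersection is exact, and the pitch is a
  user-facing parameter.
* No support structures, hollowing, printability analysis, ROC/AUC or MRMC
  variance-component modelling — all out of scope.
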