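# Methods

This note documents the models, conventions, and numerical choices
behind `ctveval`, and what its synthetic cohort does and does not show
about real clinical data.

## Masks and geometry

A segmentation mask is a 3-D boolean lattice with voxel spacing
(Δx, Δy, Δz) in mm and an origin; voxel centers sit at
`origin + index · spacing` with 0-based indices. The third lattice axis
(k) is the cranio-caudal axis with increasing k pointing cranially,
matching the dominant RAS/superior-positive NIfTI layout; cohorts
acquired with a different orientation should be reoriented on load.
Binarization maps any value > 0 to foreground, tolerating 0/1 and 0/255
mask dialects. NIfTI-1 headers store spacing as float32, so round-trips
preserve spacing to float32 precision (exactly, for float32-representable
values such as 2.5).

## Post-processing chain

Predictions are cleaned before any comparison, in fixed order:

1. **Largest connected component** (default 26-connectivity, the usual
   3-D clinical convention; 6-connectivity available). Equal-size ties
   keep the component containing the lexicographically smallest voxel
   index, making the output deterministic. A separate
   `remove_small_components` (default threshold 1000 voxels) is provided
   for reference-mask refinement.
2. **Cranio-caudal harmonization** (optional, default on): the
   prediction is cropped, inclusively, to the reference's first/last
   foreground slices. Only the prediction is ever cropped. Deriving the
   crop box from the reference leaks the true extent into every
   prediction; this mirrors the prompted-model protocol it emulates and
   is a deliberate, documented limitation — harmonized metrics measure
   volumetric agreement conditioned on a correct extent, not free-running
   performance.

## Metrics

Overlap: Dice and IoU on voxel counts; two empty masks count as perfect
agreement (1.0), while surface metrics for an empty mask are reported
missing (NaN), never zero — an empty prediction is never rewarded.

Surface distances: the surface of a mask is the set of foreground
voxels with at least one 6-connected background (or out-of-lattice)
neighbor. Directed distances are exact Euclidean distances in mm
between voxel centers (no sub-voxel surface model), computed with an
exact distance transform. ASD, HD, and HD95 are the mean, maximum, and
95th percentile (linear interpolation) of the *pooled* multiset of both
directed distance sets, making all three symmetric by construction.
Pooling (rather than taking the max of per-direction percentiles) is
the common library convention for HD95.

Volume difference is signed positive when the reference (clinical)
contour is larger, in cm³.

Cranial/caudal differences compare the two cranial-most and the two
caudal-most foreground slices respectively, as absolute values in cm
(|Δslices|·Δz/10); signed versions are available for diagnostics.

## Ensemble probability map and residuals

Averaging K boolean predictions yields an agreement fraction k/K per
voxel. The package stores the integer support count and thresholds at
`ceil(p·K/100)` counts, never on floating-point values, so levels are
bit-exact: 100% is the intersection of all models, 100/K% the union,
and the level family {100/K, …, 100} is nested by construction. A tiny
epsilon (1e-9) inside the ceiling guards float noise for fractional
levels such as 100/3. Whether the threshold at an exact boundary is ≥
or > is not observable from the level set itself; ≥ (via the ceiling on
counts) is adopted.

The under-segmentation residual is implemented exactly as its printed
formula, `100·(|V₁₀₀| − |V_clin ∩ V₁₀₀|)/|V_clin|` — the consensus
volume outside the clinical contour, relative to the clinical volume.
Its common verbal gloss ("the clinical CTV not covered by the
consensus") describes a different quantity,
`100·(|V_clin| − |V_clin ∩ V₁₀₀|)/|V_clin|`; that variant is exposed as
the companion diagnostic `under_segmentation_residual_coverage` rather
than silently substituted. Both residuals are pure count ratios and are
zero precisely when `V₁₀₀ ⊆ V_clin ⊆ V_low`, i.e. the clinical contour
lies inside the ensemble confidence band. The residual sum is the
per-patient arithmetic sum. Cumulative curves are plain ECDFs, and the
"crossing" of a cumulative frequency f is the type-7
(linear-interpolation) empirical f-quantile of the residuals.

## Statistical comparison

Segmentation metrics on a test cohort are generally non-Gaussian, so
model comparison is rank-based. The package provides Shapiro–Wilk with
exported QQ pairs as the programmatic stand-in for a visual normality
check (constant input is flagged degenerate, not tested), and a 95%
dispersion interval mean ± 1.96·SD (the band for individual
observations around a noisy metric curve, not the standard error of the
mean — the deliberate reading of an ambiguous convention).

The Friedman statistic uses within-row average ranks for ties and the
plain chi-square form on k−1 degrees of freedom, without the
tie-correction factor, so a fully tied table gives Q = 0, p = 1. On
tie-free data it agrees with `scipy.stats.friedmanchisquare` to
machine precision (checked in the tests); under ties the two differ by
the tie-correction convention.

Conover's post-hoc compares column rank sums R_j with the statistic

    t_ij = |R_i − R_j| / sqrt( 2n(A₁ − C₁)/((n−1)(k−1)) · (1 − T₁/(n(k−1))) )

on a t distribution with (n−1)(k−1) degrees of freedom, where
A₁ = Σ r_ij², C₁ = nk(k+1)²/4, and T₁ is the tie-corrected Friedman
statistic. Pairwise p-values are reported unadjusted by default (Holm
available as a config option); significance marks are gated on a
significant omnibus. Two degenerate regimes are handled explicitly: a
fully tied table (A₁ = C₁) returns p = 1 everywhere, and perfectly
consistent rankings (T₁ = n(k−1)) collapse the variance and give p = 0
for unequal pairs.

**Known property — anticonservative pairs next to an outlier model.**
The variance factor 1 − T₁/(n(k−1)) shrinks when one model ranks
consistently worst, which inflates the pairwise type-I rate *among the
remaining, exchangeable models* above the nominal α (measured ≈8% per
pair at α = 0.05, n = 10, k = 4 on the synthetic cohorts). This is
inherent to Conover's unadjusted procedure, not an implementation
artifact; consumers who need family-wise control should enable Holm
adjustment.

## Synthetic cohort generator

Each patient's clinical CTV phantom is a half-ellipsoid clipped flat at
a posterior chest-wall plane, with laterality (left/right lattice half)
drawn per a configurable mix, smooth random shape variation (a
Gaussian-filtered random field added to the ellipsoid's implicit
function before thresholding, guaranteeing closed surfaces), and a
physical volume drawn from a configurable range. Defaults: voxel
spacing (1, 1, 2.5) mm; volume range 200–1500 cm³ defined at the
default 320×160×80 lattice and scaled proportionally with the physical
lattice volume, so scaled-down lattices keep a realistic fill fraction.
A volume that cannot fit inside the lattice (given the laterality and
chest-wall constraints) raises rather than silently shrinking.

Model predictions perturb the clinical mask with three error modes:

- **Boundary noise** (mm): a unit-variance Gaussian random field with
  10 mm correlation length, scaled by the profile's noise level, is
  compared against the signed Euclidean distance of the clinical
  surface; this displaces the surface smoothly by ~the stated mm scale.
- **Cranio-caudal bias** (slices): each end's shift is drawn from a
  rounded normal with the profile's (mean, SD); positive shifts extend
  the extent by replicating the boundary slice, negative shifts crop.
- **Satellites**: with the profile's probability, one small ellipsoidal
  component (20–80 voxels by default) is placed disconnected from the
  main mask (2-voxel dilation margin).

The default ensemble has four profiles: three *exchangeable* good
models (1.5 mm boundary noise — chosen to land surface distances in the
clinically reported ~1.5 mm regime at 1 mm in-plane voxels — cc-bias SD
2 slices, satellite probability 0.05) and one degraded model (3 mm
noise, cc bias mean 2 / SD 3 slices, satellite probability 0.4)
emulating a high-outlier architecture that the rank tests should single
out.

Randomness is fully deterministic: one master seed; per-patient,
per-stream generators derived via `SeedSequence(seed,
spawn_key=(patient, stream))` with stream 0 for anatomy, 1+m for model
m, and 10000 for the clinician-group label. Regenerating with the same
seed reproduces bit-identical masks and manifests.

**What the phantom does not emulate**: CT intensities, anatomically
detailed breast shape, spatially *correlated* errors between models
(each model's noise field is independent), and systematic
clinician-style bias. The last two matter: real model ensembles share
training data and failure modes, so real consensus volumes stray
outside the clinical contour far more than independent noise does.
Consequently the synthetic under/over residuals and crossings are much
smaller than values observed on clinical cohorts; passing tests
demonstrate the correctness and calibration of the *pipeline*, not the
clinical magnitude of ensemble disagreement.

## Problem sizes

The test suite and the acceptance script use scaled-down cohorts chosen
as the package's own default verification sizes: metric oracles on
12×12×12 lattices, cohort-level checks on 48×48×32 to 96×64×48 lattices
with 5–20 patients, the Friedman calibration on 1000 null tables of
100×6, and the discrimination experiment on 100 cohorts of 10 patients.
At these sizes the full suite runs in a few minutes on one CPU.

## Limitations

- Surfaces are voxel-center based; no sub-voxel surface interpolation,
  so distances are quantized at the spacing scale.
- Harmonization leaks the reference extent (see above).
- The Friedman chi-square approximation is used rather than the exact
  permutation distribution or the Iman–Davenport F form; for small
  n·k the approximation is coarse.
- Unadjusted Conover p-values are anticonservative near an outlier
  model (see above).
- The generator's laterality constraint caps the feasible phantom
  volume per lattice; very large volume requests on small lattices
  raise.
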