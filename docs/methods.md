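# Methods

This note documents the models, estimators and numerical choices behind
`trabfab`, and what the synthetic phantoms do and do not establish about
real CT data.

## Scope and model

Cancellous (trabecular) bone is a porous network of rod- and plate-like
struts. Its directional arrangement within a volume of interest (VOI) is
summarised by a **fabric tensor** `H`: a symmetric positive-definite 3x3
tensor whose eigenvectors `u1, u2, u3` are the principal fabric directions
and whose eigenvalues `e1 >= e2 >= e3 > 0` measure alignment along them.
The **degree of anisotropy** is `DA = e1/e3` (1 = isotropic). The toolkit
estimates per-VOI fabric from segmented CT stacks, references regional mean
fabric directions in a bone-fixed anatomical frame, and provides the
supporting statistics and a thin-walled-tube torsional buckling calculator.

## Voxel grids and coordinates

Grids use the CT-stack axis order `(slice, row, column)` mapping to world
axes `(z, y, x)`; world points and directions are `(x, y, z)` triples in
millimetres, with voxel centres at `origin + index * spacing`. Anisotropic
spacing is supported everywhere except the local-thickness transform, which
assumes near-isotropic voxels (its painting step uses a single radius per
bin).

## Segmentation protocols

Four protocols cover the input regimes the pipeline is designed for:

1. **High-contrast micro-CT** — Bernsen local thresholding over a discrete
   ball window (default radius 5 px): a voxel is bone iff the local
   contrast `max - min` reaches the contrast threshold (default 30) *and*
   the voxel value exceeds the local mid-grey. Low-contrast windows are
   assigned to background; this deliberately drops uniform dense non-bone
   material (dried marrow) *and* implies that solid regions thicker than
   twice the window radius lose their interior — acceptable for trabecular
   struts, which are thinner than that, and the reason the window radius
   must exceed the expected strut half-thickness.
2. **Medical CT (anisotropic voxels)** — 3D cubic upsampling first: in-plane
   axes by a multiplier `m` (default 3), the axial axis by `m*f` where
   `f = slice thickness / pixel resolution`, yielding isotropic voxels at
   `pixel/m`; then protocol 1. If `f < 1` (slices thinner than pixels) only
   the in-plane axes are resampled, down to the slice thickness (the
   protocol-3 geometry).
3. **Peripheral QCT** — in-plane isotropising resample if needed, a small
   3D median denoise (radius 2-3 px), then protocol 1.
4. **Noisy low-voltage scans** — median-difference background subtraction:
   `median3D(small radius) - sequential 2D medians(large radius, all three
   slicing directions)`, negatives clipped at 0; then a small 3D mean
   filter and a global high-pass threshold; finally floating-voxel removal.

All filter windows are discrete balls; borders are edge-replicated so every
filter preserves constants, which makes protocol 4 exactly invariant to
adding a constant to the input.

**Floating-voxel removal** keeps the single largest 26-connected component
(ties broken by first label). Cancellous bone is one connected network, so
anything disconnected is segmentation noise. Corollary for phantom design:
a parallel-rod lattice is *not* connected, so segmentation tests use the
connected three-direction strut lattice; the rod lattice is reserved for
fabric tests, which do not run the cleanup.

**Protocol-4 global threshold.** The threshold is a free parameter (the
workflow this reproduces used a fixed 1-2 grey values chosen per specimen).
When unset, the default is adaptive: `max(2.0, 0.5 * P99.9)` where `P99.9`
is the 99.9th percentile of the smoothed, background-subtracted image. On
structured input `P99.9` sits at the bone plateau, so the cut falls at half
the bone level — the mean filter's half-maximum, i.e. the true boundary.
On structure-free input the percentile collapses toward the residual noise
floor and the absolute floor of 2 grey values dominates. The residual after
median-difference subtraction is the curvature bias of the large-radius 2D
median against the low-frequency drift, of order
`amplitude * (radius / drift wavelength)^2`; with drift varying over the
whole specimen this is well below 2 for realistic scan extents (>= ~128
voxels at the default noise amplitude), which is the regime in which the
structure-free false-positive rate is effectively zero.

## VOI sampling

VOIs are equal spheres on a face-centred-cubic lattice with
nearest-neighbour distance exactly one diameter (touching, never
overlapping), anchored at the mask centroid, with the close-packed [111]
stacking along z by default and any orthonormal orientation accepted. A
sphere is retained when at least 95% of its voxels lie inside the
cancellous mask (voxels beyond the image count as outside). The 95% default
is a reproducible surrogate for manual pruning of VOIs that stray into
cortex or the medullary cavity; 98% (or stricter) is appropriate when the
mask is a simple solid and fully interior VOIs are wanted. Exact 100%
containment is not usable: voxel-count containment of a discretised sphere
is below 1.0 for almost every placement.

**Trabecular spacing (Tb.Sp)** is the mean local thickness of the
background phase: each background voxel is assigned the diameter of the
largest sphere that both covers it and fits in the background, computed
from the Euclidean distance transform with radius binning (40 bins by
default, well below a voxel for typical geometries). The **continuum rule**
accepts a VOI when its diameter spans at least 5 mean trabecular spacings
(boundary inclusive).

## Fabric estimation

**Directions.** `n` quasi-uniform, antipodally unique directions from a
Fibonacci hemisphere lattice, rigidly rotated by a seeded random rotation
so no direction is privileged by the lattice construction. Default
`n = 2049`, the batch-analysis value used throughout; the mean outer
product deviates from `I/3` by < 0.01 (Frobenius) at that size.

**Star volume distribution (SVD, default).** 4,000 points are sampled
uniformly from the bone phase inside the VOI (with replacement when fewer
exist). For each direction a bidirectional ray through each point measures
the uninterrupted bone intercept length, marching at half-voxel steps with
nearest-voxel lookup, censored at the VOI sphere (censored fraction
reported per direction). The directional value used for tensor fitting is
`(mean L^3)^(1/3)` — the star length scale — making SVD and MIL
commensurable.

**Mean intercept length (MIL).** For each direction, a parallel-line grid
(default spacing 2 voxels) spans the VOI disc; `MIL(n)` = total bone length
along the lines / number of bone intercepts. Intercepts shorter than one
voxel are discarded from numerator and denominator: they are below the
scan's resolution, and on voxelised surfaces they are overwhelmingly
staircase fragments of grazing lines. Without this filter the near-axis
MIL of strongly aligned structures collapses (a line almost parallel to a
strut surface fragments into dozens of sub-voxel runs), which both deflates
anisotropy and tilts the recovered primary direction by up to ~15 degrees;
with it, rod-lattice primary directions are recovered to < 4 degrees. A
direction whose line grid meets no bone is censored to the VOI diameter and
flagged. Voxel-based MIL retains a small cubic-symmetric orientation bias
(raw directional values are a few percent higher along grid axes); this
bias has no second-order (quadric) component and therefore does not enter
the fitted tensor, but raw directional ratios should only be interpreted
for microstructure resolved at >= ~5 voxels per feature.

**Tensor fit.** The orientation quadric `n . M . n = 1 / v(n)^2` is fitted
to the directional values by linear least squares over the 6 independent
components of `M`; the fabric tensor is `H = M^(-1/2)`, so `H`'s
eigenvalues equal the directional measure along its principal axes
(the standard MIL-ellipsoid convention). `H` is trace-normalised to 3
(isotropy = identity; the normalisation is internal and affects no ratio),
eigenvalues sorted descending, each eigenvector's sign fixed so its
largest-magnitude component is positive (fabric directions are axes; the
sign carries no meaning). A non-positive-definite fit raises an error that
names the most offending directions. Exact quadric data are inverted to
machine precision; `DA` is invariant under uniform rescaling of the volume
and equivariant under 90-degree lattice rotations to within the
Monte-Carlo noise of the direction sampling (< 2 degrees).

**Batch analysis** derives one direction-set rotation and one point-sample
seed per VOI deterministically from the batch seed, and records per-VOI
failures (no bone phase, degenerate fit) in the result table instead of
aborting.

## Anatomical referencing

The femoral frame is right-handed with +x lateral, +y anterior,
+z proximal: `z` is the inertia-tensor eigenvector with the smallest
moment (the long axis; sign resolved by a caller-supplied proximal point —
automatic detection of "which end is proximal" is deliberately out of
scope), `y = normalize(z x c)` with `c` the medial-to-lateral
condyle-centre vector, `x = y x z`. With +z proximal and `c` pointing
lateral, `z x c` points anterior for a right femur; left bones are mirrored
about the sagittal plane before frame construction, and fabric axes
measured on a left bone are mirrored the same way when referenced
(`AnatomicalFrame.reference_axis`), so left/right twins give identical
angles to machine precision. A near-degenerate inertia tensor (relative
gap between the two smallest moments < 1%) is refused rather than guessed.

Condyle spheres are least-squares fits (algebraic initialisation,
Levenberg-Marquardt geometric refinement) to user-digitised surface-point
patches; coplanar patches are rejected by a singular-value condition test.

**Axial means.** Fabric directions are axes, so each vector is sign-flipped
into the hemisphere of the running resultant before summation, and the
result is refined by a second pass aligning all axes to the first-pass
mean, removing order dependence. The mean is reported with the resultant
length `R-bar = |sum|/n` in [0, 1].

**Angles and stereoplots.** Anterior inclination is the signed angle
between +z and the projection of the axis onto the sagittal (y-z) plane,
anterior positive; medial inclination is the coronal analogue, medial
(-x) positive. Stereographic output is the equal-angle (Wulff) projection:
radius `tan(theta/2)` from the chosen pole (northern or southern
hemisphere), azimuth preserved, antipodal flip into the hemisphere first;
it round-trips with its inverse to 1e-12.

## Statistics

**Major-axis (MA) regression** is the first principal axis of the bivariate
covariance; `r^2` is the squared Pearson correlation. Zero covariance is
resolved toward the larger-variance coordinate; a vertical axis reports an
infinite slope.

**Permutation test of the MA slope** (default 100,000 replicates, two-sided
add-one estimator `p = (1 + #extreme) / (n_perm + 1)`). Permuting y leaves
both marginal variances fixed, so exceedance is assessed on the absolute
centred cross-product `|Sxy|` (monotone-equivalent to `|r|`), which is a
monotone function of the evidence against a zero slope in every variance
configuration. The MA slope itself is *not* monotone in the association
when `var(y) > var(x)` — near-zero covariance then drives the major axis
toward the vertical, so thresholding on `|slope|` would assign large
statistics to null permutations and no p-value below ~0.3 even for a
perfect line. With `|Sxy|`, a perfect line attains the minimum p and the
type-I error is calibrated (0.05 +/- 0.02 over 1,000 null simulations at
n = 50, 2,000 replicates — the documented Monte-Carlo testing reduction of
the 100,000-replicate default).

**Breusch-Pagan**: auxiliary regression of squared OLS residuals on the
predictor. Default is the classical form (ESS/2 of the regression of
`u^2 / mean(u^2)` on x, chi-square 1 df); `studentized=True` gives the
Koenker `n R^2` form (cross-checked against statsmodels). Power against
`sd ∝ x` at n = 200 exceeds 0.8; type-I error is calibrated. The
normal-probability plot the regression workflow calls for is exported as
ordered residuals vs normal quantiles with no automated decision — that
check is visual by design.

**ICC(2,k)**: two-way random-effects, average-measures intraclass
correlation from the two-way mean squares,
`(MSR - MSE) / (MSR + (MSC - MSE)/n)`, with `k = 5` scorers in the
intended use. Bones with any missing score are dropped first (the
reliability of a k-scorer mean is defined only where all k scored); fewer
than two complete rows raises. Agrees with a direct ANOVA oracle and with
pingouin's ICC(A,k) to 1e-9.

**Score aggregation**: a bone's mean score is the mean of its numeric
scores unless 'n/a' entries outnumber them, in which case the aggregate is
'n/a'. A scorer rating the cancellous extent feature as 0 propagates 'n/a'
to that scorer's entries for the dependent orientation/association
features. Synthetic score tables round half-up to the categorical scale
(platform-stable) and clip to the scale range.

## Torsional buckling

Closed-form thin-walled-cylinder relations (SI units):
`D = E t^3 / (12(1 - nu^2))`, `tau_crit = k pi^2 D / (l^2 t)`,
`tau = T / (2 t A) = 2T / (pi d^2 t)` for a circular section, and
`T_crit = K pi^3 d^2 t^3 / (2 l^2)` with `K = k E / (12(1 - nu^2))`.
The chain of the first three reproduces the fourth exactly (verified to
1e-12 relative over random parameter sweeps), and the stated scaling laws
(`t^3`, `d^2`, `l^-2`) hold identically. The module is a calculator: no
empirical `k` is bundled, and validity requires `t << d`, which is
documented rather than enforced.

## Synthetic phantoms: what they emulate, and what they do not

- **Rod lattice** — strongly aligned trabecular tracts: parallel cylinders
  (default radius 0.2 mm, pitch 1.0 mm, ~13% BV/TV) on an optionally
  jittered square grid; ground-truth u1 is the rod axis. Not connected —
  used for fabric recovery, not segmentation.
- **Strut lattice** — union of three orthogonal rod lattices: a connected,
  near-isotropic network (~26% BV/TV) standing in for real cancellous bone
  in segmentation tests.
- **Plate stack** — parallel slabs; ground-truth u3 is the normal, Tb.Sp
  equals the gap exactly.
- **Boolean sphere model** — isotropy control: spheres (default grain
  radius 0.15 mm) placed uniformly until a target BV/TV (default
  tolerance +/-2 percentage points). A finite VOI of this medium carries
  genuine sampling anisotropy that decays with VOI size: per-VOI DA is
  ~1.07 on average at a 2.0 mm VOI radius (13 grain radii) with seed-wise
  maxima ~1.14, and can reach ~1.18 at the 10-grain-radius lower end of
  the continuum regime — a property of the medium, not estimator error.
- **Pseudo-CT corruption** — the noise regime protocol 4 targets: a smooth
  low-frequency field interpolated from a 2x2x2 control grid (drift over
  the whole specimen, like beam hardening; peak amplitude default 60 of a
  255 bone value), salt-and-pepper impulses at 5% of voxels, optional
  Gaussian blur. Deliberately *not* modelled: detector ring artefacts,
  streaking, partial-volume grey ramps at bone boundaries, spatially
  correlated electronic noise. Segmentation Dice on these phantoms
  (>= 0.90 protocol 4, >= 0.95 protocol 1) therefore demonstrates that the
  protocol logic is correct, not that any particular real scan will reach
  those figures.
- **Bone phantom** — femur-like geometry: a cortical tube along +z with two
  distal condylar spheres at known centres and epiphyseal rod-lattice fill
  with a prescribed tilt; used for the end-to-end test that a 20-degree
  anterior fill tilt survives segment -> pack -> fabric -> frame -> mean ->
  angles to within 3 degrees. Trabeculae must be resolvable by the
  protocol in use: the demo uses 0.6 mm rods at 0.2 mm voxels because a
  radius-2 median erases structures thinner than ~2 voxels, exactly as it
  would on a real under-resolved scan.
- **Score tables / allometry samples** — two-way score = bone + scorer +
  residual effects with planted missingness; bivariate lines with optional
  `sd ∝ x^p` heteroscedastic noise, for calibrating the statistics.

## Problem sizes and tolerances

Fabric-recovery checks run 20 random-axis 128^3 rod lattices at the full
2,049-direction / 4,000-point sampling; segmentation checks use 96^3
structured and 128^3 structure-free volumes; the statistics calibrations
use 1,000 null simulations (2,000 permutation replicates each) and 500
power simulations; the demo pipeline phantom is a 30 mm bone at 0.2 mm
voxels. These sizes were chosen so each property is measured with
comfortable statistical margin while a complete run of the suite and the
acceptance script stays in the minutes range on a single CPU. Angular
tolerances (5 degrees for single-VOI recovery, 2 degrees for exact lattice
rotations, 3 degrees end-to-end) reflect Monte-Carlo direction sampling
plus voxelisation, measured margins being several-fold tighter in the SVD
case.

## Known limitations

- Local thickness assumes near-isotropic voxels and reports a binned
  approximation (bin width << voxel for the defaults).
- Voxel-based MIL carries the cubic orientation bias described above; SVD
  is the default estimator partly for this reason.
- The Bernsen variant fixes one convention for low-contrast windows
  (background); data where bone interiors exceed twice the window radius
  need a larger window or protocol 4.
- Condyle patch selection and the proximal hint are user inputs; no
  automatic landmarking is attempted.
- No beam-hardening physics, mesh-based VOI clipping, or fossil-specific
  artefact handling: the qualitative workflow for low-resolution fossil
  scans is out of scope.
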