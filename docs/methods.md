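# Methods

This note records what the package computes, the conventions and numerical
choices behind each stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Coordinate and unit conventions

All computation is in millimeters (mm, mm², mm³). Voxel index `(i, j, k)`
maps to the world position `origin + index · spacing` — a voxel-center
convention with 0-based indices — so physical spacing enters every distance
even for anisotropic voxels. Reporting converts to the clinical units only
at output: volumes in mL, surfaces in cm², diameters and rim widths in cm,
SpCD/SmCD/MSR kept in mm. NIfTI is the exchange format for volumes (spacing
from the header, origin from the affine translation); DICOM handling is out
of scope.

## Segmentation

Foreground is `value ≥ threshold`, where the threshold is either absolute or
a fraction of the volume maximum (PET default 0.40 of SUVmax, a common PET
delineation practice; everything downstream is threshold-parameterized).
Lesions are 26-connected components; components smaller than `min_voxels`
(default 10) are discarded as noise speckles. The *inner* (necrotic /
non-enhancing) region of each lesion is obtained by 6-connected hole
filling: permissive connectivity for merging lesion voxels, conservative
connectivity for declaring a cavity enclosed. Labels are ordered by
decreasing size, and all per-lesion measures are computed on the largest
lesion by filled volume `(N + N′)·Vv` (ties break to the lowest label).

For contrast-enhanced MRI the gray-level threshold can be chosen
per volume: candidate thresholds between an estimated background floor
(border-shell mean + 2 SD) and the volume maximum are scanned, keeping the
lowest one whose largest connected CE component is maximal. This is a
deterministic replacement for interactive slice-by-slice correction; an
optional morphological opening is available but off by default.

**Multilesionality.** Foci are the components at the lesion-defining (high)
threshold. One focus → unifocal. With several foci, if any two fall in a
common component at a *low* threshold — faint elevated background uptake,
operationalized as background mean + 2 SD from the border shell — the tumor
is multifocal; otherwise multicentric. Both map to the boolean
"multilesional" used in the statistics.

**PET total volume.** The filled support `(N + N′)·Vv` is used as the PET
total volume (and as the `V` in MSR and sphericity), i.e. enclosed
low-uptake cavities count toward tumor size. This is an interpretive choice,
consistent with treating `N′` necrotic voxels as part of the tumor.

## SUV metrics

* SUVmax/SUVmean and σ_SUV are computed over the **active** voxels only.
  σ_SUV uses the population convention (divide by N): COV describes the
  voxel set itself, not a sample estimate of a larger population.
* **SUVpeak**: the SUV field of the *whole grid* is convolved with the
  3×3×3 uniform kernel (weights 1/27, zero-padded borders); the peak is the
  mask-restricted maximum of the filtered field. Neighbors outside the
  segmentation but inside the image therefore contribute to the average —
  the filter is applied to the spatial SUV distribution, the mask only
  restricts the arg-max search. The kernel lives on voxel indices, not
  physical mm, so it is always 27 voxels even with anisotropic spacing.
  Arg-max ties break by lexicographic index order.
* COV = σ_SUV / SUVmean; COV ≥ 0.30 is classified heterogeneous (boundary
  value included), below 0.30 homogeneous.
* MTV = N·Vv (mL); TLA = SUVmean × MTV.

## Geometry

* **Surface**: marching cubes at level 0.5 on the filled mask in physical
  coordinates, after a light Gaussian anti-aliasing (σ = 0.8 voxels). A raw
  binary mask produces a staircase isosurface whose area overestimates the
  smooth surface by ~8% *independent of resolution*; the anti-aliased
  surface converges (measured: ≤1.2% error for a 10 mm sphere at 1 mm and
  0.5 mm spacing). Lesions only a few voxels across, where the smoothed
  field never reaches the iso-level, fall back to the raw mask so the area
  stays defined (a single voxel has positive finite area).
* **Sphericity** = π^(1/3)(6V)^(2/3)/S with V, S in mm³/mm². With the
  anti-aliased surface, voxelized spheres measure 1.000 ± 0.01; a mesh
  tolerance of +0.02 above 1 is accepted for discretization.
* **maxD**: maximum pairwise distance between world coordinates of surface
  voxel centers (voxels with a face-adjacent background neighbor), computed
  over convex-hull vertices; degenerate (coplanar/collinear) masks fall back
  to brute force. A single voxel has maxD 0 by convention.
* **Centroid**: unweighted mean of active voxel centers — necrotic voxels
  excluded. An SUV-weighted variant exists behind the `weights` argument but
  is not the default, since the defining sum runs over segmented voxel
  coordinates without intensity weights.
* **SmCD / SpCD**: Euclidean distances (mm) from the SUVmax voxel center /
  SUVpeak cube center to the centroid.
* **MSR** = (3V/4π)^(1/3) with V the *total* (filled) volume, so necrosis
  counts toward the normalizing radius; **nSpCD** = SpCD/MSR. The
  central/peripheral cut defaults to 0.66 — a cohort mean, exposed as
  configuration rather than a constant, because a new dataset should
  recompute it.
* **Spherical rim width** δs = (3V_total/4π)^(1/3) − (3V_inner/4π)^(1/3):
  the difference of equivalent spherical radii, an interpretive
  implementation of "spherical approximation of the average rim size". With
  no inner volume δs equals MSR.

## Phantoms

Phantoms exist so that each measure can be checked against analytic ground
truth. A lesion is a sphere of radius R, optionally perturbed radially by a
band-limited smooth angular function g (a sum of six low-frequency plane
waves on the unit direction, normalized to peak ≈1, fixed by the seed):
`r(u) = R(1 + b·g(u))`. The amplitude b ("bumpiness") is a one-parameter
irregularity axis along which sphericity decreases monotonically from ≈1.
The necrotic core is a concentric low-uptake sphere strictly inside the
lesion. The hotspot is an isotropic Gaussian bump (σ = 2 voxels) added to
the rim uptake at fraction f of the radius along a seeded random direction —
f is the ground truth that nSpCD should recover (measured recovery error
≤0.03 for f ∈ {0, 0.25, 0.5, 0.75, 0.9} at r = 15 mm, 1 mm spacing, well
inside the ±0.1 design tolerance). Two-lesion phantoms can be joined by a
thin corridor at a configurable faint uptake to exercise the
multifocal/multicentric rule. Noise is additive Gaussian truncated at zero.

What the phantoms do **not** emulate: scanner point-spread/partial-volume
effects, Poisson-like PET count noise, MRI bias fields, and irregular
(non-star-shaped) topologies. Passing the phantom tests therefore
demonstrates the correctness of the measurement chain on clean geometry, not
robustness to scanner physics.

## Cohort simulation

Survival times follow a Weibull proportional-hazards model
`S(t|x) = exp(−(t/λ)^k · e^{β᾿x})` with shape k = 1.3 and scale λ = 14.6
months for OS (λ = 6.6 for PFS), chosen so the median OS ≈ 11 months and
median PFS ≈ 5 months at population-typical covariates — the survival scale
of IDH wild-type high-grade glioma. Covariates are drawn to match that
population: age ~ Normal(61.44, 12.64) truncated to [18, 90], multilesional
with probability 0.333, complete chemoradiation (Stupp) protocol with
probability 0.63, sphericity ~ Normal(0.63, 0.14) truncated to (0, 1]. The
default hazard ratios are 1.044 per year of age, 2.813 for incomplete
protocol, 2.203 for multilesionality, and 0.788 per tenth of sphericity.
Covariates enter the linear predictor centered at their population means —
centering moves effects between baseline and predictor without changing any
hazard ratio, and keeps the baseline interpretable as the typical patient.
PFS uses its own hazard ratios (1.027 per year, 2.197 for incomplete
protocol; no multilesion/sphericity effect) and is constrained to
PFS ≤ OS. Censoring is administrative at the empirical (1 − censor_rate)
quantile of the drawn event times (default rate 0.11), which achieves the
requested fraction in expectation and is exactly reproducible.

Because hazard ratios are non-collapsible in Cox models, recovery checks fit
the full multivariate model; a univariate fit of one covariate with the
others active in the generator is attenuated by design, not by error.

## Statistics

* Pearson correlation per (PET, MRI) feature pair with pairwise-complete
  rows; pairs with r > 0.75 and p < 0.05 flagged robust; constant columns
  reported missing.
* Median dichotomization: "≤ median" vs "> median" on the endpoint time
  (ties to the lower group); Welch's unequal-variance t-test by default
  (pooled-variance behind a flag); Kolmogorov–Smirnov normality p reported
  as a flag, not a gate. No multiple-testing correction by default.
* ROC: empirical curve for the rule "positive if value ≥ threshold"; AUC by
  the trapezoidal rule (hence exactly the Mann–Whitney statistic
  U/(n₁n₂), which the tests verify independently); cutoff maximizing
  Youden's J, ties to the lowest threshold, reported as the midpoint between
  that threshold and the next lower observed value. The positive class (poor
  prognosis) is defined by the caller, typically survival ≤ the cohort
  median.
* Kaplan–Meier per group with the two-sided log-rank (Mantel–Cox) test; with
  no censoring the estimator equals the empirical survival function.
* Cox models via partial likelihood with Efron tie handling (appropriate
  for monthly-resolution ties); sphericity rescaled to per-0.1 units so its
  HR reads "per tenth"; Wald 95% CIs and p-values; a warning (not an error)
  below ~10 events per covariate; non-convergence is reported per model with
  NaN estimates and a flag rather than aborting a run.

## Problem sizes used in the test and calibration runs

Grids up to 96³ voxels (10 mm spheres at 0.5 mm spacing); nSpCD recovery at
r = 15 mm on 44³ grids; 20 seeded phantom triplets for the multilesionality
check; Cox calibration with 100 replicates of n = 500 for CI coverage of the
generator truth plus 400 null replicates for type-I error; oracle
equivalence on 200 random 9³ grids (SUVpeak) and 100 random small tables
(ROC). Measured calibration on these sizes: CI coverage ≥ 92% per
covariate, null rejection rates within [2.5%, 7.5%], classification accuracy
100%.

## Known limitations

* Threshold segmentation assumes lesions are brighter than background and
  roughly contiguous; diffuse, non-enhancing, or rim-ambiguous tumors need
  manual methods the package deliberately does not model.
* The necrosis definition (enclosed holes) misses cavities open to the
  lesion surface.
* SUVpeak uses the fixed 27-voxel kernel, so its physical averaging volume
  depends on voxel size; with very anisotropic voxels the "cube" is
  physically elongated.
* The sphericity of very small lesions (a few voxels) is mesh-noisy; values
  there should not be over-interpreted.
* The cohort simulator draws covariates independently of each other, so it
  does not reproduce clinical correlations (e.g. age with resection extent);
  it is a calibration instrument, not an epidemiological model.
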