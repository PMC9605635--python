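# gliomics

PET/MRI radiomic feature extraction and prognostic analysis for high-grade
glioma, with synthetic phantoms and simulated survival cohorts.

## What this package is for

In IDH wild-type high-grade gliomas, the spatial pattern of radiotracer
uptake on choline-PET — not just its intensity — carries prognostic
information: less spherical tumors, multiple lesions, and a metabolic
hotspot displaced toward the tumor boundary all mark more aggressive
disease. `gliomics` implements the full measurement chain for this kind of
study, for imaging scientists who want to compute these markers on their own
volumes or to study the statistical behavior of the pipeline on controlled
synthetic data:

* **Segmentation** — threshold-based semiautomatic delineation of PET and
  contrast-enhanced T1 MRI volumes (26-connected components, configurable
  absolute or fraction-of-maximum thresholds), with an active/inner
  (necrotic) partition by hole filling and a two-threshold
  multifocal/multicentric classifier.
* **SUV metrics** — SUVmax, SUVmean, SUVpeak, metabolic tumor volume (MTV),
  total lesion activity (TLA), and the coefficient of variation
  COV = σ_SUV / SUVmean with the 0.30 heterogeneity cut.
* **3D geometry** — volumes, triangulated-isosurface surface area, maximum
  3D diameter, spherical rim width, and sphericity
  `Φ = π^(1/3) (6V)^(2/3) / S`.
* **Peak-to-centroid distances** — SmCD and SpCD, the Euclidean distances
  from the SUVmax voxel and the SUVpeak cube center to the lesion centroid
  `(x̄, ȳ, z̄)`, and the normalized form
  `nSpCD = SpCD / MSR`, `MSR = (3V/4π)^(1/3)`, a size-free radial position of
  the metabolic hotspot (≈0 central, ≈1 at the boundary).
* **Survival statistics** — PET↔MRI Pearson correlation tables, median
  dichotomization with t-tests, ROC cutoffs by Youden's J, Kaplan–Meier with
  log-rank, and univariate/multivariate Cox proportional-hazards models
  (hazard ratio per year of age, per tenth of sphericity, …).
* **Synthetic ground truth** — 3D lesion phantoms with controllable shape
  irregularity, necrotic core, and hotspot radial position, plus Weibull
  proportional-hazards cohort simulation with known hazard ratios, so every
  stage is testable without patient data.

Volumes are NIfTI (`nibabel`); cohort tables are CSV; all internal
computation is in millimeters, with reporting in the clinical units
(mL, cm², cm).

## Worked example

Build a spherical 15 mm-radius PET phantom whose uptake hotspot sits at
75% of the radius, segment it, and measure it:

```python
from gliomics import (PhantomSpec, LesionSpec, ThresholdRule, make_phantom,
                      segment_threshold, pet_features, geom_features)

lesion = LesionSpec(center=(22.0, 22.0, 22.0), base_radius=15.0, rim_suv=2.0,
                    hotspot_radial_fraction=0.75, hotspot_suv=4.0)
spec = PhantomSpec(grid_shape=(44, 44, 44), spacing=(1.0, 1.0, 1.0),
                   lesions=[lesion], background_suv=0.5, seed=3)
grid, truth = make_phantom(spec)

ls = segment_threshold(grid, ThresholdRule(absolute=1.0))
pf = pet_features(grid, ls, 1)
gf = geom_features(grid, ls, 1, pet=pf)
print(f"SUVmax   {pf.suv_max:.2f}   SUVpeak {pf.suv_peak:.2f}   SUVmean {pf.suv_mean:.2f}")
print(f"MTV      {pf.mtv_ml:.2f} mL   TLA {pf.tla:.2f}   COV {pf.cov:.2f} ({pf.heterogeneity})")
print(f"volume   {gf.volume_total_ml:.2f} mL   surface {gf.surface_cm2:.2f} cm2   sphericity {gf.sphericity:.3f}")
print(f"maxD     {gf.max_diameter_cm:.2f} cm   MSR {gf.msr_mm:.2f} mm")
print(f"SpCD     {gf.spcd_mm:.2f} mm   nSpCD {gf.nspcd:.3f} ({gf.nspcd_class})")
```

prints

```
SUVmax   5.89   SUVpeak 5.06   SUVmean 2.03
MTV      14.15 mL   TLA 28.78   COV 0.11 (homogeneous)
volume   14.15 mL   surface 28.28 cm2   sphericity 1.000
maxD     3.00 cm   MSR 15.00 mm
SpCD     11.00 mm   nSpCD 0.733 (peripheral)
```

The sphere measures as expected — sphericity 1.000, maximum diameter 2r =
3 cm, mean spherical radius 15 mm — and the hotspot placed at radial
fraction 0.75 is recovered as nSpCD 0.733, classified peripheral at the
default 0.66 cut.

The same chain runs from the command line on NIfTI + CSV inputs:

```bash
gliomics --seed 1 all --out runs/demo --n 10        # end-to-end synthetic demo
gliomics phantom --out runs/phantoms --n 5          # phantoms + ground truth
gliomics simulate-cohort --out runs/cohort.csv      # survival cohort CSV
gliomics extract --volumes vols.csv --cohort cohort.csv --out runs/study
gliomics analyze --features runs/study/features.csv --out runs/reports
```

Every run writes a manifest with all thresholds, the seed, and software
versions, so it can be reproduced exactly.

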