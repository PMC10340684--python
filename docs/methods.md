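# Methods

## Coordinate and geometry conventions

Volumes are axis-aligned scalar grids with array axes (x, y, z): x
left–right (the midsagittal plane is a constant-x plane), y
anterior–posterior, z inferior–superior. The world coordinate (mm) of voxel
(i, j, k) is `origin + (i, j, k)·spacing`; voxel indices are 0-based, boxes
half-open `[lo, hi)`. NIfTI files carry a diagonal affine encoding exactly
this mapping; rotated or sheared acquisitions are out of scope (inputs are
assumed coregistered by the hybrid scanner). A voxel belongs to an ROI box
when its center lies inside the closed mm box — this rule is deterministic
and spacing-robust, so mm bounds are invariant to resolution while index
bounds scale consistently.

PET is always resampled onto the CT grid (trilinear interpolation in world
coordinates, zero fill outside support), never the reverse, because the
masks are CT-derived.

## SUV conversion

Body-weight SUV: `SUV = C / (D_dec / W)` with C the activity concentration
in Bq/mL, W the body weight in grams, and `D_dec = D·2^(−Δt/T½)` the
injected dose decay-corrected to the acquisition time (T½ = 109.77 min for
fluorine-18). The decay convention — dose corrected to acquisition start,
equivalently concentrations already decay-corrected by the scanner — is the
common vendor convention and is configurable (`decay_correct=False` uses
the raw dose). Doses are accepted in MBq or mCi (1 mCi = 37 MBq) and stored
in MBq. Alternative normalizations (lean mass, BSA) are not implemented;
body weight is assumed throughout.

## ROI boundary rules

* **Knee**: axial slab from 4 cm inferior to 4 cm superior of the
  intercondylar eminence (80 mm unclipped height). Only the axial planes
  are anatomically prescribed; in-plane, the box spans the lateral
  half-volume on the eminence's side of the midsagittal plane (default:
  the volume's x-center, configurable). This separates left from right
  while keeping femur, tibia, and patella cortex inside the slab.
* **Hip**: lateral border at the femoral head–neck junction plane, medial
  border 2 mm lateral to the pelvic brim (the lateral direction is
  inferred from the junction lying lateral of the brim, which also makes
  the construction side-agnostic), superior/inferior borders 10 mm beyond
  the femoral-neck edge. A medial border falling on the lateral side of
  the junction plane is rejected as inconsistent landmarks. The femoral
  neck is thereby excluded.
* **SI**: 20 mm lateral and medial of the sacrum–ilium articulation line,
  vertically spanning the articulation's superior and inferior ends.

The anterior–posterior extent of hip and SI boxes is not anatomically
prescribed; it defaults to the full AP field of view (configurable
`ap_bounds_mm`). Since only voxels in the bone HU band survive
segmentation, a generous AP extent does not change the mask. Boxes are
clipped to the volume and the clipping is recorded. Landmarks are inputs
(JSON, mm world coordinates), not auto-detected: the method is
deliberately semiautomated, with manual delineation of boundaries.

## Segmentation

Bone is the closed HU band [150, 1500] inside the box (inclusive bounds).
Region growing — connected components of the thresholded set containing
seed voxels, 26-connectivity by default — is available for cases where
disconnected high-density structures must be excluded; inside an
anatomically bounded box the two coincide for connected bone, so plain
thresholding is the default and the choice is recorded in the mask's
provenance. The pipeline's seeded mode takes all voxels ≥ 300 HU
(confident cortical bone) as seeds.

Morphological closing uses a disk structuring element of radius 20
**pixels** applied per axial slice, mirroring slice-based workstation
behaviour; the radius is unitless in the workstation convention, and the
pixel interpretation is adopted (configurable, including a 3D-ball mode).
Closing is implemented by exact Euclidean distance transforms — dilation is
`EDT(background) ≤ r`, erosion `EDT(foreground) > r` — which is
mathematically identical to dilation/erosion with the Euclidean disk/ball
(an offset is in the element iff its norm ≤ r) but scales to radius-20
elements; tests verify exact agreement with direct dilate-then-erode using
an explicit disk footprint. The element is clipped at volume borders
(background padding, no wraparound), the output is clipped to the region
box, and radius 0 is the identity. Closing is computed on the box
subvolume, which is provably identical to closing the full volume and
clipping when the mask is confined to the box.

The global SUVmean is the unweighted arithmetic mean over the final mask's
voxels (voxels are uniform, so no volume weighting is needed); an empty
mask is an error, never a silent zero. The subject-level statistic fed to
correlations is the unweighted left/right average.

## Statistics

Two-sided tests throughout, α = 0.05 by default. Pearson correlations use
pairwise deletion, so the effective n varies per cell and is reported with
every r/p pair; cells with fewer than 3 complete pairs or a degenerate
(zero-variance) variable are reported unavailable. The p-value is the
t-transform `t = r√(n−2)/√(1−r²)` with n−2 df, and equals the p of the
univariate least-squares regression whose slope/intercept are reported
alongside. Laterality is a classical paired t-test on right−left per joint
and tracer (t = 0, p = 1 when all differences vanish), optionally
restricted to right-handed subjects. No multiple-testing correction is
applied by default; Benjamini–Hochberg q-values can be annotated behind a
flag.

The minimal detectable correlation solves the Fisher-z sample-size
approximation `n = ((z₁₋α/₂ + z_power)/atanh(r))² + 3` for r by bisection
to 1e-6 (a closed form exists, but bisection keeps the monotone defining
relation explicit and testable). At n = 18, power 0.8, α = 0.05 this gives
r = 0.619. The formula is approximate and slightly conservative at small
n: simulated power of the Pearson t-test at the returned r is ≈ 0.82 at
n = 18, approaching the nominal 0.80 by n ≈ 50 (the atanh estimator's
finite-sample bias ρ/(2(n−1)) and the "+3" correction both act in the
conservative direction). Tests assert this true behaviour: empirical power
at the returned r is at or above target and close to nominal at moderate n.

## Synthetic phantoms

Phantoms place geometric bone — spheres with a 6 mm cortical shell and
marrow cavity (knee r = 22 mm, hip r = 24 mm with a cortical neck tube that
the hip box must exclude), and hollow boxes with 6 mm walls (SI) — in a
128×128×160 grid at 2 mm spacing (both sides in one volume; unit tests use
64×64×96 at 4 mm, same mm geometry). HU classes: cortex 1000, marrow 100,
soft tissue 40; Gaussian CT noise (σ = 15 HU) is clipped per class so no
voxel crosses the 150/1500 HU thresholds — the threshold rule therefore
reproduces the cortical ground truth with zero-voxel disagreement by
construction, and the sub-150-HU marrow cavity is captured only by
closing, exercising the subcortical-capture property.

PET is generated on its own coarser grid (3 mm default) with activity
`C = SUV_design · D_dec/W` painted over the bone region dilated by 4 mm
(uptake extending into immediately adjacent tissue, as in periarticular
tracer distributions) over a background of SUV 0.4, plus 2% Gaussian noise.
The margin keeps trilinear interpolation at in-mask voxel centers inside
the uniform-activity region, so the designed SUV is recoverable to well
within the 5% end-to-end tolerance; the tolerance absorbs residual
resampling blur and noise. Defaults embed the study conditions: NaF bone
SUV 1.587 (knee-scale bone turnover), doses of 0.11 (FDG) / 0.08 (NaF)
mCi/kg at 77.7 kg, uptake intervals of 180 (FDG) / 90 (NaF) minutes. The
phantoms contain no scanner physics (no attenuation artifacts, Poisson
sinogram noise, motion, or partial-volume effects), so passing tests
demonstrate correctness of the measurement pipeline, not robustness to
acquisition physics.

## Synthetic cohorts

Cohort tables are drawn from a Gaussian copula: a latent multivariate
normal with a designed correlation matrix (validated symmetric PSD; the
offending eigenvalue is reported otherwise) mapped through per-variable
truncated-normal quantile functions calibrated to published-range medians,
IQRs (σ = IQR/1.349), and hard ranges (e.g. BMI median 28.5, range
18.7–44.1). Serum leptin, sclerostin, and DXA total fat have no published
marginals in the calibration source and use typical adult values (ledgered
in the defaults). Weight is derived as BMI·(height/100)², making the BMI
invariant exact at the cost of an implied (slightly high) weight marginal.
Handedness is drawn 13:4:1 right:left:ambidextrous. Per-side uptake
columns are the side average ± half a laterality difference (mean 0, σ = 5%
by default — the no-laterality regime; a shift fraction is available for
power experiments). Missingness is completely at random (default 10–15% on
the serum assays).

The copula preserves rank correlations exactly and Pearson correlations
only approximately; with near-normal truncated marginals the attenuation
is ≈ 0.01 at ρ = 0.5 (checked at n = 5000 within ±0.03). The default design
couples an adiposity block (BMI, leptin, total fat) to uptake — key values
corr(BMI, NaF knee) = 0.50, corr(BMI, FDG knee) = 0.62,
corr(FDG knee, NaF knee) = 0.77 — and requires supporting correlations
among the uptake columns for positive semi-definiteness; a design in which
all uptake columns load on BMI but are mutually independent is not a valid
correlation matrix.

## Problem sizes and numerical choices

Unit and acceptance tests use 64×64×96 phantom grids at 4 mm (identical mm
geometry to the 2 mm default), 10⁴-replicate Monte-Carlo calibrations, a
12-subject phantom cohort for the full round trip, and n = 5000 draws for
copula consistency — sizes chosen so the whole suite exercises every
claim at desk scale. Bisection tolerance 1e-6 on r; BMI consistency
tolerance 0.1; float comparisons at the tolerances stated per test. Seeds
are fixed in specs and flow through `numpy.random.default_rng`; every
generator is deterministic per seed.

## Known limitations

No DICOM series reading, registration, attenuation/scatter modeling,
partial-volume correction, or cortical/trabecular separation; non-diagonal
NIfTI affines are rejected rather than resliced; SUVmax/SUVpeak/TLG are
deliberately absent (the method is defined on SUVmean); clinical
applicability of correlation magnitudes rests on patient data the package
does not ship — the statistics machinery, not patient values, is what is
validated here.
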