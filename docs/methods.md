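# Methods

This package reproduces, on synthetic phantoms with known ground truth, a
hotspot-overlap analysis for head-and-neck tumors imaged with FDG-PET/CT
before radiotherapy and again at local relapse: how well does the
high-uptake sub-volume of the baseline scan predict the location of the
recurrence, and how does that answer depend on (i) whether the patient was
imaged in the radiotherapy treatment position (TP) or not (NTP), and (ii)
whether the two sessions are aligned with rigid (RR) or deformable/elastic
(ER) registration?

Because clinical scan pairs are not available, every quantity is measured
on a simulated cohort whose geometry, session misalignment and lesion
biology are controlled and whose ground truth is exact.  The analysis
chain — threshold segmentation, CT-driven registration, overlap indices,
nonparametric statistics — is the same chain one would run on patient data.

## Phantom model

Each case consists of a baseline session (PET_A, CT_A) and a recurrence
session (PET_R, CT_R) on a 64 x 64 x 48 grid at 2 x 2 x 3 mm (a desk-scale
analogue of clinical PET voxel anisotropy; runtime seconds per case).

**Scene.**  All images are evaluations of one analytic scene: a soft-tissue
ellipsoid body (40 HU) in air (-1000 HU), a spine-like bone cylinder and a
bone sphere (700 HU) near the lesion, and the lesion itself.  The PET lesion
is two-compartment — a high-uptake spherical core (`suv_core`, default 20)
inside a lower-uptake rim (`suv_rim`, default 8) on a background of SUV 1 —
so relative-SUVmax thresholds above/below the rim:core ratio switch between
core-only and whole-lesion masks, as they do in heterogeneous tumors.  The
CT lesion sits at 60 HU.

Soft tissue (and the lesion interior) carries a smooth sinusoidal HU
texture (five plane waves, 25 mm wavelength, +/-120 HU total): real tissue is
heterogeneous at this scale, and without intensity gradients inside
homogeneous compartments an intensity-driven free-form registration is
unconstrained there.  The wave directions are a randomly oriented
orthonormal triple plus two random directions; the orthonormal triple
guarantees gradient coverage along every spatial axis (purely random
directions occasionally land nearly coplanar, which makes one displacement
component unobservable).

**Session motion.**  The forward patient motion baseline -> recurrence is a
rigid transform (3 rotations about the grid center + 3 translations)
composed with a smooth deformation.  Synthesis works with the analytic
inverse map G (recurrence -> baseline): each recurrence voxel center p
takes the scene value at `G(p) = R_inv(p) + D(p)`, where D is a sum of
per-axis sinusoidal displacements (amplitude-capped so max |D| equals
`deformation_amplitude_mm`, wavelength 60-100 mm; the amplitude/wavelength
ratios keep the map invertible, checked by positive Jacobian determinants
on fixtures).  Because the scene is analytic there is no interpolation
error anywhere in the ground truth.  The exact resampling map
baseline -> recurrence (what registration must recover) is obtained by
inverting G with a fixed-point iteration and is stored per case as a rigid
part plus a dense residual field.

**Recurrence biology.**  The recurrence lesion (default smaller than the
baseline lesion) is centered at the forward-mapped baseline hotspot
centroid plus a configurable offset — the biological relapse shift on top
of the geometric session mismatch.  With zero offset and matching geometry
the recurrence reproduces the baseline exactly; as the offset grows to two
lesion radii the true-mask Dice falls monotonically from 1 to 0, which is
the dial the overlap analysis exercises.

**Position groups.**  TP cases draw all six rigid parameters from
+/-1.5 mm / +/-1.5 degrees and have no deformation (immobilization with board and
headrest).  NTP cases put one dominant axis each of rotation and
translation in the 5-8 degrees / 5-8 mm band (others +/-2), plus a 3-6 mm
deformation standing in for weight loss and post-therapeutic tissue
distortion.  These magnitudes are stipulated design values — the clinical
literature motivating this contrast does not quantify repositioning error —
chosen so that the rigid component is large but recoverable and the
deformation is the distinguishing NTP degradation.

**Noise.**  Additive Gaussian noise in SUV (default SD 0.3, clipped at 0)
and HU (default SD 3), drawn from an RNG substream separate from the
anatomy draws so noise realizations can vary under fixed anatomy.  Poisson
reconstruction texture, PSF and motion artifacts are not modeled.

**Determinism.**  A case is a pure function of (config, seed); cohorts
derive per-case seeds from the study seed via `SeedSequence.spawn`, so the
whole study is reproducible bit-for-bit on one platform.

## Segmentation

A sub-volume at threshold x is `{v in region : SUV(v) >= x * SUVmax}`
restricted to the 26-connected component containing the SUVmax voxel
(ties broken at the lowest linear index and logged).  The threshold is
inclusive with a 1e-9 relative tolerance — so the 100 % sub-volume is
non-empty and a voxel sitting exactly on the cut cannot flip with the
rounding of x * SUVmax; masks are nested in x and exactly invariant to
positive rescaling of the PET.  The search region is an
explicit physical bounding box — ground-truth lesion box + 15 mm margin in
simulations, mirroring the manual region placement of clinical practice.
The connected-component restriction keeps remote physiological uptake in
the search box from inflating the VOI.

Baseline scans yield A_30 ... A_90 (7 masks), recurrence scans R_40 and R_70.
MTV is the volume of A_40 in cc; SUVmean is the mean SUV over that mask;
TLG = SUVmean x MTV (g).

## Registration

Both methods register CT_A (fixed) to CT_R (moving) — the sessions share a
modality, so the dissimilarity is mean squared intensity difference — and
the estimated transform maps baseline points into recurrence space, i.e.
exactly the resampling map that pulls recurrence masks onto the baseline
grid.

**RR** optimizes a 6-parameter Euler transform with a regular-step gradient
descent over a 3-level pyramid (shrink 4/2/1, smoothing 2/1/0 mm), metric
restricted to a 40 mm focus box around the lesion (tumor area plus bone
landmarks), full-resolution unsampled metric for determinism.  On noiseless
phantoms a (5 mm, 5 degree) misalignment is recovered to better than
0.15 mm / 0.1 degree.

**ER** composes the rigid initialization with a free-form B-spline field,
refined coarse-to-fine in two stages (32 mm control spacing at shrink 4,
then 16 mm at shrink 3; L-BFGS-B, 20/30 iterations).  Stages are chained by
collapsing the accumulated map to a dense displacement field (ITK does not
support a B-spline as the moving-initial transform of a further metric
evaluation).  The metric is evaluated inside the body (CT > -200 HU),
where tissue constrains the field.  Smoothness is regularized implicitly
by the control-point spacing and the multi-resolution schedule; there is
no explicit bending-energy term.  If the optimized field fails to improve
the body-restricted dissimilarity over the rigid initialization, the rigid
result is returned as a zero field, so ER is never worse than RR in
metric terms.  On noiseless phantoms a 4 mm sinusoidal deformation is
recovered to a mean residual of 0.4-1.0 mm over the lesion (surveyed over
17 field realizations).

**Resampling.**  Scalar volumes are pulled trilinearly; binary masks are
interpolated as floats and re-binarized at 0.5 (on these grids this keeps
sphere volumes within a few per cent — about ten voxel-volumes on an 11 mm
sphere — which is the dominant resampling error of the pipeline).  An
identity transform between matching grids short-circuits to a bit-exact
copy.

## Overlap indices and agreement

For each (A_X, R_X) pair, measured in the baseline grid: Dice
2|A∩R|/(|A|+|R|), Jaccard |A∩R|/|A∪R|, overlap fraction
OF = |A∩R|/min(|A|,|R|), and the directed fractions |A∩R|/|A| and
|A∩R|/|R|.  OF uses the min-denominator definition — the standard overlap
fraction, and the only definition consistent with reported tables in which
OF coincides with |A∩R|/|R| when R is the smaller volume and with
|A∩R|/|A| when A is.  Ratios with an empty denominator are defined as 0
with a warning so cohort aggregation stays total; a pair of two empty
masks is an error.

Index magnitudes are banded poor / fair / moderate / good / very good with
half-open cutpoints at 0.205, 0.405, 0.605, 0.805, which reconciles the
conventional two-decimal band notation (0-0.20, 0.21-0.40, ...) with
continuous values.  The banding is applied to subgroup means; no
inter-rater kappa is computed because the procedure has no second rater —
the conventional kappa-style band labels are reused for mean index values.

## Statistics

Four subgroups are summarized (TP-RR, TP-ER, NTP-RR, NTP-ER): mean, SD and
n per (index, A-threshold, R-threshold) cell, with the band of the mean.
Method contrasts within a position group use Wilcoxon signed-rank tests on
per-case paired differences; position contrasts within a method use
Mann-Whitney U.  Exact null distributions are used for n <= 25 when ties
permit, otherwise the normal approximation with tie correction; all-zero
difference vectors report p = 1.  P-values are reported raw — no
multiple-testing correction across the 70-cell grid, matching the
fidelity-first reporting convention — and every report carries the number
of tests performed.  Significance is read at p < 0.05.  Both tests agree
with permutation oracles on small fixtures (tested).

The uptake arm synthesizes baseline-only sessions for a controlled group
and relapse groups whose lesion radii are shifted one radius-SD upward,
then compares MTV and TLG by Mann-Whitney U.  For that arm the core:rim
uptake ratio is kept below 2.4 so the 40 % threshold always captures the
whole lesion and MTV tracks lesion size rather than jumping bimodally
between core and lesion volume.

## What passing tests do and do not show

The phantoms are deliberately easy relative to patients: uptake is
piecewise-constant, anatomy is smooth, noise is Gaussian, deformations are
low-frequency sinusoids well inside the B-spline model class, and the
recurrence is a sphere offset from the hotspot.  Overlap indices on this
cohort are therefore systematically higher than values reported on
clinical material, and cross-case variance is smaller.  What the synthetic
study does establish is directional and structural: the counting
identities of the study design (43 cases -> 86 scans, 387 VOIs, 6,020 index
values); that the five indices behave exactly as their set-theoretic
definitions; that rigid registration recovers rigid misalignment almost
exactly, so the TP-NTP contrast under RR isolates the un-modeled
deformation; that elastic registration recovers most of the deformation,
so ER > RR off treatment position with paired significance while the
ER-RR difference in TP is near zero; and that larger lesions produce
larger MTV/TLG through the actual segmentation path.  None of this
validates the method on patient data.

## Numerical choices and degenerate inputs

- Volumes in cc throughout; physical coordinates are voxel centers in mm;
  0-based indices; masks stored as unsigned 8-bit NIfTI.
- Thresholds are percentages in configuration (labels A_30 ... A_90) and
  fractions internally; delineation requires a strictly positive SUVmax in
  the search region and errors otherwise.
- Geometry is never defaulted: missing/zero spacing, 4D volumes and
  non-orthonormal direction matrices are errors.
- Registration determinism: unsampled metrics, fixed iteration caps, no
  random sampling; reruns are bit-identical on one platform.
- Study sizes: the default cohort (43 cases at 64 x 64 x 48) runs in
  5-10 minutes on one CPU; per-case cost is dominated by the elastic
  registration (~8 s).

## Known limitations

- No PET reconstruction physics (OSEM/PSF/TOF), no DICOM, no respiratory
  or swallowing motion, no multi-focal disease.
- The elastic method is a generic B-spline stand-in for proprietary
  constrained free-form engines; only its qualitative role (recovering
  smooth non-rigid error) is comparable.
- Binary-mask warping at 0.5 threshold biases very small masks; an R_70
  core of a few voxels can vanish under resampling (handled as an empty-
  denominator case, not an error).
- Agreement bands on phantom means sit higher than clinical experience;
  see "What passing tests do and do not show".
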