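# Methods

`mmseg` implements a semi-automatic detector of multiple-myeloma (MM) focal
lesions on whole-body diffusion-weighted MRI (WB-DWI), with apparent
diffusion coefficient (ADC) quantification and a lesion-level validation
protocol. This note records the model, the conventions and defaults, the
numerically delicate choices, and what the synthetic phantoms do and do not
establish.

## The detection model

MM focal lesions are hypercellular marrow deposits: bright on high-b-value
DWI, at or below muscle intensity on T1-weighted imaging, and almost always
inside or near the skeleton. The detector encodes exactly these three facts:

1. **Search region.** A population DWI template ("atlas") carrying
   pre-drawn masks of the normally hyperintense organs (spleen, kidneys,
   spinal cord, bladder, testes) and of a band around the skeleton is
   registered to the patient's high-b DWI (rigid → affine → B-spline
   free-form deformation, mutual information). Both masks are propagated
   through the resulting transform, the skeleton band is dilated by a
   spherical kernel of 6 mm (to keep the appendicular skeleton in), the
   organ mask by 4 mm (to guarantee complete removal), and the search
   region is the dilated skeleton minus the dilated organs. Dilation radii
   are physical (mm) and spacing-aware: a voxel enters the dilated set iff
   its center lies within the radius of an input voxel center (closed
   ball), so anisotropic grids behave correctly.

2. **Outlier threshold.** Inside the search region, lesion candidates are
   the intensity outliers

       I >= Q3 + k (Q3 − Q1)

   with Q1/Q3 the quartiles *of the region's own intensity distribution*
   (not the whole volume — the region is the organ-removed,
   skeleton-restricted image the rule was designed for). Quartiles use
   linear interpolation of order statistics (the ubiquitous "type 7"
   convention, also what the tests' independent sort-based oracle uses).
   The comparison is inclusive (≥). `k` is a per-patient dial; the default
   4.0 is the most frequently useful value, with a practical range of
   about 2.5–7.5. A zero interquartile range means the region is constant
   and thresholding is meaningless: the code warns and returns no
   components rather than segmenting everything.

3. **Connected components and the T1 filter.** Candidate voxels are split
   into 26-connected components (most permissive 3-D connectivity, so a
   lesion is never split across a face/edge/corner contact; configurable
   to 6 or 18). Components are deterministic: labels are assigned 1..K by
   each component's first voxel in raster order. The T1 volume is
   bias-correctable through an optional N4 hook (delegated to SimpleITK's
   N4 filter) and aligned to the b0 DWI by **rigid-only** registration.
   For each candidate component the fraction `f` of voxels whose aligned
   T1 intensity is strictly greater than the mean intensity of a psoas
   muscle reference mask is computed; the component is removed iff
   `f >= pct_cutoff` (default 0.90, practical range 0.60–0.99). The filter
   only ever deletes whole components — voxel memberships are never
   edited, and no size criterion is applied anywhere in the pipeline.
   Running without T1 ("DWI-only mode") simply skips this stage.

The two dials (`k`, `pct_cutoff`) are the "semi-automatic" part: they are
exposed per case on the CLI (`--k`, `--t1-cutoff`) exactly because no fixed
value works for every exam.

## Registration

The inner optimization is delegated to SimpleITK's registration framework;
this package owns the staging, initialization, composition, and
reproducibility contract.

* Stages: rigid (Euler, initialized by aligning geometric centers), then
  affine, then a single-resolution cubic B-spline free-form deformation;
  each later stage optimizes on top of the earlier stages' frozen result,
  and the total transform composes as rigid∘affine∘FFD (fixed-grid point
  through FFD last-in, i.e. the refinement nests inside the coarse stages).
* Similarity: Mattes mutual information, 32 bins, random voxel sampling at
  a configurable fraction (default 10%) with a seed derived from
  `RegistrationConfig.seed` — registration is therefore bitwise
  reproducible for a fixed config.
* Optimizer: stochastic gradient descent with adaptively re-estimated step
  length — realized as ITK's regular-step gradient descent (step relaxed
  by 0.6 whenever the gradient direction reverses, parameter scales from
  physical shift) under random MI sampling. In our experiments this
  adaptive-step variant converged reliably where ITK's
  learning-rate-estimating gradient descent stalled on
  piecewise-near-constant volumes.
* Multi-resolution: 4 levels for rigid and affine (shrink 8/4/2/1), 1
  level for the FFD, at most 255 iterations per level by default. The FFD
  control-point spacing defaults to 32 mm — coarse relative to whole-body
  anatomy, cheap to optimize, and finer than the smooth inter-subject
  deformations it must capture.
* Intensity images are resampled with linear interpolation. Binary masks
  are warped with nearest-neighbor so the output stays strictly binary;
  the subsequent mm-scale dilations absorb the boundary jitter this
  introduces.
* `RegistrationConfig.desk_scale()` is a reduced preset (3/2/1 levels, 80
  iterations, 40 FFD iterations, 48 mm grid, 5% sampling) used by the test
  suite and the acceptance script on the synthetic volumes, where it
  recovers 10 mm translations to ~0.1 mm; the protocol defaults remain the
  config defaults.
* A constant image has no MI gradient and is rejected; an optimizer that
  stops on its iteration cap logs a warning and the best-so-far result is
  kept.

## Atlas construction

The template is built by iterative mean-image registration: choose a first
template, register every subject to it, average the registered images
(plain voxelwise arithmetic mean, no prior intensity normalization), use
the mean as the next template, repeat — 3 rounds by default, optionally
stopping early once the mean absolute template change falls below a
fraction of the intensity range.

Two refinements make the scheme well-behaved on small cohorts:

* **Representative first template.** `initial_template_index=None` picks
  the subject with the smallest mean squared difference to the naive
  cohort mean — a concrete reading of "choose a representative image".
* **Mean-displacement re-centering.** The raw scheme anchors the template
  to the first subject's pose: every round's mean image lives in that
  subject's frame, so the template inherits its displacement from the
  population mean shape. After each round the average of the subject
  transforms (as a dense displacement field on the template grid) is
  negated and composed into every subject's chain before a single
  resampling pass; the averaged image is thereby re-centered on the
  population mean shape. For identical inputs the correction cancels the
  optimizer's own wobble exactly, which is what makes the fixed-point test
  sharp (template change per round ~1e-6 of the intensity range).

Per-gender atlases are an invocation choice (`--gender` tags the saved
bundle); nothing in the pipeline is gender-specific.

## ADC quantification

ADC is the two-point mono-exponential inversion
`ADC = −ln(S_i/S_0)/(b_i − b_0)` in mm²/s (b in s/mm²). Voxels with a
non-positive signal in either input have no defined ADC and are excluded
via a validity mask instead of becoming ±inf. Negative ADC values (noise
pushing S_i above S_0) are *retained* by default to preserve histogram
shape; `clip_negative` floors them at zero for users who prefer that
convention. Per-lesion reports cover volume (ml = voxel count × voxel
volume / 1000, the radiology convention) and the ADC histogram metrics
median, mean, 5th/25th/75th/95th percentiles (same percentile convention
as the threshold), skewness (Fisher g1) and excess kurtosis (Fisher g2,
normal → 0). Shape statistics of a constant or tiny (<3 voxel) sample are
reported as undefined, never as 0. The report can be restricted to the
predicted components matched to the gold standard, for matched-only
agreement analyses.

## Validation metrics

* **Gold standard**: voxelwise majority vote over reader masks, quorum 3
  of 4 by default.
* **Dice**: 2|A∩B|/(|A|+|B|); undefined (NaN) when both masks are empty.
* **Lesion-level matching**: a gold-standard lesion is detected if at
  least one voxel overlaps any predicted component, and a predicted
  component is correct if it overlaps any gold-standard lesion; each
  lesion and each prediction is counted once regardless of how many
  partners it overlaps (a single blob covering two lesions detects both
  and contributes one correct prediction). Sensitivity = detected/GS,
  PPV = correct/predicted; a 0/0 rate is reported as undefined, never
  silently 0.
* **Printing**: the 3-decimal reporting helper truncates toward zero
  (4/6 → 0.666); full-precision values stay on the metrics object.
* **ICC**: ICC(2,1) — two-way random effects, absolute agreement, single
  measures — computed directly from the two-way ANOVA mean squares, with
  the subject-effect F test (MSR/MSE) for the p-value. The model choice is
  isolated in one function; pingouin's implementation serves as an
  independent cross-check in the tests, not as the implementation.
* The comparison of two DSC distributions (e.g. algorithm-vs-readers
  against inter-reader) delegates to scipy's Wilcoxon signed-rank test.

## The synthetic phantom

`mmseg.phantom` generates paired high-b DWI / b0 / T1 volumes plus ground
truth on one grid, 64×48×112 voxels at 2.5 mm isotropic (160×120×280 mm
field of view) by default — deliberately small so that full-pipeline
experiments run in minutes on a single core. Geometry: an elliptical body
cylinder tapering toward high z, paired low-signal lung voids, a curved
tube as the skeleton band (lesion spheres strictly inside it, non-touching),
ellipsoidal bright organ blobs away from the band, and a box psoas disjoint
from the band. The taper and lungs give the body outline a real z-gradient
so registration is constrained along the body axis. Intensities: DWI
background 100, organs 220–250, lesions at background + `contrast` ×
background-IQR where the IQR is that of the Gaussian noise floor
(1.349 σ); the default contrast of 6 IQRs makes lesions clear outliers
under k = 4, and a "hard" setting of 3 exists for sensitivity curves. T1:
body 300, psoas 150, lesions 80 (hypointense vs psoas); the optional
confounder blob is DWI-bright *and* T1-bright inside the band —
detectable, atlas-invisible, and removable only by the T1 filter. The b0
volume is derived from the high-b volume through the forward model
`S0 = S_high · exp(b · ADC)` with per-tissue ADC (background 1.4×10⁻³,
lesions 0.7×10⁻³ mm²/s), so inverting the model on the noise-free volumes
reproduces the planted ADC exactly. Noise is Rician (magnitude of a
complex Gaussian, σ = 5 by default), the correct magnitude-MRI model;
Gaussian noise is available for analytic tests. Generation is bitwise
reproducible per seed.

Cohorts are smoothly deformed (B-spline, ~90 mm control spacing,
coefficient σ = `deformation_scale`), globally intensity-jittered,
independently-noised copies of one subject; a rigid perturbation mode
(translation σ plus ~2° rotations) exists for registration-recovery
experiments. Truth masks are warped with the same transform
(nearest-neighbor), so set relations are preserved exactly.

**What the phantoms do not emulate:** real marrow heterogeneity (diffuse
infiltration patterns, hematopoietic reconversion), coil-shading
artifacts, station-stitching seams, partial-volume fat/water effects,
anatomically realistic organ shapes, or reader variability. Passing the
synthetic detection suite therefore demonstrates that the algorithm logic
is correct under its own assumptions — not that clinical performance
matches any particular cohort. The clinical-scale agreement numbers
(DSC ≈ 0.27 against a reader consensus, etc.) require real WB-MRI exams
and are out of scope here.

## Problem sizes used by the tests and the acceptance script

Full-pipeline detection runs use 20 default-resolution subjects with 3–8
lesions each (half carrying a confounder), patients being 5 mm-scale
smooth deformations of the atlas anatomy, with the desk-scale registration
preset. Atlas experiments use 5-subject cohorts at 6 mm deformation and 2
averaging rounds; registration recovery uses translations up to 10 mm.
These sizes were chosen so the whole battery completes in well under an
hour on one core while every stage (both registrations included) is
genuinely exercised.

## Known limitations

* The unregularized B-spline stage under stochastic MI cannot drive the
  residual on piecewise-constant synthetic imagery to zero; pairwise
  registration residuals on deformed phantoms plateau at roughly the
  noise-floor×2–3 level. The template-vs-naive-average comparison
  consequently passes with a modest, seed-dependent margin rather than a
  dramatic one.
* The T1 filter uses the Methods-style voxel-fraction rule
  (`f >= cutoff`); an alternative reading based on per-lesion percentiles
  compared to the psoas mean is noted in the source but not implemented.
* The psoas reference mask is an input (manual or atlas-propagated); no
  automatic psoas delineation is provided.
* Extramedullary disease outside the skeleton band is by design invisible
  to the detector.
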