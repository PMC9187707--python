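# Methods

This note documents the models, algorithms and numerical choices behind
`boutonquant`, in the order data flows through the pipeline.

## Acquisition model and the synthetic generator

Real inputs are four-channel 3D spinning-disk confocal stacks of
immunolabeled postmortem cortex: vGlut1 (excitatory bouton marker), vGAT
(inhibitory bouton marker), CB1R (the measured receptor), and lipofuscin
(autofluorescent lysosomal aggregates imaged at constant exposure for
exclusion).  Since no such images ship with the package, the
`synthetic` module generates stacks with the same geometry and a fully
recorded ground truth; every claim the test suite makes about the pipeline
is made against that truth.

**Geometry.** Default lateral pitch 55/512 ≈ 0.1074 µm, z step 0.25 µm,
12-bit ADU ceiling (4095).  Stacks are acquired from the plane furthest
from the coverglass upward, so the last z plane is the tissue surface; the
`ImageStack.surface` field records this and depth-dependent code refuses to
run when it is absent.  Stack depth in a study is 20% of the measured
(shrunken) section thickness.

**Boutons.** Each bouton is a Gaussian core (σ = radius/2) convolved with an
anisotropic Gaussian PSF surrogate for the 1.40 NA optics (σ lateral 0.2 µm,
axial 0.5 µm; configurable), rendered at a drawn peak amplitude
(1500–2500 ADU) and radius (0.25–0.4 µm, giving true volumes well inside
the 0.03–2.0 µm³ analysis gate).  Centres are placed by rejection sampling
with an ellipsoidal exclusion zone — 1.2 µm lateral, 2.0 µm axial by
default — so rendered puncta represent distinct, resolvable boutons; the
axial floor is larger because the PSF is ~2.5× elongated in z and closer
z-neighbours would blend into one mask.

**CB1R channel.** Under each marker punctum the CB1R channel carries a
flat-topped plateau (super-Gaussian, exp(−ρ⁶), lateral half-width 2.6 blob
sigmas, axial 1.7) whose amplitude is calibrated — numerically, against the
PSF-blurred plateau averaged over the ellipsoid a typical mask covers — so
that the *expected mask-mean equals the planted* `cb1r_mean_adu`.  The
plateau shape makes the read insensitive to the exact mask size and keeps
neighbouring boutons from contaminating each other at the allowed
separations; the whole plateau field is then blurred with the PSF so that
deconvolution has a well-defined target.  A constant diffuse background
(100 ADU) models non-bouton (somatic/dendritic) CB1R.  Lipofuscin blobs
additionally bleed a configurable fraction (default 0.5) of their intensity
into the CB1R channel, which is what makes the lipofuscin exclusion filter
consequential.

**Noise.** Poisson noise on photon-equivalent counts (gain 0.5 ADU/photon)
plus Gaussian read noise (3 ADU), then integer quantization and clipping to
the camera ceiling.  Peak SNR at default amplitudes is far above 5.  All
randomness flows from one `numpy.random.Generator`; identical (spec, seed)
pairs are bit-identical.

**Study hierarchy.** A study draws, per site × cell-type row, an expected
CB1R mean = cell mean (species × cell type × region calibration table)
+ subject deviate (shared by all of a subject's rows — the random
intercept) + an independent row deviate; rows are floored at 150 ADU
because a mask mean can never fall below the rendered 100 ADU background.
Default SDs: 300 ADU between subjects, 150 between rows; within a site,
bouton-level means are unit-mean lognormal multiples of the row expectation
(CV 0.4, capped at 2.5 to respect the ADU ceiling).  The lognormal choice
is a modelling assumption, not data-derived.  The default calibration
table plants the primate pattern (inhibitory ≫ excitatory everywhere;
regional variation confined to inhibitory boutons, peaking in A1) and a
human-patterned table is included as an alternative.

**What the generator does not emulate.** Autofluorescence gradients,
spectral crosstalk beyond the lipofuscin bleed, optical aberrations beyond
a Gaussian PSF, anisotropic or non-spherical boutons, spatial clustering of
boutons, and any z-dependence of staining efficiency.  Passing tests
therefore demonstrate the pipeline's correctness and calibration under
these idealized conditions, not performance on real tissue.

## Preprocessing

**Deconvolution surrogate.** The original workflow used a commercial blind
deconvolution; here restoration is Richardson–Lucy with a known (or
user-supplied) PSF, `skimage.restoration` underneath.  It conserves flux to
<1% and sharpens (peak up, FWHM down) as expected.  Because the generator
defines intensity truth on the optics-blurred image, restoring the CB1R
channel *raises* absolute mask means (it concentrates the same flux into
fewer voxels); intensity-recovery analyses therefore run with
`--skip-deconvolution`, and the deconvolution path is validated separately:
on a resolved single bouton with a wide receptor plateau, the mask-mean
read changes by only a few percent between the raw and restored channel.

**DoG channel.** Difference of Gaussians with σ = 0.7 and 2.0 *pixels*,
computed in 2D independently per z plane (the z sampling is anisotropic;
a 3D mode exists but is non-default), reflective boundaries.  Output may be
negative; it is used for segmentation only.

## Segmentation

Iterative combined intensity/morphological thresholding of the DoG channel:

1. T ← Otsu threshold of the DoG grid (256 equal-width bins over the
   observed range).  The Otsu maximizer is computed over bin indices in
   exact integer arithmetic — the between-class-variance maximizer is
   invariant under the affine map from indices to bin centres — so the
   result has no floating-point argmax ambiguity; ties break to the lowest
   edge.
2. Binarize at ≥ T; label 26-connected 3D components; keep components with
   volume in [0.03, 2.0] µm³ (inclusive; 11–693 voxels at default
   geometry); union-merge survivors into the accumulator; T ← T + 50 gray
   levels; repeat until T exceeds the channel maximum (≤ ~82 iterations at
   12 bits).
3. Finalize: relabel the accumulated union, re-apply the size gate (the
   merge can produce out-of-gate components), record each object's birth
   threshold (lowest T at which any of its voxels was accepted).

The gate invariant — no emitted object outside [0.03, 2.0] µm³ — is
asserted on every returned mask set.  Masks are then bound to the
*deconvolved* (or raw, when skipping) channel; all intensity statistics are
means over mask voxels of that channel and never touch the DoG grid.
Lipofuscin is segmented with the same algorithm with the lower bound
dropped and the upper bound removed (aggregates can be large).

## Exclusion filters and the dependent measure

Four independent predicates, keyed on the object centroid (an any-voxel
mode is configurable):

* **Depth** — keep 2 µm ≤ depth ≤ 4 µm, where depth = (distance of the
  centroid from the tissue-surface end, in measured space) / (measured
  thickness / 40 µm).  Antibody penetrance motivates the band; shrinkage
  correction expresses it in original-section coordinates.
* **Edge** — exclude centroids in the outer 2% of x or y (spherical
  aberration near the field edge): bands [0, 0.02·N) and beyond
  N − 1 − 0.02·N for an N-pixel dimension.
* **Overlap** — any object sharing ≥ 1 voxel with an object of the other
  marker channel is excluded from both sides (ambiguous cell type).
* **Lipofuscin** — any bouton sharing ≥ 1 voxel with a lipofuscin mask.

Flags are independent, so filter order is irrelevant; an object survives
iff all four flags are false, and n_total = n_surviving + n_flagged is
asserted per site.  The dependent measure is the arithmetic mean CB1R
intensity over surviving boutons, one row per (site, cell type); a site
with zero survivors of a type emits no row and a warning.

## Mixed-model ANOVA

Per species (never pooled): for site-row y,

y = β₀ + region + cell type + region×cell type + u(subject) + ε,
u ~ N(0, σ²ᵤ), ε ~ N(0, σ²ₑ)

with sum-to-zero factor coding (the Wald F tests are then the Type III
ANOVA tests).  The fitter profiles the REML criterion down to a 1-D search
in λ = σ²ᵤ/σ²ₑ (block-diagonal Woodbury identities make each evaluation
O(n)); the boundary λ = 0 is reachable exactly, where the fit reduces to
OLS with the classical mean-squared-error variance — this is how the
classical two-way ANOVA oracle agreement is exact.  Layer is carried as
metadata but is not a model term.

Denominator degrees of freedom: default "residual" (n − rank X; the
granularity in which results are conventionally reported for site-level
rows), with a Satterthwaite option computed from the observed information
of the REML criterion in (σ²ᵤ, σ²ₑ) by finite differences (per-eigencontrast
df, pooled for multi-df effects); both are reported side by side when
enabled.  Post-hocs mirror the reporting convention: simple-effect F of
region within each cell type (Bonferroni m = number of cell types) and all
pairwise region contrasts within each cell type (m = number of pairs).
Bonferroni is min(1, m·p).

Calibration, measured by the test suite and the acceptance script: the
interaction test's type-I error over 1000 stack-free null replicates is
5% ± 2%; planted cell-type effects of 3× the residual SD are detected at
p < 0.001 in ≥ 90% of replicates.  With only two subjects the plug-in SE
of quantities involving the subject intercept is poorly estimated (the
variance ratio has ~1 df), so 2-SE coverage checks are run where they are
well posed: cell means under more subjects or no subject variance, and
within-subject region contrasts (which cancel the intercept) under the
2-subject design.

## Numerical and degenerate-input choices

* Thresholding is inclusive (≥ T); size-gate bounds inclusive both ends.
* 26-connectivity for 3D labeling (6 configurable).
* Otsu on a constant grid raises a degenerate-histogram error; an empty or
  all-background grid yields an empty mask set, not an error.
* Exposure normalization is idempotent (guarded by a provenance flag) and
  is applied before segmentation and intensity extraction.
* A measured thickness above the 40 µm cut thickness, a nonpositive
  exposure, an unknown stack orientation, a single subject, or an unknown
  config key each raise immediately rather than degrade silently.
* Reruns with the same design/seed/config produce byte-identical CSVs.

## Problem sizes

The packaged analyses use scaled-down fields so a full study runs in
seconds-to-minutes on one CPU: study sites default to 80×80 px (25 boutons
per marker channel; the dense variant 112×112 px with 60) rather than the
full 512×512 acquisition frame — a smaller random sampling window with the
same pixel pitch, z sampling and bouton density regime.  The detection
benchmark keeps the dense 256×256×16 regime with 200 puncta per channel at
a 1.1 µm lateral / 1.6 µm axial placement floor (a 16-plane stack cannot
hold that density at the default axial floor).  Statistical calibration
runs stack-free (site rows simulated directly from the hierarchy), which is
what makes 1000-replicate calibration cheap.

## Known limitations

* Absolute intensity calibration is defined on the optics-blurred image;
  enabling Richardson–Lucy restoration inflates absolute mask means (ratios
  are far less affected).  Real-data users comparing across preparations
  should treat ADU values as relative, exactly as the underlying assay does.
* Touching boutons are not split (no watershed); at the default placement
  floors this costs a few percent of detections in the dense benchmark.
* A bright oversized object cannot be reliably rejected by the size gate:
  the iterative algorithm re-captures its in-gate bright core at higher
  thresholds.  This is a property of the published algorithm, not a defect
  of the implementation; the exclusion-filter demonstration uses dim
  oversized blobs, which the gate does reject.
* With two subjects per species the subject variance is estimable but very
  noisy; fixed-effect tests of within-subject factors remain calibrated
  (they cancel the intercept), which is the regime the study design relies
  on.
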