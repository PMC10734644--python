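# Methods

`dbmasym` quantifies dynamic inter-hemispheric brain asymmetry between two
longitudinal imaging timepoints (a fetal and a neonatal scan) with
deformation-based morphometry (DBM): local anatomical change is read off
the Jacobian determinant of nonlinear image registrations rather than from
segmentations.  Because suitable clinical cohorts are not publicly
deposited, the package ships a synthetic-data generator whose ground truth
is analytic, and every claim the test suite makes is a claim about
recovering that ground truth.

## The two frameworks

**Framework A — asymmetry of growth.**  For each subject the fetal image
is registered to the neonatal image, first linearly (similarity: rigid +
isotropic scale), then deformably.  The log-Jacobian determinant (log-JD)
of the *nonlinear component only* is the growth map: the global scale
change — which dominates this age interval — is factored out, and the map
shows where growth deviated locally from the global trend.  The growth map
is carried into the space of a left-right symmetric neonatal-age template,
where its midline-mirrored copy realizes the "flipped" group, and a paired
voxelwise test of non-flipped vs flipped maps localizes growth asymmetry.
Demeaned gestational ages at both scans enter as nuisance covariates.

A note on the flipped pathway: registering the mirrored brain to the
template with a second numerical registration is mathematically identical
to mirror-conjugating the non-flipped registration when the template is
exactly symmetric — ours is symmetric by construction (a voxel-exact flip
fixed point).  The package uses the conjugation because two independent
numerical registrations are only approximately mirror-equivariant; their
systematic difference (a few hundredths of a log-JD unit with the built-in
engine, consistent across subjects) is indistinguishable from a genuine
asymmetry signal in a paired test and would contaminate the contrast.

**Framework B — static asymmetry and its change.**  Per subject and
timepoint, the image is rigidly midline-aligned to the symmetric mid-age
template (so that "flip" is a pure grid-axis reversal), the mirrored copy
is deformably registered to the original, and the log-JD of that
registration is the static asymmetry map.  The map is transported to the
mid-age template through the original image's linear + deformable template
registration.  Three paired tests follow: static fetal and static neonatal
(each subject's map against its own template-space mirrored copy; demeaned
age at scan and sex as covariates) and temporal (neonatal vs fetal maps;
sex and both ages as covariates).

**Sign conventions.**  `jacobian_log_map` returns log det(I + du/dx) of
the pull-back field (fixed-space point x maps to moving-space point
x + u(x)); a pure scaling field u = (s-1)x therefore gives 3 ln s
everywhere.  Framework A negates this quantity so growth is positive: the
recovered fetal-to-neonatal pull-back contracts wherever the neonate
expanded.  Framework B keeps the raw sign of the flip-to-original
registration.  Every contrast runs as two one-sided tests, one per
direction, each reported at corrected p < 0.025 (together: two-sided 0.05).

## Registration

Linear registration uses a multiresolution (4x/2x/1x) continuous
optimization of the global correlation metric over rigid / similarity /
affine models, initialized from intensity centers of mass plus a
second-moment estimate of the isotropic scale.  Step sizes are
deliberately conservative: a nearly mirror- and point-symmetric brain has
a spurious orientation-reversing optimum almost as deep as the true one,
and large first steps can hop into it.  An orientation-reversing result is
rejected and retried with smaller steps, then raised as an error.

The deformable engine is a multiresolution diffeomorphic demons iteration
(SimpleITK), with Gaussian smoothing of the update field (default sigma
1.5 voxels) and the total field (default 1.0), update steps capped at 2 mm,
and 100/60/30 iterations over the 4x/2x/1x pyramid.  Demons forces are
intensity differences, so the moving image is first mapped onto the fixed
image's intensity distribution by exact quantile matching (histogram
specification); this is what makes cross-contrast (fetal vs neonatal T2)
registration meaningful for the engine.  A returned field must have a
strictly positive Jacobian determinant at every interior voxel; if not,
the registration retries with 1.5x stronger total-field smoothing and
halved steps (up to twice) before raising.  The engine is pluggable:
downstream stages consume only the `DisplacementField`, so an external
registration tool can be substituted without touching morphometry or
inference.

**Background bleaching.**  Skull-stripped images have a dark background
whose interface with bright extracerebral fluid differs strongly between
timepoints and attracts the deformable registration.  Before the nonlinear
step, a deterministic two-class 1D k-means separates background from
brain, and background voxels are set to the image's 99th-percentile
intensity.  Both inputs of a registration must share this preprocessing
(bleaching one side only inverts the background's quantile position and
breaks the intensity standardization); the pipeline bleaches subjects and
template alike, and out-of-field voxels created by resampling are filled
with the bleached background value.

## Morphometry

Log-JD maps are computed by central differences in physical mm (one-sided
at the boundary).  The log scale symmetrizes expansion and contraction and
matches the negative "JD values" such studies report for cortex.  Maps are
transported to template space by interpolation only — never multiplied by
the template-warp Jacobian — because the statistic of interest is the
subject-level quantity evaluated at homologous template locations.
Group smoothing is Gaussian with the kernel renormalized over the in-mask
support (no leakage from outside the brain mask), default FWHM 3 mm,
config-exposed.

## Inference

Paired designs are tested by sign-flipping whole-subject difference maps.
Nuisance covariates enter at the difference level via Freedman-Lane
residualization: differences are residualized against the demeaned
covariates, residuals are sign-flipped, the nuisance fit is added back,
and the full model is refitted per permutation.  When 2^n patterns fit in
the permutation budget (default 5,000) the null is enumerated exhaustively
(minimum p = 1/2^n); otherwise p-values use the add-one estimator
(1+b)/(1+B).

The voxel statistic is a **pseudo-t**: the residual variance map is
smoothed (in-mask, default FWHM 6 mm) before entering the denominator, as
in non-parametric statistical mapping.  With n of order 10-20, plain t
develops unbounded spikes at voxels whose difference variance is
accidentally near zero; those spikes dominate TFCE for the observed and
null statistics alike and destroy power.  The pseudo-t is recomputed
identically for every sign-flip, so exchangeability — and therefore FWER
control — is untouched; the 200-cohort null calibration in the acceptance
suite verifies this empirically.

TFCE integrates extent^E x height^H (E=0.5, H=2) over thresholds
h = dh, 2dh, ..., max with dh = observed-max/100 by default, positive and
negative tails separately, 26-connectivity.  The implementation activates
voxels in descending height order into a union-find structure with lazy
per-component accumulation — exactly equivalent to relabeling the
suprathreshold components at every threshold, which is what the test
oracle does.  Family-wise error is controlled by the max-statistic of the
TFCE map across permutations.  Clusters are the 26-connected components of
corrected 1-p >= 0.975, reported largest-first with their lowest p,
hemisphere (centroid side of the midline), centroid, and the min/max/mean
log-JD of the across-subject mean map inside the cluster.

## The phantom

Anatomy is a nested-shell ellipsoid evaluated analytically at arbitrary
physical points: CSF rim, cortical GM ribbon with sinusoidal boundary
undulation (a folding proxy), WM core, paired deep-GM blobs, paired
ventricles, brainstem, cerebellum.  All terms are even in the left-right
coordinate, so templates are exactly mirror-symmetric.  Sixteen named
landmarks (six midline, five per hemisphere) sit at fixed loci of the
anatomy.  Six-class labels follow the CSF/GM/WM/dGM/BS/Cer legend.

A subject pair is generated as: fetal anatomy = template scaled by 1/s
(default global scale s = 1.3, jittered per subject by 2%, matching the
roughly 2.2-fold brain-volume increase between scans near 32 and 42
gestational weeks), with reduced cortical undulation; neonatal anatomy =
template warped by the planted expansion bumps.  Per-subject variability
comprises the scale jitter, 2% anisotropic shape jitter, in-plane (y,z)
translations (the midsagittal plane stays on the grid-center plane, so
flipping remains a pure axis reversal), undulation phase jitter, and
additive Gaussian intensity noise (sd 2 on a 0-100 intensity scale;
phantoms are high-SNR magnitude-like images, so no Rician model).  T2-like
contrast tables differ between timepoints in magnitude but not intensity
ordering — WM remains hyperintense to cortical GM at both ages, as it does
on T2 until well after term — which keeps monotone intensity
standardization meaningful.  Cohorts default to n = 20 with a 14/6
female/male split and scan ages drawn near 32.4 +/- 1.1 and 41.7 +/- 1.4
gestational weeks.

Planted asymmetry is a sum of radial Gaussian expansion bumps
B(x) = x + (x-c)(m(r)-1), m(r) = 1 + (g-1) exp(-r^2/2 sigma^2), whose
Jacobian is analytic (3 ln g at the center); bump strength is validated at
spec construction so the ground-truth Jacobian stays safely positive.  A
"growth" bump exists only in the neonatal anatomy; a "both" bump plants
identical static asymmetry at the two timepoints, leaving the growth
transform affine.  The default planted site is centered on the cortical
GM/WM transition (local linear scale 1.3, sigma about 1/4 of the brain's
half-width): intensity-driven registration cannot see the expansion of
homogeneous tissue (the aperture problem), so a detectable phantom effect
must straddle image features, and its extent is in line with the large
(several-cm^3) asymmetry clusters reported for this age window.

What the phantom does *not* model: true gyrification (folding is a
boundary undulation, not emerging gyri), MRI artifacts (bias fields,
motion, slice profiles), skull or maternal tissue, or tissue-specific
growth rates.  Passing tests therefore demonstrate that the pipeline
recovers known geometric asymmetry under realistic contrast, noise and
inter-subject variability — not that it resolves the far harder
correspondence problems of real cortical development, where the emulated
study itself notes registration cannot track emerging structures.

## Numerical choices and degenerate inputs

- Canonical space is RAS, left-right on array axis 0; all I/O reorients to
  axis-aligned RAS and oblique orientations are rejected.
- Images use the pull-back (fixed to moving) convention; landmarks move
  with the anatomy (the inverse map).  Field inversion is fixed-point
  iteration, 20 iterations, 0.01 mm tolerance.
- Resampling fills out-of-field voxels with 0, or with the bleached
  background value for bleached inputs; voxel coordinates that overshoot
  the lattice boundary by float rounding (< 1e-6) are snapped back, since
  constant-mode interpolation would otherwise discard a boundary plane.
- Degenerate inference inputs raise: all-zero paired differences
  (degenerate design), rank-deficient covariates, empty smoothing masks,
  non-positive Jacobians.
- Wilcoxon strategy comparisons use the exact null for n <= 25, drop zero
  differences, and report two-sided p; all-zero differences give p = 1
  with a degenerate flag.  Dice omits labels absent from both volumes
  rather than scoring 0.

## Problem sizes

Tests and the acceptance script run the study at desk scale: 32-cube
phantoms for calibration and determinism checks, 40- or 48-cube 20-subject
cohorts for planted-effect recovery, 256-512 permutations where the
exhaustive null or the planted effect size makes more permutations
uninformative.  The spatial design is fully parameterized, so the
clinical-scale configuration (0.75 mm grids, 5,000 permutations) is a
config change, not a code change.

## Known limitations

- The demons engine under-recovers the planted log-JD amplitude (roughly
  a third of the analytic value at the default regularization): DBM
  effect sizes are engine- and regularization-dependent, which is one of
  the points the evaluation protocol is designed to expose.
- The static-asymmetry maps of Framework B inherit any non-mirror-
  equivariant bias of the engine; the static contrasts difference each
  map against its own mirror, which cancels the symmetric part of that
  bias but not an antisymmetric part.
- FWER calibration exercises the inference stack on registration-free
  null maps (smoothed noise in the brain mask); running hundreds of full
  registration cohorts is outside desk scale, and exchangeability — the
  property FWER rests on — does not depend on how the per-subject maps
  were produced.
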