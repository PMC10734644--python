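# dbmasym

Deformation-based morphometry (DBM) of **dynamic inter-hemispheric brain
asymmetry** between two longitudinal imaging timepoints — the setting of
fetal-to-neonatal MRI studies, where the brain more than doubles in volume
between scans and the question is not *whether* it grows but *where growth
differs between homotopic regions of the two hemispheres*.

The package implements the full analysis chain, exercised end to end on
synthetic phantom cohorts with known, planted asymmetric growth:

- **Framework A (growth asymmetry).** Register each subject's fetal image
  to its neonatal image (linear + diffeomorphic), take the log-Jacobian
  determinant (log-JD) of the nonlinear component as the growth map —
  `log det(I + du/dx)`, global scale factored out — and test non-flipped
  vs midline-flipped growth maps voxelwise in a symmetric template space.
- **Framework B (static asymmetry and its change).** Per timepoint,
  register each brain's mirror image to itself; the log-JD is the static
  asymmetry map.  Carry the maps to a mid-age template and test static
  asymmetry per timepoint plus its fetal-to-neonatal change.
- **Inference.** Paired sign-flip permutation testing (exhaustive when
  2^n fits the budget), Freedman–Lane covariate adjustment, pseudo-t with
  smoothed variance, threshold-free cluster enhancement
  (TFCE: Σ e_h^E · h^H · dh, E=0.5, H=2), max-statistic FWER control, and
  cluster tables (size, lowest corrected p, hemisphere, per-cluster log-JD
  min/max/mean) at corrected p < 0.025 per direction.
- **Evaluation.** Registration accuracy via per-label Dice, the absolute
  relative volume difference |(|A|−|B|)/|A||, per-landmark Euclidean
  distances over 16 named anatomical landmarks, and exact Wilcoxon
  signed-rank comparisons between registration strategies.
- **Phantoms.** An analytic nested-shell brain (six tissue classes,
  sinusoidal cortical undulation, 16 landmarks) generating longitudinal
  cohorts with known global scaling, lateralized Gaussian expansion bumps
  with closed-form Jacobians, per-subject anatomy jitter, contrast
  differences between timepoints, and intensity noise.

## Worked example

Twenty synthetic subjects with a left-hemisphere growth bump (local linear
scale 1.3) planted at the cortical GM/WM transition, 48³ grids:

```python
from dataclasses import replace
import dbmasym as d

spec0 = d.PhantomSpec(grid_shape=(48, 48, 48))
spec = replace(spec0, asym_sites=(d.default_asym_site(spec0, "L"),))
cohort = d.synthesize_cohort(20, spec, seed=11)

cfg = d.FrameworkConfig()
cfg.inference.n_perm = 512
cfg.inference.seed = 11

report = d.run_framework_a(cohort, d.build_template(spec0, "neonatal"), cfg)
print(report.clusters.df[["hemisphere", "size_voxels", "lowest_p",
                          "jd_mean", "centroid_x", "contrast"]])
```

Output (a few minutes on one core):

```
  hemisphere  size_voxels  lowest_p   jd_mean  centroid_x               contrast
0          L          707  0.001949  0.171424   14.544554  nonflipped_gt_flipped
1          R          707  0.001949  0.020034   32.455446  flipped_gt_nonflipped
```

The significant cluster (corrected p = 0.002, 707 voxels) sits in the left
hemisphere at the planted site — its overlap with the analytic bump
support is Dice 0.66 — and its mean growth log-JD (+0.17) shows the extra
left-sided expansion.  The mirrored right-hemisphere cluster in the
opposite contrast direction is the same effect seen from the other side of
the paired flip design.

A command-line interface wraps the same stages
(`dbmasym phantom | register | jacobian | framework-a | framework-b |
evaluate | validate`), configured by a schema-validated YAML file; every
run writes a manifest with the config snapshot and seeds so it can be
reproduced bit-identically.

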