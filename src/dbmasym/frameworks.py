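"""End-to-end orchestration of the two asymmetry frameworks.

Framework A (growth asymmetry): register each subject's fetal image to its
neonatal image (linear + deformable), take the log-JD of the nonlinear
component as the growth map, and carry it into the space of a symmetric
neonatal-age template.  There the flipped pathway (mirrored brain and JD
registered to the template) is realized by mirror-conjugating the
non-flipped registration — exact for a mirror-symmetric template — and
flipped vs non-flipped growth maps are tested voxelwise.

Framework B (static asymmetry and its change): per timepoint, mirror the
midline-aligned image and register the mirrored copy to the original; the
log-JD of that registration is the static asymmetry map.  Asymmetry maps
are carried to a mid-age template, where three paired tests run: static
fetal, static neonatal (each subject's map against its own mirrored copy)
and temporal (neonatal vs fetal maps).

Sign conventions.  Growth maps are reported growth-positive: the log-JD of
the recovered fetal->neonatal pull-back is negated, so a region that
expanded more than the global affine predicts has a positive value.
Static maps keep the raw log-JD of the mirror-to-original registration.
Every contrast runs as two one-sided tests (one per direction), each
thresholded at corrected p < 0.025.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import AffineTransform, VolumeGrid, flip_lr, resample
from .inference import (ClusterTable, DesignInfo, InferenceConfig,
                        PermutationResult, extract_clusters,
                        paired_permutation)
from .morphometry import (JDMap, jacobian_log_map, propagate_to_template,
                          smooth_in_mask, stack_maps)
from .phantom import SubjectPair, TemplateBundle
from .registration import (RegistrationConfig, bleach_background,
                           register_deformable, register_linear, warp)

log = logging.getLogger("dbmasym")


@dataclass
class FrameworkConfig:
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    smooth_fwhm_mm: float = 3.0
    bleach: bool = True
    linear_model: str = "similarity7"

    def snapshot(self) -> dict:
        return {
            "registration": asdict(self.registration),
            "inference": asdict(self.inference),
            "smooth_fwhm_mm": self.smooth_fwhm_mm,
            "bleach": self.bleach,
            "linear_model": self.linear_model,
        }


@dataclass
class FrameworkReport:
    framework_tag: str
    subjects: list                       # per-subject manifest dicts
    results: dict                        # direction tag -> PermutationResult
    clusters: ClusterTable
    config: dict
    seed: int
    design: DesignInfo | None = None

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.clusters.to_tsv(out_dir / f"{self.framework_tag}_clusters.tsv")
        if self.design is not None:
            cols = {"pair_id": self.design.pair_ids}
            for j, name in enumerate(self.design.covariate_names):
                cols[name] = self.design.covariates[:, j]
            pd.DataFrame(cols).to_csv(
                out_dir / f"{self.framework_tag}_design.csv", index=False,
                float_format="%.6f")
        for tag, res in self.results.items():
            g = res.grid()
            g.like(res.corrp).save(out_dir / f"{self.framework_tag}_{tag}_corrp.nii.gz")
            g.like(res.observed_stat).save(out_dir / f"{self.framework_tag}_{tag}_tstat.nii.gz")
        manifest = {
            "framework": self.framework_tag,
            "seed": self.seed,
            "config": self.config,
            "subjects": self.subjects,
            "directions": {tag: {"n_perm": int(res.n_perm_effective),
                                 "exhaustive": bool(res.exhaustive),
                                 "max_stat": float(res.observed_stat.max()),
                                 "min_p": float(1.0 - res.corrp.max())}
                           for tag, res in self.results.items()},
        }
        with open(out_dir / f"{self.framework_tag}_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def _prep(img: VolumeGrid, cfg: FrameworkConfig) -> VolumeGrid:
    return bleach_background(img) if cfg.bleach else img


def _background_value(img: VolumeGrid) -> float:
    """Fill value for resampling: the (constant) corner background."""
    return float(img.data[0, 0, 0])


def _register_to_template(image: VolumeGrid, template_image: VolumeGrid,
                          cfg: FrameworkConfig):
    """Linear + deformable subject->template registration (pull-back maps
    template space -> subject space).  Both images must share the same
    preprocessing (bleached or raw)."""
    lin = register_linear(image, template_image, model=cfg.linear_model)
    aligned = resample(image, template_image, lin,
                       fill=_background_value(image))
    fld = register_deformable(aligned, template_image, cfg.registration)
    return lin, fld


def _both_direction_inference(maps_A, maps_B, design, cfg, mask, reference,
                              jd_groups, direction_tags):
    """Run the one-sided test in both directions; pooled cluster table."""
    results, tables = {}, []
    for tag_a, tag_b, tag in ((0, 1, direction_tags[0]),
                              (1, 0, direction_tags[1])):
        stacks = (maps_A, maps_B)
        res = paired_permutation(stacks[tag_a], stacks[tag_b], design,
                                 cfg.inference, mask=mask,
                                 reference=reference)
        results[tag] = res
        tab = extract_clusters(res, jd_groups, cfg.inference,
                               midline_x=reference.center[0])
        tab.df["contrast"] = tag
        tables.append(tab.df)
    non_empty = [t for t in tables if len(t)]
    merged = (pd.concat(non_empty, ignore_index=True) if non_empty
              else tables[0])
    return results, ClusterTable(merged)


# ---------------------------------------------------------------------------
# Framework A
# ---------------------------------------------------------------------------

def run_framework_a(cohort, neonatal_template: TemplateBundle,
                    cfg: FrameworkConfig | None = None) -> FrameworkReport:
    """Growth-asymmetry analysis: flipped vs non-flipped growth JD maps.

    Per subject: fetal->neonatal linear+deformable registration, growth
    log-JD from the nonlinear component only, propagation to the symmetric
    template (where the flipped pathway is the mirror-conjugate of the
    same registration), mask-restricted smoothing, then a paired
    sign-flip permutation test with demeaned fetal and neonatal
    gestational ages as covariates.
    """
    cfg = cfg or FrameworkConfig()
    tpl = neonatal_template
    tpl_img = _prep(tpl.image, cfg)
    mask = tpl.labels.brain_mask()
    maps_nonflip, maps_flip, manifests, kept = [], [], [], []
    for pair in cohort:
        try:
            fet = _prep(pair.fetal.image, cfg)
            neo = _prep(pair.neonatal.image, cfg)
            lin = register_linear(fet, neo, model=cfg.linear_model)
            fet_lin = resample(fet, neo, lin, fill=_background_value(fet))
            growth_field = register_deformable(fet_lin, neo, cfg.registration)
            # growth-positive: negate the pull-back log-JD
            jd = jacobian_log_map(growth_field,
                                  source=f"A:{pair.subject_id}").negated()

            lin_n, fld_n = _register_to_template(neo, tpl_img, cfg)
            jd_t = propagate_to_template(jd, lin_n, fld_n, tpl.image)
            # The mirrored pathway (flipped brain + JD registered to the
            # template) is realized by mirror-conjugating the non-flipped
            # registration: for an exactly symmetric template the two are
            # mathematically identical, and conjugation enforces the
            # mirror-equivariance that two independent numerical
            # registrations only approximate.
            jdf_t = JDMap(jd_t.values[::-1].copy(), jd_t.spacing,
                          jd_t.origin, jd.source + ":flipped")
            maps_nonflip.append(smooth_in_mask(jd_t, mask, cfg.smooth_fwhm_mm))
            maps_flip.append(smooth_in_mask(jdf_t, mask, cfg.smooth_fwhm_mm))
            kept.append(pair)
            manifests.append({
                "id": pair.subject_id,
                "fetal_age_GW": pair.fetal.age_GW,
                "neonatal_age_GW": pair.neonatal.age_GW,
                "sex": pair.sex,
                "fet2neo_scale": lin.scale,
                "template_propagation": "linear+deformable composition",
            })
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            log.warning("framework A: subject %s failed: %s",
                        pair.subject_id, exc)
    if len(kept) < 2:
        raise RuntimeError("fewer than 2 subjects survived framework A")

    design = DesignInfo(
        pair_ids=[p.subject_id for p in kept],
        covariates=np.column_stack([
            [p.fetal.age_GW for p in kept],
            [p.neonatal.age_GW for p in kept]]),
        covariate_names=["fetal_GW", "neonatal_GW"])
    A = stack_maps(maps_nonflip)
    B = stack_maps(maps_flip)
    results, clusters = _both_direction_inference(
        A, B, design, cfg, mask, tpl.image,
        jd_groups={"nonflipped": A, "flipped": B},
        direction_tags=("nonflipped_gt_flipped", "flipped_gt_nonflipped"))
    return FrameworkReport("frameworkA", manifests, results, clusters,
                           cfg.snapshot(), cfg.inference.seed, design)


# ---------------------------------------------------------------------------
# Framework B
# ---------------------------------------------------------------------------

def _static_asymmetry_map(image: VolumeGrid, template: TemplateBundle,
                          cfg: FrameworkConfig, tag: str,
                          template_image: VolumeGrid | None = None):
    """Static asymmetry log-JD of one timepoint, in template space.

    The image is rigidly midline-aligned to the symmetric template so the
    flip is a pure axis reversal, the mirrored copy is registered to the
    original, and the log-JD of that field is propagated through the
    original's template registration.
    """
    tpl_img = template_image if template_image is not None \
        else _prep(template.image, cfg)
    rigid = register_linear(image, tpl_img, model="rigid6")
    aligned = resample(image, tpl_img, rigid, fill=_background_value(image))
    flipped = flip_lr(aligned)
    fld = register_deformable(flipped, aligned, cfg.registration)
    jd = jacobian_log_map(fld, source=tag)
    lin, defo = _register_to_template(aligned, tpl_img, cfg)
    return propagate_to_template(jd, lin, defo, template.image)


def run_framework_b(cohort, midage_template: TemplateBundle,
                    cfg: FrameworkConfig | None = None,
                    analyses=("static_fetal", "static_neonatal", "temporal")):
    """Static asymmetry per timepoint plus its fetal->neonatal change.

    Returns three reports: static fetal, static neonatal (each: subject
    asymmetry map vs its own mirrored copy, with demeaned GW at scan and
    sex as covariates) and temporal (neonatal vs fetal asymmetry maps,
    with sex and both ages as covariates).  ``analyses`` restricts which
    of the three inferences are run (skipped ones return None).
    """
    cfg = cfg or FrameworkConfig()
    tpl = midage_template
    tpl_img = _prep(tpl.image, cfg)
    mask = tpl.labels.brain_mask()
    fet_maps, neo_maps, manifests, kept = [], [], [], []
    for pair in cohort:
        try:
            fet_jd = _static_asymmetry_map(
                _prep(pair.fetal.image, cfg), tpl, cfg,
                tag=f"B:fetal:{pair.subject_id}", template_image=tpl_img)
            neo_jd = _static_asymmetry_map(
                _prep(pair.neonatal.image, cfg), tpl, cfg,
                tag=f"B:neonatal:{pair.subject_id}", template_image=tpl_img)
            fet_maps.append(smooth_in_mask(fet_jd, mask, cfg.smooth_fwhm_mm))
            neo_maps.append(smooth_in_mask(neo_jd, mask, cfg.smooth_fwhm_mm))
            kept.append(pair)
            manifests.append({
                "id": pair.subject_id,
                "fetal_age_GW": pair.fetal.age_GW,
                "neonatal_age_GW": pair.neonatal.age_GW,
                "sex": pair.sex,
                "template_propagation": "linear+deformable composition",
            })
        except Exception as exc:  # noqa: BLE001
            log.warning("framework B: subject %s failed: %s",
                        pair.subject_id, exc)
    if len(kept) < 2:
        raise RuntimeError("fewer than 2 subjects survived framework B")

    sex_code = np.array([1.0 if p.sex == "F" else 0.0 for p in kept])
    fet_age = np.array([p.fetal.age_GW for p in kept])
    neo_age = np.array([p.neonatal.age_GW for p in kept])
    ids = [p.subject_id for p in kept]

    F = stack_maps(fet_maps)
    N = stack_maps(neo_maps)
    F_flip = F[:, ::-1]
    N_flip = N[:, ::-1]

    reports = {"frameworkB_static_fetal": None,
               "frameworkB_static_neonatal": None,
               "frameworkB_temporal": None}
    selected = {f"frameworkB_{a}" for a in analyses}
    for tag, A, B, cov, names in (
        ("frameworkB_static_fetal", F, F_flip,
         np.column_stack([fet_age, sex_code]), ["fetal_GW", "sex"]),
        ("frameworkB_static_neonatal", N, N_flip,
         np.column_stack([neo_age, sex_code]), ["neonatal_GW", "sex"]),
        ("frameworkB_temporal", N, F,
         np.column_stack([sex_code, fet_age, neo_age]),
         ["sex", "fetal_GW", "neonatal_GW"]),
    ):
        if tag not in selected:
            continue
        design = DesignInfo(pair_ids=ids, covariates=cov,
                            covariate_names=names)
        if tag == "frameworkB_temporal":
            groups = {"neonatal": N, "fetal": F}
            dirs = ("neonatal_gt_fetal", "fetal_gt_neonatal")
        else:
            groups = {"nonflipped": A, "flipped": B}
            dirs = ("nonflipped_gt_flipped", "flipped_gt_nonflipped")
        results, clusters = _both_direction_inference(
            A, B, design, cfg, mask, tpl.image, jd_groups=groups,
            direction_tags=dirs)
        reports[tag] = FrameworkReport(tag, manifests, results, clusters,
                                       cfg.snapshot(), cfg.inference.seed,
                                       design)
    return (reports["frameworkB_static_fetal"],
            reports["frameworkB_static_neonatal"],
            reports["frameworkB_temporal"])


# ---------------------------------------------------------------------------
# registration-accuracy evaluation protocol
# ---------------------------------------------------------------------------

def run_registration_evaluation(cohort, template: TemplateBundle,
                                cfg: FrameworkConfig | None = None) -> pd.DataFrame:
    """Accuracy of the three large registration steps on a cohort.

    For each subject: fetal->neonatal, fetal->template and
    neonatal->template registrations are scored by propagating the moving
    labels and landmarks and computing per-label Dice, per-label absolute
    volume difference, and per-landmark Euclidean distance against the
    target's own labels/landmarks.  Returns the long-format AccuracyTable.
    """
    from .evaluation import (accuracy_table, dice_per_label, landmark_error,
                             volume_difference_per_label)
    from .grid import map_points

    cfg = cfg or FrameworkConfig()
    records = []
    for pair in cohort:
        cases = (
            ("fet2neo", pair.fetal, pair.neonatal.image,
             pair.neonatal.labels, pair.neonatal.landmarks),
            ("fetal2template", pair.fetal, template.image,
             template.labels, template.landmarks),
            ("neonatal2template", pair.neonatal, template.image,
             template.labels, template.landmarks),
        )
        for strategy, moving_tp, fixed_img, fixed_labels, fixed_lm in cases:
            mov = _prep(moving_tp.image, cfg)
            fix = _prep(fixed_img, cfg)
            lin = register_linear(mov, fix, model=cfg.linear_model)
            mov_lin = resample(mov, fix, lin, fill=_background_value(mov))
            fld = register_deformable(mov_lin, fix, cfg.registration)
            composed = fld.compose_affine(lin)
            moved_labels = resample(moving_tp.labels, fixed_labels, composed,
                                    interpolation="nearest")
            moved_lm = map_points(moving_tp.landmarks, composed)
            for lbl, v in dice_per_label(fixed_labels, moved_labels).items():
                records.append((pair.subject_id, strategy, "dice",
                                fixed_labels.legend.get(lbl, str(lbl)), v))
            for lbl, v in volume_difference_per_label(
                    fixed_labels, moved_labels).items():
                records.append((pair.subject_id, strategy,
                                "volume_difference",
                                fixed_labels.legend.get(lbl, str(lbl)), v))
            for name, v in landmark_error(moved_lm, fixed_lm).items():
                records.append((pair.subject_id, strategy, "landmark_mm",
                                name, v))
    return accuracy_table(records)
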