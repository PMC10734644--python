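"""Phantom generator: symmetry, determinism, analytic ground truth."""

import numpy as np
import pytest

from dbmasym import PhantomSpec, analytic_growth_jd, build_template, flip_lr
from dbmasym.phantom import (AsymSite, BumpMap, default_asym_site,
                             synthesize_cohort, synthesize_subject,
                             spec_from_dict, spec_to_dict)

from conftest import clean_spec


class TestTemplate:
    def test_image_is_exact_flip_fixed_point(self, template32):
        assert np.array_equal(flip_lr(template32.image).data,
                              template32.image.data)

    def test_labels_mirror_consistent(self, template32):
        assert np.array_equal(flip_lr(template32.labels).labels,
                              template32.labels.labels)

    def test_midline_landmarks_on_midplane(self, template32, spec32):
        mid = spec32.center[0]
        for name in ("PMJ", "posterior_commissure", "culmen"):
            assert template32.landmarks[name][0] == pytest.approx(mid)

    def test_sixteen_landmarks_with_hemisphere_suffixes(self, template32):
        names = template32.landmarks.names
        assert len(names) == 16
        assert sum(n.endswith("_L") for n in names) == 5
        assert sum(n.endswith("_R") for n in names) == 5

    def test_labels_partition_head_mask(self, template32):
        labels = template32.labels.labels
        fractions = [np.mean(labels[labels > 0] == k) for k in range(1, 7)]
        assert sum(fractions) == pytest.approx(1.0)
        assert all(f > 0 for f in fractions)  # every tissue class present

    def test_asymmetric_spec_rejected(self, bumped_spec48):
        with pytest.raises(ValueError):
            build_template(bumped_spec48, "neonatal")

    def test_mid_age_template_sized_between_timepoints(self, spec32):
        neo = build_template(spec32, "neonatal")
        mid = build_template(spec32, "mid_age")
        fet = build_template(spec32, "fetal")
        vols = [int(t.labels.brain_mask().sum()) for t in (fet, mid, neo)]
        assert vols[0] < vols[1] < vols[2]


class TestSubject:
    def test_deterministic_in_spec_and_seed(self, spec32):
        a = synthesize_subject(spec32, 5)
        b = synthesize_subject(spec32, 5)
        assert np.array_equal(a.fetal.image.data, b.fetal.image.data)
        assert np.array_equal(a.neonatal.labels.labels, b.neonatal.labels.labels)
        assert a.fetal.age_GW == b.fetal.age_GW

    def test_symmetric_spec_gives_flip_symmetric_subject(self, clean_pair):
        for tp in (clean_pair.fetal, clean_pair.neonatal):
            assert np.allclose(flip_lr(tp.image).data, tp.image.data,
                               atol=1e-10)
            assert np.array_equal(flip_lr(tp.labels).labels, tp.labels.labels)

    def test_neonatal_older_and_bigger(self, clean_pair):
        assert clean_pair.neonatal.age_GW > clean_pair.fetal.age_GW
        assert (clean_pair.neonatal.labels.brain_mask().sum()
                > clean_pair.fetal.labels.brain_mask().sum())

    def test_forward_map_carries_fetal_landmarks_to_neonatal(self, clean_pair):
        moved = clean_pair.ground_truth.forward_points(
            clean_pair.fetal.landmarks.positions)
        assert np.allclose(moved, clean_pair.neonatal.landmarks.positions,
                           atol=1e-6)


class TestGroundTruthJD:
    def test_zero_without_growth_bumps(self, spec32, clean_pair):
        jd = analytic_growth_jd(spec32, clean_pair)
        assert np.all(jd.values == 0.0)

    def test_static_bumps_cancel_in_growth_jd(self):
        spec0 = clean_spec((32, 32, 32))
        site = default_asym_site(spec0, "L", peak_factor=1.2, timing="both")
        spec = clean_spec((32, 32, 32), asym_sites=(site,))
        pair = synthesize_subject(spec, 3)
        jd = analytic_growth_jd(spec, pair)
        assert np.abs(jd.values).max() < 1e-9

    def test_peak_value_and_location(self, bumped_spec48):
        site = bumped_spec48.asym_sites[0]
        pair = synthesize_subject(bumped_spec48, 3)
        jd = analytic_growth_jd(bumped_spec48, pair)
        g = bumped_spec48.grid()
        peak_vox = np.unravel_index(jd.values.argmax(), jd.shape)
        peak_mm = g.voxel_to_world(peak_vox)
        assert np.linalg.norm(peak_mm - np.asarray(site.center)) <= site.radius_mm
        assert jd.values.max() == pytest.approx(3 * np.log(site.peak_factor),
                                                rel=0.05)

    def test_matches_finite_difference_of_composed_transform(self, bumped_spec48):
        """Analytic log-JD vs central differences of the analytic forward
        map, evaluated on continuous coordinates (step 1e-3 mm)."""
        pair = synthesize_subject(bumped_spec48, 3)
        gt = pair.ground_truth
        g = bumped_spec48.grid()
        jd = analytic_growth_jd(bumped_spec48, pair).values
        rng = np.random.default_rng(0)
        idx = rng.choice(np.flatnonzero(jd > 0.01), size=20, replace=False)
        pts = g.world_coords().reshape(-1, 3)[idx]
        h = 1e-3
        for p, expected in zip(pts, jd.ravel()[idx]):
            x0 = gt.neonatal_bumps.inverse(p[None])[0]  # template anatomy pt
            J = np.zeros((3, 3))
            for j in range(3):
                e = np.zeros(3)
                e[j] = h
                J[:, j] = (gt.neonatal_bumps((x0 + e)[None])[0]
                           - gt.neonatal_bumps((x0 - e)[None])[0]) / (2 * h)
            assert np.log(np.linalg.det(J)) == pytest.approx(expected, abs=1e-3)

    def test_monotone_in_peak_factor(self):
        spec0 = clean_spec((32, 32, 32))
        base = default_asym_site(spec0, "L", peak_factor=1.15)
        values = []
        for g in (1.1, 1.2, 1.3):
            site = AsymSite(base.center, base.radius_mm, g, "L")
            spec = clean_spec((32, 32, 32), asym_sites=(site,))
            pair = synthesize_subject(spec, 3)
            jd = analytic_growth_jd(spec, pair)
            values.append(jd.values.max())
        assert values[0] < values[1] < values[2]

    def test_bump_volume_consistency(self, bumped_spec48):
        """Integral of exp(log-JD) over a region approximates the warped
        region's volume ratio (mask-warping oracle, < 2% relative)."""
        pair = synthesize_subject(bumped_spec48, 3)
        gt = pair.ground_truth
        g = bumped_spec48.grid()
        jd = analytic_growth_jd(bumped_spec48, pair).values
        site = bumped_spec48.asym_sites[0]
        # region = sphere around the bump in template (pre-bump) space
        pts = g.world_coords().reshape(-1, 3)
        r = np.linalg.norm(pts - np.asarray(site.center), axis=1)
        region_template = (r <= 1.5 * site.radius_mm)
        vol_template = region_template.sum()
        # volume integral of exp(jd) over the warped region
        region_neo_pts = gt.neonatal_bumps.inverse(pts)
        region_neo = (np.linalg.norm(region_neo_pts - np.asarray(site.center),
                                     axis=1) <= 1.5 * site.radius_mm)
        vol_integral = np.exp(-jd.ravel()[region_neo]).sum()
        assert vol_integral == pytest.approx(vol_template, rel=0.02)


class TestBumpValidation:
    def test_overly_strong_bump_rejected(self, spec32):
        site = default_asym_site(spec32, "L", peak_factor=4.0)
        with pytest.raises(ValueError, match="Jacobian|magnitude"):
            clean_spec((32, 32, 32), asym_sites=(site,))

    def test_site_outside_brain_rejected(self, spec32):
        with pytest.raises(ValueError, match="outside"):
            clean_spec((32, 32, 32), asym_sites=(
                AsymSite((1.0, 1.0, 1.0), 4.0, 1.2, "L"),))

    def test_wrong_hemisphere_declaration_rejected(self, spec32):
        c = spec32.center + spec32.semi_axes * np.array([0.4, 0, 0])
        with pytest.raises(ValueError, match="hemisphere"):
            clean_spec((32, 32, 32), asym_sites=(
                AsymSite(tuple(c), 4.0, 1.2, "L"),))

    def test_bump_map_inverse_roundtrip(self, bumped_spec48, rng):
        bm = bumped_spec48.neonatal_bumps()
        pts = rng.uniform(10, 38, size=(50, 3))
        assert np.allclose(bm(bm.inverse(pts)), pts, atol=1e-6)


class TestCohort:
    def test_sex_ratio_matches_study(self):
        spec = clean_spec((16, 16, 16))
        cohort = synthesize_cohort(20, spec, seed=1)
        sexes = [p.sex for p in cohort]
        assert sexes.count("F") == 14 and sexes.count("M") == 6

    def test_age_distributions_near_study_means(self):
        spec = clean_spec((16, 16, 16))
        cohort = synthesize_cohort(20, spec, seed=1)
        fetal = np.mean([p.fetal.age_GW for p in cohort])
        neonatal = np.mean([p.neonatal.age_GW for p in cohort])
        assert abs(fetal - 32.4) < 1.0
        assert abs(neonatal - 41.7) < 1.0

    def test_reproducible_and_distinct(self):
        spec = PhantomSpec(grid_shape=(16, 16, 16), noise_sd=0.0)
        a = synthesize_cohort(4, spec, seed=9)
        b = synthesize_cohort(4, spec, seed=9)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.fetal.image.data, pb.fetal.image.data)
        ids = {p.subject_id for p in a}
        assert len(ids) == 4
        assert not np.array_equal(a[0].fetal.image.data,
                                  a[1].fetal.image.data)

    def test_cohort_too_small_rejected(self, spec32):
        with pytest.raises(ValueError):
            synthesize_cohort(1, spec32, seed=0)


class TestSpecSerialization:
    def test_roundtrip_through_dict(self, bumped_spec48):
        d = spec_to_dict(bumped_spec48)
        back = spec_from_dict(d)
        assert back.grid_shape == bumped_spec48.grid_shape
        assert back.asym_sites == bumped_spec48.asym_sites
        assert back.fetal_contrast == bumped_spec48.fetal_contrast
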