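"""Synthetic longitudinal brain phantoms with known growth and asymmetry.

The generator emulates the data structure a fetal/neonatal asymmetry study
assumes: per subject, a pair of T2-like volumes related by a known global
scaling (brain growth over roughly nine weeks) plus optional localized,
lateralized expansion "bumps"; six-class tissue labels; sixteen named
anatomical landmarks; intensity noise and tissue-contrast differences
between the timepoints.  Anatomy is a nested-shell ellipsoid (CSF rim,
undulated cortical GM ribbon, WM core, paired deep-GM blobs and
ventricles, brainstem, cerebellum), defined analytically so that labels,
landmarks, and the ground-truth transform are all evaluated in closed form
at arbitrary physical points — no interpolation error enters the ground
truth.

Ground-truth geometry.  Template (neonatal-scale) anatomy lives at scale 1;
a subject's fetal anatomy is the template scaled by 1/s.  Localized
expansion is a sum of radial Gaussian bumps B(x) = x + sum_i (x-c_i)
(m_i(r)-1) with m_i(r) = 1 + (g_i-1) exp(-r^2 / 2 sigma_i^2); its Jacobian
is analytic.  A bump with timing "growth" is present only in the neonatal
anatomy (asymmetry appears between timepoints); timing "both" plants the
same static asymmetry at both timepoints, so the growth transform stays
purely affine there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import (LabelVolume, LandmarkSet, TISSUE_LEGEND, VolumeGrid,
                   flip_lr)
from .morphometry import JDMap
from .registration import DisplacementField

# T2-like tables: unmyelinated WM is hyperintense to cortical GM at both
# ages; the WM/GM contrast narrows toward term as myelination begins, so
# the two timepoints differ in contrast magnitude but not intensity order.
FETAL_CONTRAST = {0: 0.0, 1: 100.0, 2: 42.0, 3: 66.0, 4: 52.0, 5: 48.0, 6: 56.0}
NEONATAL_CONTRAST = {0: 0.0, 1: 100.0, 2: 48.0, 3: 58.0, 4: 53.0, 5: 50.0, 6: 54.0}

#: normalized (unit-ellipsoid) landmark offsets; _L is the negative-x side
_LANDMARKS_MID = {
    "posterior_commissure": (0.0, -0.15, 0.10),
    "infracollicular_sulcus": (0.0, -0.35, -0.30),
    "PMJ": (0.0, -0.27, -0.50),
    "fourth_ventricle_caudal": (0.0, -0.42, -0.80),
    "optic_chiasm": (0.0, 0.31, -0.45),
    "culmen": (0.0, -0.54, -0.30),
}
_LANDMARKS_HEMI = {
    "rostral_hemisphere": (0.32, 0.88, 0.0),
    "rostral_temporal": (0.73, 0.38, -0.40),
    "rostral_ventricle": (0.27, 0.38, 0.10),
    "caudal_ventricle": (0.27, -0.23, 0.10),
    "caudal_hemisphere": (0.36, -0.85, 0.0),
}


@dataclass(frozen=True)
class AsymSite:
    """One lateralized Gaussian expansion bump in template space."""

    center: tuple          # mm, template space
    radius_mm: float       # Gaussian sigma = radius_mm / 2
    peak_factor: float     # local linear scale g at the bump center
    hemisphere: str        # "L" or "R"
    timing: str = "growth"  # "growth" (neonatal only) or "both"

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("bump radius must be positive")
        if self.peak_factor <= 0:
            raise ValueError("peak_factor must be positive")
        if self.hemisphere not in ("L", "R"):
            raise ValueError("hemisphere must be 'L' or 'R'")
        if self.timing not in ("growth", "both"):
            raise ValueError("timing must be 'growth' or 'both'")


@dataclass
class PhantomSpec:
    """Study conditions for the synthetic cohort.

    Defaults encode the emulated study: a fetal scan near 32.4 GW and a
    neonatal scan near 41.7 GW separated by a ~1.3x linear brain scale-up,
    a 14/6 female/male cohort of twenty, and high-SNR T2-like contrast.
    """

    grid_shape: tuple = (64, 64, 64)
    spacing_mm: float = 1.0
    global_scale: float = 1.3
    asym_sites: tuple = ()
    noise_sd: float = 2.0
    fetal_contrast: dict = field(default_factory=lambda: dict(FETAL_CONTRAST))
    neonatal_contrast: dict = field(default_factory=lambda: dict(NEONATAL_CONTRAST))
    undulation_amp_fetal: float = 0.015
    undulation_amp_neonatal: float = 0.035
    scale_jitter_sd: float = 0.02
    shape_jitter_sd: float = 0.02
    translation_jitter_mm: float = 1.5
    fetal_age_mean: float = 32.4
    fetal_age_sd: float = 1.1
    neonatal_age_mean: float = 41.7
    neonatal_age_sd: float = 1.4
    female_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.asym_sites = tuple(
            s if isinstance(s, AsymSite) else AsymSite(**s)
            for s in self.asym_sites)
        if not (1.0 < self.global_scale <= 1.6):
            raise ValueError("global_scale must lie in (1, 1.6]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self._validate_sites()

    # -- geometry helpers -------------------------------------------------
    @property
    def spacing(self) -> np.ndarray:
        return np.full(3, float(self.spacing_mm))

    @property
    def center(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) / 2.0 * self.spacing

    @property
    def semi_axes(self) -> np.ndarray:
        """Brain ellipsoid semi-axes in mm (scale with the grid extent)."""
        extent = np.asarray(self.grid_shape) * self.spacing
        return extent * np.array([0.345, 0.406, 0.313])

    def grid(self) -> VolumeGrid:
        return VolumeGrid(np.zeros(self.grid_shape), self.spacing)

    def _validate_sites(self):
        semi = self.semi_axes
        for site in self.asym_sites:
            q = (np.asarray(site.center) - self.center) / semi
            if np.linalg.norm(q) > 0.9:
                raise ValueError(f"asym site at {site.center} lies outside "
                                 "the brain")
            left = site.center[0] < self.center[0]
            if left != (site.hemisphere == "L"):
                raise ValueError("asym site center not in its declared "
                                 "hemisphere")
        for timing in ("growth", "both"):
            bm = self._bumps(timing)
            if bm.sites:
                det = bm.det_jacobian(self._probe_points())
                if det.min() <= 0.05:
                    raise ValueError(
                        "bump magnitudes too large: analytic Jacobian "
                        f"approaches zero (min det {det.min():.3f})")

    def _probe_points(self) -> np.ndarray:
        g = self.grid()
        return g.world_coords().reshape(-1, 3)[::7]

    def _bumps(self, timepoint: str) -> "BumpMap":
        if timepoint == "growth":          # neonatal anatomy bumps
            sites = [s for s in self.asym_sites]
        else:                              # "both": bumps shared by fetal
            sites = [s for s in self.asym_sites if s.timing == "both"]
        return BumpMap(tuple(sites))

    def neonatal_bumps(self) -> "BumpMap":
        return self._bumps("growth")

    def fetal_bumps(self) -> "BumpMap":
        return self._bumps("both")


def default_asym_site(spec: PhantomSpec, hemisphere: str = "L",
                      peak_factor: float = 1.3,
                      timing: str = "growth") -> AsymSite:
    """A canonical planted site: anterior-temporal, one hemisphere.

    Centered on the cortical GM/WM transition of the chosen hemisphere,
    where image registration has matchable features (expansion of purely
    homogeneous tissue is invisible to intensity-driven registration — the
    aperture problem), with an extent comparable to the large asymmetry
    clusters reported in fetal/neonatal cohorts.
    """
    semi = spec.semi_axes
    sign = -1.0 if hemisphere == "L" else 1.0
    center = spec.center + semi * np.array([sign * 0.55, 0.35, -0.10])
    return AsymSite(tuple(center), radius_mm=float(semi[0] * 0.55),
                    peak_factor=peak_factor, hemisphere=hemisphere,
                    timing=timing)


class BumpMap:
    """Sum-of-radial-Gaussian-bumps diffeomorphism with analytic Jacobian."""

    def __init__(self, sites):
        self.sites = tuple(sites)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64)
        out = pts.copy()
        for s in self.sites:
            d = pts - np.asarray(s.center)
            r2 = (d ** 2).sum(axis=-1)
            sigma = s.radius_mm / 2.0
            m = (s.peak_factor - 1.0) * np.exp(-r2 / (2.0 * sigma ** 2))
            out = out + d * m[..., None]
        return out

    def inverse(self, pts: np.ndarray, n_iter: int = 40,
                tol: float = 1e-9) -> np.ndarray:
        """Fixed-point inversion of the bump map."""
        pts = np.asarray(pts, dtype=np.float64)
        if not self.sites:
            return pts.copy()
        x = pts.copy()
        for _ in range(n_iter):
            delta = pts - self(x)
            x = x + delta
            if np.abs(delta).max() < tol:
                break
        return x

    def jacobian(self, pts: np.ndarray) -> np.ndarray:
        """Analytic Jacobian matrices dB/dx at the given points."""
        pts = np.asarray(pts, dtype=np.float64)
        J = np.broadcast_to(np.eye(3), pts.shape[:-1] + (3, 3)).copy()
        for s in self.sites:
            d = pts - np.asarray(s.center)
            r2 = (d ** 2).sum(axis=-1)
            sigma = s.radius_mm / 2.0
            e = np.exp(-r2 / (2.0 * sigma ** 2))
            m = (s.peak_factor - 1.0) * e
            # d/dx [d * m(r)] = m I + d outer d * m'(r)/r ; m'/r = -m/sigma^2
            J += m[..., None, None] * np.eye(3)
            J += (-m / sigma ** 2)[..., None, None] * (
                d[..., :, None] * d[..., None, :])
        return J

    def det_jacobian(self, pts: np.ndarray) -> np.ndarray:
        return np.linalg.det(self.jacobian(pts))

    def log_det_jacobian(self, pts: np.ndarray) -> np.ndarray:
        return np.log(self.det_jacobian(pts))


# ---------------------------------------------------------------------------
# analytic anatomy
# ---------------------------------------------------------------------------

def _structure(qc, semi_q):
    qc = np.asarray(qc, dtype=np.float64)
    semi_q = np.asarray(semi_q, dtype=np.float64)
    def inside(q):
        return (((q - qc) / semi_q) ** 2).sum(axis=-1) <= 1.0
    return inside


_VENTRICLE_L = _structure((-0.27, 0.08, 0.10), (0.14, 0.31, 0.20))
_VENTRICLE_R = _structure((+0.27, 0.08, 0.10), (0.14, 0.31, 0.20))
_DGM_L = _structure((-0.36, -0.08, 0.0), (0.20, 0.23, 0.25))
_DGM_R = _structure((+0.36, -0.08, 0.0), (0.20, 0.23, 0.25))
_BRAINSTEM = _structure((0.0, -0.31, -0.70), (0.18, 0.19, 0.40))
_CEREBELLUM = _structure((0.0, -0.62, -0.60), (0.55, 0.27, 0.35))


def _labels_at_normalized(q: np.ndarray, undulation_amp: float,
                          phase: np.ndarray | None = None) -> np.ndarray:
    """Six-class tissue labels at normalized (unit-ellipsoid) coordinates.

    Every term is even in q[...,0], so the anatomy is exactly left-right
    mirror symmetric.
    """
    phase = np.zeros(2) if phase is None else np.asarray(phase)
    rho = np.sqrt((q ** 2).sum(axis=-1))
    # cortical folding proxy: sinusoidal boundary undulation, even in x
    W = (np.cos(4.0 * np.pi * q[..., 0])
         * np.cos(5.0 * np.pi * q[..., 1] + phase[0])
         * np.cos(3.0 * np.pi * q[..., 2] + phase[1]))
    rho_outer = rho * (1.0 + 0.3 * undulation_amp * W)
    rho_inner = rho * (1.0 + undulation_amp * W)

    labels = np.zeros(q.shape[:-1], dtype=np.int16)
    inside = rho_outer <= 1.0
    labels[inside] = 1                                   # CSF rim
    labels[inside & (rho_inner <= 0.93)] = 2             # cortical GM
    labels[inside & (rho_inner <= 0.78)] = 3             # WM core
    cer = inside & _CEREBELLUM(q)
    labels[cer] = 6
    bs = inside & _BRAINSTEM(q)
    labels[bs] = 5
    wm = labels == 3
    labels[wm & (_DGM_L(q) | _DGM_R(q))] = 4
    labels[(labels == 3) & (_VENTRICLE_L(q) | _VENTRICLE_R(q))] = 1
    return labels


@dataclass
class AnatomyModel:
    """Continuous anatomy of one subject/template in template space."""

    spec: PhantomSpec
    anatomy_scale: float = 1.0        # 1 = neonatal size, 1/s = fetal size
    undulation_amp: float = 0.035
    semi_scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    phase: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def labels_at(self, pts: np.ndarray) -> np.ndarray:
        semi = self.spec.semi_axes * self.anatomy_scale * self.semi_scale
        q = (np.asarray(pts) - self.spec.center) / semi
        return _labels_at_normalized(q, self.undulation_amp, self.phase)

    def landmarks(self) -> LandmarkSet:
        semi = self.spec.semi_axes * self.anatomy_scale * self.semi_scale
        names, pos = [], []
        for n, off in _LANDMARKS_MID.items():
            names.append(n)
            pos.append(self.spec.center + np.asarray(off) * semi)
        for n, off in _LANDMARKS_HEMI.items():
            off = np.asarray(off)
            for suffix, sign in (("_L", -1.0), ("_R", 1.0)):
                names.append(n + suffix)
                pos.append(self.spec.center
                           + off * np.array([sign, 1.0, 1.0]) * semi)
        return LandmarkSet(names, np.array(pos))


def _render(labels: np.ndarray, contrast: dict, spec: PhantomSpec,
            pv_sigma_vox: float = 0.45) -> np.ndarray:
    lut = np.zeros(max(contrast) + 1)
    for k, v in contrast.items():
        lut[k] = v
    img = lut[labels]
    if pv_sigma_vox > 0:
        img = ndimage.gaussian_filter(img, pv_sigma_vox)
    return img


def _symmetrize(img: np.ndarray) -> np.ndarray:
    """Exact mirror-symmetrization (bitwise flip fixed point)."""
    return 0.5 * (img + img[::-1])


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

@dataclass
class TemplateBundle:
    image: VolumeGrid
    labels: LabelVolume
    landmarks: LandmarkSet
    timepoint_tag: str


@dataclass
class Timepoint:
    image: VolumeGrid
    labels: LabelVolume
    landmarks: LandmarkSet
    age_GW: float


@dataclass
class GroundTruth:
    """Analytic fetal->neonatal transform of one phantom subject.

    The forward anatomy map is Phi = T_n^{-1} o B_neo o B_fet^{-1} o A
    with A the subject's fetal->template similarity (scale s) and B_* the
    bump diffeomorphisms in template space.
    """

    scale: float
    fetal_bumps: BumpMap
    neonatal_bumps: BumpMap
    fetal_translation: np.ndarray
    neonatal_translation: np.ndarray
    center: np.ndarray

    def forward_points(self, pts: np.ndarray) -> np.ndarray:
        """Map fetal-space mm points to neonatal-space mm points."""
        a = self.scale * (np.asarray(pts) - self.center) + self.center \
            - self.fetal_translation * self.scale
        a = self.fetal_bumps.inverse(a)
        return self.neonatal_bumps(a) + self.neonatal_translation

    def nonlinear_pullback_field(self, reference: VolumeGrid) -> DisplacementField:
        """Residual (post-affine) pull-back field on the neonatal grid.

        This is the field an ideal deformable registration recovers after
        the linear component has been factored out: u(y) = B_fet(
        B_neo^{-1}(y)) - y in anatomy-aligned neonatal space.
        """
        pts = reference.world_coords().reshape(-1, 3)
        a = self.neonatal_bumps.inverse(pts - self.neonatal_translation)
        u = self.fetal_bumps(a) - pts
        return DisplacementField(u.reshape(reference.shape + (3,)),
                                 reference.spacing.copy(),
                                 reference.origin.copy())

    def growth_log_jd(self, reference: VolumeGrid) -> np.ndarray:
        """Closed-form log-JD of the nonlinear growth on the neonatal grid.

        Positive where the neonatal anatomy expanded beyond the global
        affine; identically zero when no growth-timed bumps exist.
        """
        pts = reference.world_coords().reshape(-1, 3)
        a = self.neonatal_bumps.inverse(pts - self.neonatal_translation)
        val = (self.neonatal_bumps.log_det_jacobian(a)
               - self.fetal_bumps.log_det_jacobian(a))
        return val.reshape(reference.shape)


@dataclass
class SubjectPair:
    subject_id: str
    fetal: Timepoint
    neonatal: Timepoint
    sex: str
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

_TEMPLATE_SCALE = {"neonatal": 1.0, "mid_age": None, "fetal": None}


def build_template(spec: PhantomSpec, tag: str = "neonatal") -> TemplateBundle:
    """Exactly left-right symmetric template at the requested age scale."""
    if spec.asym_sites:
        raise ValueError("templates must be symmetric: spec.asym_sites must "
                         "be empty")
    if tag == "neonatal":
        scale, amp = 1.0, spec.undulation_amp_neonatal
        contrast = spec.neonatal_contrast
    elif tag == "mid_age":
        scale = 1.0 / np.sqrt(spec.global_scale)
        amp = 0.5 * (spec.undulation_amp_fetal + spec.undulation_amp_neonatal)
        contrast = {k: 0.5 * (spec.fetal_contrast[k] + spec.neonatal_contrast[k])
                    for k in spec.neonatal_contrast}
    elif tag == "fetal":
        scale, amp = 1.0 / spec.global_scale, spec.undulation_amp_fetal
        contrast = spec.fetal_contrast
    else:
        raise ValueError(f"unknown template tag {tag!r}")

    model = AnatomyModel(spec, anatomy_scale=scale, undulation_amp=amp)
    g = spec.grid()
    pts = g.world_coords()
    labels = model.labels_at(pts)
    img = _symmetrize(_render(labels, contrast, spec))
    return TemplateBundle(
        image=VolumeGrid(img, spec.spacing),
        labels=LabelVolume(labels, spec.spacing),
        landmarks=model.landmarks(),
        timepoint_tag=tag,
    )


def synthesize_subject(spec: PhantomSpec, subject_seed: int,
                       subject_id: str | None = None,
                       fetal_age: float | None = None,
                       neonatal_age: float | None = None,
                       sex: str | None = None) -> SubjectPair:
    """One longitudinal pair with analytic ground-truth growth.

    Deterministic in (spec, subject_seed).  The fetal image is the
    template anatomy shrunk by 1/s with reduced cortical undulation and
    fetal contrast; the neonatal image carries the growth bumps; noise is
    added after all geometry.
    """
    rng = np.random.default_rng(subject_seed)
    subject_id = subject_id or f"sub-{subject_seed:06d}"

    s = spec.global_scale * float(np.exp(rng.normal(0, spec.scale_jitter_sd)))
    s = float(np.clip(s, 1.0 + 1e-6, 1.6))
    semi_scale = np.exp(rng.normal(0, spec.shape_jitter_sd, 3))
    semi_scale[0] = 1.0  # keep the midline plane at the grid center plane
    phase = rng.normal(0, 0.5, 2)
    # in-plane (y,z) translations preserve the midsagittal alignment
    t_fet = np.array([0.0, *rng.normal(0, spec.translation_jitter_mm, 2)])
    t_neo = np.array([0.0, *rng.normal(0, spec.translation_jitter_mm, 2)])

    ages = _draw_ages(spec, rng)
    fetal_age = float(fetal_age if fetal_age is not None else ages[0])
    neonatal_age = float(neonatal_age if neonatal_age is not None else ages[1])
    if sex is None:
        sex = "F" if rng.random() < spec.female_fraction else "M"

    B_fet = spec.fetal_bumps()
    B_neo = spec.neonatal_bumps()
    g = spec.grid()
    pts = g.world_coords().reshape(-1, 3)
    c = spec.center

    fet_model = AnatomyModel(spec, anatomy_scale=1.0,
                             undulation_amp=spec.undulation_amp_fetal,
                             semi_scale=semi_scale, phase=phase)
    neo_model = AnatomyModel(spec, anatomy_scale=1.0,
                             undulation_amp=spec.undulation_amp_neonatal,
                             semi_scale=semi_scale, phase=phase)

    # fetal voxel x holds anatomy B_fet^{-1}(A(x)), A(x) = c + s(x-c) - s*t
    a_fet = s * (pts - c) + c - t_fet * s
    fet_labels = fet_model.labels_at(B_fet.inverse(a_fet)).reshape(g.shape)
    # neonatal voxel y holds anatomy B_neo^{-1}(y - t_neo)
    a_neo = B_neo.inverse(pts - t_neo)
    neo_labels = neo_model.labels_at(a_neo).reshape(g.shape)

    fet_img = _render(fet_labels, spec.fetal_contrast, spec)
    neo_img = _render(neo_labels, spec.neonatal_contrast, spec)
    if spec.noise_sd > 0:
        fet_img = fet_img + rng.normal(0, spec.noise_sd, fet_img.shape)
        neo_img = neo_img + rng.normal(0, spec.noise_sd, neo_img.shape)

    gt = GroundTruth(scale=s, fetal_bumps=B_fet, neonatal_bumps=B_neo,
                     fetal_translation=t_fet, neonatal_translation=t_neo,
                     center=c.copy())
    # sanity: the composed analytic transform must be orientation-preserving
    probe = spec._probe_points()
    if B_neo.sites and B_neo.det_jacobian(probe).min() <= 0:
        raise ValueError("ground-truth Jacobian non-positive; reduce bump "
                         "magnitudes")

    tmpl_landmarks = AnatomyModel(spec, 1.0, semi_scale=semi_scale).landmarks()
    lm_names = tmpl_landmarks.names
    lm_tpl = tmpl_landmarks.positions
    lm_neo = B_neo(lm_tpl) + t_neo
    lm_fet = (B_fet(lm_tpl) + t_fet * s - c) / s + c

    spacing = spec.spacing
    fetal = Timepoint(
        image=VolumeGrid(fet_img, spacing),
        labels=LabelVolume(fet_labels, spacing),
        landmarks=LandmarkSet(lm_names, lm_fet),
        age_GW=fetal_age)
    neonatal = Timepoint(
        image=VolumeGrid(neo_img, spacing),
        labels=LabelVolume(neo_labels, spacing),
        landmarks=LandmarkSet(lm_names, lm_neo),
        age_GW=neonatal_age)
    if neonatal.age_GW <= fetal.age_GW:
        raise ValueError("neonatal age must exceed fetal age")
    return SubjectPair(subject_id, fetal, neonatal, sex, gt)


def _draw_ages(spec: PhantomSpec, rng) -> tuple:
    for _ in range(100):
        fet = rng.normal(spec.fetal_age_mean, spec.fetal_age_sd)
        neo = rng.normal(spec.neonatal_age_mean, spec.neonatal_age_sd)
        if neo - fet >= 4.0:
            return float(fet), float(neo)
    return spec.fetal_age_mean, spec.neonatal_age_mean


def analytic_growth_jd(spec: PhantomSpec, pair: SubjectPair) -> JDMap:
    """Closed-form log-JD of the nonlinear growth on the neonatal grid.

    Identically zero when the spec plants no growth-timed asymmetry (the
    global affine is factored out by construction).
    """
    g = spec.grid()
    return JDMap(pair.ground_truth.growth_log_jd(g), spec.spacing,
                 g.origin.copy(), source=f"analytic:{pair.subject_id}")


def synthesize_cohort(n: int, spec: PhantomSpec,
                      seed: int | None = None) -> list:
    """Deterministic cohort of longitudinal pairs.

    Per-subject seeds derive from the cohort seed; the sex assignment hits
    the emulated study's 14/6 female/male ratio exactly at n = 20 (round
    (0.7 n) females in general), and ages are jittered around the fetal
    and neonatal scan means.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    seed = spec.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                     for s in root.spawn(n)]
    rng = np.random.default_rng(root.generate_state(1)[0] % (2 ** 31))
    n_female = int(round(spec.female_fraction * n))
    sexes = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sexes)
    cohort = []
    for i in range(n):
        cohort.append(synthesize_subject(
            spec, subject_seeds[i], subject_id=f"sub-{i + 1:03d}",
            sex=str(sexes[i])))
    return cohort


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort, spec: PhantomSpec, out_dir, seed=None) -> dict:
    """Write per-subject NIfTI + landmark CSV files and a JSON manifest."""
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "n": len(cohort), "spec": spec_to_dict(spec),
                "subjects": []}
    for pair in cohort:
        rec = {"id": pair.subject_id, "sex": pair.sex,
               "fetal_age_GW": pair.fetal.age_GW,
               "neonatal_age_GW": pair.neonatal.age_GW,
               "ground_truth": {
                   "scale": pair.ground_truth.scale,
                   "fetal_translation": pair.ground_truth.fetal_translation.tolist(),
                   "neonatal_translation": pair.ground_truth.neonatal_translation.tolist(),
               }}
        for tp_name in ("fetal", "neonatal"):
            tp = getattr(pair, tp_name)
            base = f"{pair.subject_id}_{tp_name}"
            tp.image.save(out_dir / f"{base}_T2.nii.gz")
            tp.labels.save(out_dir / f"{base}_labels.nii.gz")
            tp.landmarks.to_csv(out_dir / f"{base}_landmarks.csv")
            rec[tp_name] = {
                "image": f"{base}_T2.nii.gz",
                "labels": f"{base}_labels.nii.gz",
                "landmarks": f"{base}_landmarks.csv",
            }
        manifest["subjects"].append(rec)
    with open(out_dir / "cohort.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def spec_to_dict(spec: PhantomSpec) -> dict:
    d = {}
    for k, v in vars(spec).items():
        if k == "asym_sites":
            d[k] = [vars(s) | {"center": list(s.center)} for s in v]
        elif isinstance(v, np.ndarray):
            d[k] = v.tolist()
        elif isinstance(v, dict):
            d[k] = {int(kk): float(vv) for kk, vv in v.items()}
        elif isinstance(v, tuple):
            d[k] = list(v)
        else:
            d[k] = v
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    for key in ("fetal_contrast", "neonatal_contrast"):
        if key in d:
            d[key] = {int(k): float(v) for k, v in d[key].items()}
    if "asym_sites" in d:
        d["asym_sites"] = tuple(
            AsymSite(center=tuple(s["center"]), radius_mm=s["radius_mm"],
                     peak_factor=s["peak_factor"], hemisphere=s["hemisphere"],
                     timing=s.get("timing", "growth"))
            for s in d["asym_sites"])
    return PhantomSpec(**d)
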