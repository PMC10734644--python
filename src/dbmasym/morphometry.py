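"""Jacobian-determinant morphometry: log-JD maps, mask-restricted smoothing,
and propagation to template space.

The log scale is used throughout: log-JD > 0 marks local expansion of the
fixed-space volume element under the pull-back map x -> x + u(x)
(det(I + du/dx) > 1), log-JD < 0 marks contraction, and an identity field
gives exactly zero.  Values are transported to template space by
interpolation only — never multiplied by the template-warp Jacobian — so
the statistic stays the subject-level quantity evaluated at homologous
template locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import AffineTransform, GeometryError, VolumeGrid, resample
from .registration import DisplacementField

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class JDMap:
    """Log-Jacobian-determinant scalar field on a grid geometry."""

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    source: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log-JD map contains non-finite values")

    @property
    def shape(self):
        return self.values.shape

    def grid(self) -> VolumeGrid:
        return VolumeGrid(self.values, self.spacing, self.origin)

    def negated(self) -> "JDMap":
        return JDMap(-self.values, self.spacing.copy(), self.origin.copy(),
                     self.source)

    def save(self, path, raw_jd: bool = False) -> None:
        data = np.exp(self.values) if raw_jd else self.values
        VolumeGrid(data, self.spacing, self.origin).save(path)

    @classmethod
    def load(cls, path, source: str = "") -> "JDMap":
        g = VolumeGrid.load(path)
        return cls(g.data, g.spacing, g.origin, source)


def _displacement_gradient(fld: DisplacementField) -> np.ndarray:
    """du_i/dx_j in physical mm, central differences (one-sided at edges)."""
    grads = np.empty(fld.shape + (3, 3))
    for i in range(3):
        for j in range(3):
            grads[..., i, j] = np.gradient(fld.vectors[..., i],
                                           fld.spacing[j], axis=j)
    return grads


def jacobian_determinant(fld: DisplacementField) -> np.ndarray:
    """det(I + du/dx) at every voxel."""
    J = _displacement_gradient(fld)
    J[..., 0, 0] += 1.0
    J[..., 1, 1] += 1.0
    J[..., 2, 2] += 1.0
    return np.linalg.det(J)


def jacobian_log_map(fld: DisplacementField, source: str = "") -> JDMap:
    """Log-Jacobian of the pull-back map x -> x + u(x).

    A pure scaling field u(x) = (s-1)x yields 3*ln(s) at every interior
    voxel.  Raises if the determinant is non-positive anywhere.
    """
    det = jacobian_determinant(fld)
    n_bad = int((det <= 0).sum())
    if n_bad:
        raise ValueError(f"non-positive Jacobian determinant at {n_bad} voxels")
    return JDMap(np.log(det), fld.spacing.copy(), fld.origin.copy(), source)


def smooth_in_mask(jd: JDMap, mask: np.ndarray, fwhm_mm: float) -> JDMap:
    """Gaussian smoothing with the kernel renormalized over in-mask support.

    Out-of-mask values never leak into the mask and out-of-mask voxels are
    returned untouched.  ``fwhm_mm = 0`` is the identity.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != jd.shape:
        raise GeometryError("mask geometry mismatch")
    if not mask.any():
        raise ValueError("empty mask")
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return JDMap(jd.values.copy(), jd.spacing.copy(), jd.origin.copy(),
                     jd.source)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / jd.spacing
    m = mask.astype(np.float64)
    num = ndimage.gaussian_filter(jd.values * m, sigma_vox)
    den = ndimage.gaussian_filter(m, sigma_vox)
    out = jd.values.copy()
    valid = mask & (den > 1e-12)
    out[valid] = num[valid] / den[valid]
    return JDMap(out, jd.spacing.copy(), jd.origin.copy(), jd.source)


def propagate_to_template(jd: JDMap, linear: AffineTransform | None,
                          deformable: DisplacementField | None,
                          reference: VolumeGrid) -> JDMap:
    """Re-grid a subject-space log-JD map onto the template geometry.

    ``linear`` and ``deformable`` map reference (template) mm points into
    subject space; the full composition x -> A(x + u(x)) is applied and
    values are transported by linear interpolation only.
    """
    vol = jd.grid()
    if deformable is None:
        transform = linear
    else:
        if not deformable.grid().same_geometry(reference):
            raise GeometryError("deformable field must live on the reference grid")
        transform = (deformable if linear is None
                     else deformable.compose_affine(linear))
    out = resample(vol, reference, transform, interpolation="linear", fill=0.0)
    return JDMap(out.data, reference.spacing.copy(), reference.origin.copy(),
                 jd.source)


def stack_maps(maps) -> np.ndarray:
    """Stack per-subject JD maps into an (n, nx, ny, nz) group array."""
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise GeometryError("maps must share one geometry")
    return np.stack([m.values for m in maps], axis=0)


def save_stack(maps, path) -> None:
    """Write a group of JD maps as one 4D NIfTI (subject axis last)."""
    import nibabel as nib
    stack = stack_maps(maps)
    ref = maps[0]
    affine = ref.grid().affine
    img = nib.Nifti1Image(np.moveaxis(stack, 0, -1).astype(np.float32),
                          affine)
    img.header.set_qform(affine, code=1)
    img.header.set_sform(affine, code=1)
    nib.save(img, str(path))


def load_stack(path):
    """Read a 4D NIfTI group stack back into a list of JD maps."""
    import nibabel as nib
    img = nib.load(str(path))
    A = img.affine
    spacing = np.sqrt((A[:3, :3] ** 2).sum(axis=0))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    return [JDMap(data[..., i], spacing, A[:3, 3])
            for i in range(data.shape[-1])]
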