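"""Geometry-aware image containers and the operations shared by every stage.

The canonical space is RAS (x: left->right, y: posterior->anterior,
z: inferior->superior) with the left-right axis stored as array axis 0.
Voxel indices are 0-based; physical coordinates are millimetres.  Image
transforms follow the pull-back (fixed -> moving) convention used by every
resampling engine; point maps use the inverse, so that anatomy and
landmarks move together.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

#: fixed six-class tissue legend used throughout the pipeline
TISSUE_LEGEND = {
    0: "background",
    1: "CSF",
    2: "GM",
    3: "WM",
    4: "dGM",
    5: "BS",
    6: "Cer",
}


class GeometryError(ValueError):
    """Raised when image geometries are incompatible or non-canonical."""


@dataclass
class VolumeGrid:
    """A 3D scalar image with axis-aligned RAS geometry.

    Parameters
    ----------
    data:
        3D float array, axis order (x, y, z) in RAS.
    spacing:
        mm per voxel along each axis, strictly positive.
    origin:
        mm position of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.data.ndim != 3:
            raise GeometryError(f"expected 3D data, got {self.data.ndim}D")
        if not np.all(self.spacing > 0):
            raise GeometryError("spacing must be strictly positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] = np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    @property
    def center(self) -> np.ndarray:
        """Physical mm coordinate of the grid center (midplane intersection)."""
        return self.origin + (np.asarray(self.shape) - 1) / 2.0 * self.spacing

    def world_coords(self) -> np.ndarray:
        """Dense (nx, ny, nz, 3) array of voxel-center mm positions."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n, dtype=np.float64) for n in self.shape],
                        indexing="ij"), axis=-1)
        return idx * self.spacing + self.origin

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=np.float64) - self.origin) / self.spacing

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return np.asarray(ijk, dtype=np.float64) * self.spacing + self.origin

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=atol)
                and np.allclose(self.origin, other.origin, atol=atol))

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """New grid with the same geometry and different data."""
        return VolumeGrid(np.asarray(data, dtype=np.float64),
                          self.spacing.copy(), self.origin.copy())

    # -- I/O --------------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_qform(self.affine, code=1)
        img.header.set_sform(self.affine, code=1)
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "VolumeGrid":
        return cls.from_nifti(nib.load(str(path)))

    @classmethod
    def from_nifti(cls, img) -> "VolumeGrid":
        img = nib.as_closest_canonical(img)
        A = img.affine
        R = A[:3, :3]
        spacing = np.sqrt((R ** 2).sum(axis=0))
        if not np.allclose(R, np.diag(spacing), atol=1e-3):
            raise GeometryError(
                "oblique orientation: reorientation to axis-aligned RAS required")
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        if data.ndim != 3:
            raise GeometryError("only 3D volumes are supported")
        return cls(data, spacing, A[:3, 3])


@dataclass
class LabelVolume:
    """Integer tissue labels on a :class:`VolumeGrid` geometry."""

    labels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    legend: dict = field(default_factory=lambda: dict(TISSUE_LEGEND))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        extra = set(np.unique(self.labels)) - set(self.legend)
        if extra:
            raise ValueError(f"labels outside legend: {sorted(extra)}")

    @property
    def shape(self):
        return self.labels.shape

    def grid(self) -> VolumeGrid:
        """Geometry carrier (float view of the labels)."""
        return VolumeGrid(self.labels.astype(np.float64), self.spacing, self.origin)

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def save(self, path) -> None:
        g = VolumeGrid(np.zeros(self.shape), self.spacing, self.origin)
        img = nib.Nifti1Image(self.labels.astype(np.int16), g.affine)
        img.header.set_qform(g.affine, code=1)
        img.header.set_sform(g.affine, code=1)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "LabelVolume":
        img = nib.as_closest_canonical(nib.load(str(path)))
        A = img.affine
        R = A[:3, :3]
        spacing = np.sqrt((R ** 2).sum(axis=0))
        if not np.allclose(R, np.diag(spacing), atol=1e-3):
            raise GeometryError("oblique orientation not supported for labels")
        data = np.asanyarray(img.dataobj)
        return cls(np.rint(data).astype(np.int16), spacing, A[:3, 3])


class LandmarkSet:
    """Ordered, named landmark positions in physical RAS mm.

    Hemispheric landmarks carry an ``_L``/``_R`` suffix; midline landmarks
    carry none.  Optional per-point ``flags`` mark points that fell outside
    a transform's support during mapping.
    """

    def __init__(self, names, positions, flags=None):
        self.names = list(names)
        self.positions = np.asarray(positions, dtype=np.float64).reshape(len(self.names), 3)
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("landmark positions must be finite")
        self.flags = dict(flags) if flags else {}

    def __len__(self):
        return len(self.names)

    def __getitem__(self, name) -> np.ndarray:
        return self.positions[self.names.index(name)]

    def items(self):
        return zip(self.names, self.positions)

    # -- I/O --------------------------------------------------------------
    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.positions, columns=["x", "y", "z"])
        df.insert(0, "name", self.names)
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        df = pd.read_csv(path)
        return cls(df["name"].tolist(), df[["x", "y", "z"]].to_numpy())

    @classmethod
    def from_slicer_json(cls, path) -> "LandmarkSet":
        """Read a 3D Slicer markup file; Slicer stores LPS coordinates."""
        with open(path) as fh:
            doc = json.load(fh)
        names, pos = [], []
        for markup in doc.get("markups", []):
            for cp in markup.get("controlPoints", []):
                names.append(cp["label"])
                p = np.asarray(cp["position"], dtype=np.float64)
                sys = markup.get("coordinateSystem", "LPS")
                if sys.upper() == "LPS":
                    p = p * np.array([-1.0, -1.0, 1.0])
                pos.append(p)
        return cls(names, np.array(pos).reshape(-1, 3))


@dataclass
class AffineTransform:
    """4x4 homogeneous matrix mapping fixed-space mm points to moving-space mm.

    ``model`` records the constraint class (rigid6 / similarity7 / affine12).
    """

    matrix: np.ndarray
    model: str = "affine12"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(4, 4)
        if not np.allclose(self.matrix[3], [0, 0, 0, 1]):
            raise ValueError("bottom row must be (0,0,0,1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("singular linear block")
        if self.model not in ("rigid6", "similarity7", "affine12"):
            raise ValueError(f"unknown model {self.model!r}")

    @classmethod
    def identity(cls, model="rigid6") -> "AffineTransform":
        return cls(np.eye(4), model)

    @classmethod
    def translation(cls, t, model="rigid6") -> "AffineTransform":
        A = np.eye(4)
        A[:3, 3] = np.asarray(t, dtype=np.float64)
        return cls(A, model)

    @classmethod
    def scaling_about(cls, scale: float, center) -> "AffineTransform":
        """Isotropic scaling about a fixed physical point."""
        c = np.asarray(center, dtype=np.float64)
        A = np.eye(4)
        A[:3, :3] = np.eye(3) * scale
        A[:3, 3] = c - scale * c
        return cls(A, "similarity7")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.model)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self o other: apply ``other`` first."""
        return AffineTransform(self.matrix @ other.matrix, "affine12")

    @property
    def scale(self) -> float:
        """Geometric-mean isotropic scale of the linear block."""
        return float(np.abs(np.linalg.det(self.matrix[:3, :3])) ** (1.0 / 3.0))

    def save(self, path) -> None:
        np.savetxt(path, self.matrix, fmt="%.12g", header=self.model, comments="# ")

    @classmethod
    def load(cls, path) -> "AffineTransform":
        with open(path) as fh:
            first = fh.readline().strip()
        model = first.lstrip("# ").strip() or "affine12"
        return cls(np.loadtxt(path), model)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def flip_lr(volume):
    """Mirror an image (or labels) about its midsagittal grid-center plane.

    The input must live in the canonical midline-aligned space: the plane
    halfway along the left-right axis is the midsagittal plane.  Flipping
    is a pure axis-0 reversal, so the intensity multiset is preserved
    exactly and the operation is an involution.
    """
    if isinstance(volume, LabelVolume):
        return LabelVolume(volume.labels[::-1].copy(), volume.spacing.copy(),
                           volume.origin.copy(), dict(volume.legend))
    if isinstance(volume, VolumeGrid):
        return VolumeGrid(volume.data[::-1].copy(), volume.spacing.copy(),
                          volume.origin.copy())
    raise TypeError(f"cannot flip {type(volume).__name__}")


def flip_point(pts: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    """Point map induced by :func:`flip_lr`: x -> 2*x_mid − x."""
    pts = np.asarray(pts, dtype=np.float64)
    out = pts.copy()
    out[..., 0] = 2.0 * grid.center[0] - pts[..., 0]
    return out


def flip_landmarks(lm: LandmarkSet, grid: VolumeGrid) -> LandmarkSet:
    """Mirror landmarks; swaps the _L/_R name suffixes so that homotopic
    points keep their anatomical identity."""
    names = []
    for n in lm.names:
        if n.endswith("_L"):
            names.append(n[:-2] + "_R")
        elif n.endswith("_R"):
            names.append(n[:-2] + "_L")
        else:
            names.append(n)
    return LandmarkSet(names, flip_point(lm.positions, grid))


def _transform_points(transform, pts):
    """Pull-back point evaluation: fixed-space mm -> moving-space mm."""
    if isinstance(transform, AffineTransform):
        return transform.apply(pts)
    # duck-typed displacement field (registration.DisplacementField)
    return transform.pull_points(pts)


def resample(volume, reference, transform=None, interpolation="linear",
             fill=0.0):
    """Resample ``volume`` onto ``reference`` geometry through ``transform``.

    ``transform`` maps reference-space mm points into ``volume``-space mm
    (pull-back convention); ``None`` means identity.  Out-of-field voxels
    receive ``fill``.  Labels must use nearest interpolation.
    """
    is_labels = isinstance(volume, LabelVolume)
    if is_labels and interpolation != "nearest":
        raise ValueError("label volumes require nearest interpolation")
    src = volume.grid() if is_labels else volume
    ref = reference.grid() if isinstance(reference, LabelVolume) else reference

    if transform is None and src.same_geometry(ref):
        out = src.data.copy()
    else:
        pts = ref.world_coords().reshape(-1, 3)
        if transform is not None:
            if not isinstance(transform, AffineTransform):
                fg = transform.grid()
                if not fg.same_geometry(ref):
                    raise GeometryError(
                        "displacement field geometry must match the reference")
            pts = _transform_points(transform, pts)
        vox = src.world_to_voxel(pts).T
        # snap float-rounding overshoot at the lattice boundary (constant
        # mode would otherwise drop a whole boundary plane to fill)
        hi = (np.asarray(src.shape, dtype=np.float64) - 1)[:, None]
        eps = 1e-6
        vox = np.where((vox > hi) & (vox < hi + eps), hi, vox)
        vox = np.where((vox < 0.0) & (vox > -eps), 0.0, vox)
        order = 0 if interpolation == "nearest" else 1
        out = ndimage.map_coordinates(
            src.data, vox, order=order, mode="constant", cval=fill
        ).reshape(ref.shape)

    if is_labels:
        return LabelVolume(np.rint(out).astype(np.int16), ref.spacing.copy(),
                           ref.origin.copy(), dict(volume.legend))
    return VolumeGrid(out, ref.spacing.copy(), ref.origin.copy())


def map_points(points: LandmarkSet, transform) -> LandmarkSet:
    """Move landmarks with the anatomy.

    The map applied to points is the *inverse* of the pull-back used for
    images, so an image and its landmarks warped with the same transform
    stay in correspondence.  Points outside a displacement field's support
    are flagged (``flags[name] = True``), never raised.
    """
    if isinstance(transform, AffineTransform):
        inv = transform.inverse()
        return LandmarkSet(points.names, inv.apply(points.positions))
    mapped, oob = transform.push_points(points.positions)
    return LandmarkSet(points.names, mapped,
                       {n: bool(b) for n, b in zip(points.names, oob) if b})
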