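"""Volume containers, NIfTI I/O, SUV normalization and grid resampling.

Coordinate convention (used everywhere in this package)
-------------------------------------------------------
Voxel indices are 0-based.  World coordinates are positions of *voxel
centers*, in millimetres, on a right-handed axis-aligned grid:

    world = origin + index * spacing        (per axis)

``origin`` is the world position of the center of voxel ``(0, 0, 0)``.
The physical *extent* of an image additionally includes the half-voxel
border around the outermost centers, i.e. it spans
``origin - spacing/2`` to ``origin + (shape - 1/2) * spacing``.

On disk, volumes are NIfTI-1 with a diagonal affine built from
``spacing`` and ``origin``; intensities are stored as float32 and binary
masks as uint8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeImage",
    "SUVMap",
    "AffineTransform",
    "read_volume",
    "write_volume",
    "compute_suv",
    "interpolate_halve",
    "resample_to",
]


@dataclass(frozen=True)
class VolumeImage:
    """A 3D scalar grid with physical voxel spacing and origin.

    Parameters
    ----------
    values
        3D array of voxel values (arbitrary units). Must be finite.
    spacing
        Voxel size in mm per axis, all components > 0.
    origin
        World position (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3 or min(values.shape) < 1:
            raise ValueError(f"expected a 3D volume, got shape {values.shape}")
        n_bad = int(np.size(values) - np.isfinite(values).sum())
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")
        spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if np.any(spacing <= 0):
            raise ValueError(f"spacing must be positive, got {spacing}")
        origin = self.origin
        origin = (
            np.zeros(3) if origin is None else np.asarray(origin, np.float64).reshape(3)
        )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VolumeImage", atol: float = 1e-6) -> bool:
        """True when both images live on the identical voxel grid."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates (mm) to continuous voxel indices."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return (points - self.origin) / self.spacing

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        index = np.atleast_2d(np.asarray(index, dtype=np.float64))
        return self.origin + index * self.spacing

    def index_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Open index grids for the three axes (for vectorized geometry)."""
        return np.ogrid[0 : self.shape[0], 0 : self.shape[1], 0 : self.shape[2]]


@dataclass(frozen=True)
class SUVMap:
    """A volume in standardized-uptake-value units (g/mL convention).

    SUV is tissue activity concentration divided by injected activity per
    gram of body weight; it is dimensionless and non-negative.  The decay
    correction of the injected activity to scan time happens *before*
    construction — ``injected_activity`` is already decay-corrected.
    """

    image: VolumeImage
    injected_activity_mbq: float
    body_weight_kg: float

    def __post_init__(self):
        if self.injected_activity_mbq <= 0:
            raise ValueError("injected activity must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")
        if np.any(self.image.values < 0):
            raise ValueError("SUV values must be non-negative")

    @property
    def values(self) -> np.ndarray:
        return self.image.values


@dataclass(frozen=True)
class AffineTransform:
    """Rigid/affine map from a moving image's world frame into a reference frame.

    ``x_ref = linear @ x_moving + translation`` (mm on both sides).
    """

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        linear = np.asarray(self.linear, dtype=np.float64).reshape(3, 3)
        translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if abs(np.linalg.det(linear)) < 1e-12:
            raise ValueError("singular linear part in affine transform")
        object.__setattr__(self, "linear", linear)
        object.__setattr__(self, "translation", translation)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(inv, -inv @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return points @ self.linear.T + self.translation


def _nifti_affine(image: VolumeImage) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(image.spacing)
    affine[:3, 3] = image.origin
    return affine


def read_volume(path: str | Path) -> VolumeImage:
    """Read a 3D NIfTI-1 volume.

    Spacing is taken from the voxel sizes and the origin from the affine
    translation; rejects non-3D images and images with non-finite voxels
    (the error names the offending voxel count).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim} dimensions")
    affine = img.affine
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    origin = affine[:3, 3]
    return VolumeImage(values=data, spacing=spacing, origin=origin)


def write_volume(image: VolumeImage, path: str | Path, *, mask: bool = False) -> None:
    """Write a volume as NIfTI-1 (float32; uint8 when ``mask=True``)."""
    dtype = np.uint8 if mask else np.float32
    nifti = nib.Nifti1Image(image.values.astype(dtype), _nifti_affine(image))
    nib.save(nifti, str(path))


def compute_suv(
    activity: VolumeImage, injected_activity_mbq: float, body_weight_kg: float
) -> SUVMap:
    """Build an SUV map from an activity-concentration volume.

    ``activity`` is in kBq/mL; ``injected_activity_mbq`` is the injected
    activity decay-corrected to scan time.  With body density taken as
    1 g/mL,

        SUV(v) = activity(v) [kBq/mL] / (dose [kBq] / weight [g])

    so a concentration numerically equal to the injected dose per gram of
    body gives SUV = 1.
    """
    if injected_activity_mbq <= 0:
        raise ValueError("injected activity must be positive")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    if np.any(activity.values < 0):
        raise ValueError("activity concentrations must be non-negative")
    dose_kbq = injected_activity_mbq * 1000.0
    weight_g = body_weight_kg * 1000.0
    suv_values = activity.values / (dose_kbq / weight_g)
    suv_image = VolumeImage(suv_values, activity.spacing, activity.origin)
    return SUVMap(suv_image, injected_activity_mbq, body_weight_kg)


def interpolate_halve(image: VolumeImage) -> VolumeImage:
    """Resample onto a grid with half the voxel size on every axis.

    Output has exactly twice the input dimensions; the fine voxel centers
    are placed cell-centered so the physical extent of the image is
    preserved: fine center ``j`` sits at input index ``j/2 - 1/4``.
    Trilinear interpolation with edge clamping, so constants stay
    constant and no value falls outside the input's [min, max].
    """
    out_shape = tuple(2 * n for n in image.shape)
    coords = np.meshgrid(
        *[np.arange(n) / 2.0 - 0.25 for n in out_shape], indexing="ij"
    )
    fine = ndimage.map_coordinates(
        image.values, coords, order=1, mode="nearest", prefilter=False
    )
    new_spacing = image.spacing / 2.0
    # first fine center: world(origin) shifted back a quarter of the old voxel
    new_origin = image.origin - image.spacing / 4.0
    return VolumeImage(fine, new_spacing, new_origin)


def resample_to(
    moving: VolumeImage,
    reference: VolumeImage,
    transform: AffineTransform | None = None,
    mode: str = "intensity",
) -> VolumeImage:
    """Resample ``moving`` onto the grid of ``reference``.

    ``transform`` maps moving world coordinates into the reference world
    frame (identity when omitted).  ``mode='intensity'`` uses trilinear
    interpolation; ``mode='mask'`` uses nearest-neighbor and returns a
    strictly {0,1} volume.  Voxels falling outside the moving image get 0.
    """
    if mode not in ("intensity", "mask"):
        raise ValueError(f"mode must be 'intensity' or 'mask', got {mode!r}")
    transform = transform or AffineTransform.identity()
    inv = transform.inverse()

    idx = np.indices(reference.shape, dtype=np.float64).reshape(3, -1).T
    world_ref = reference.index_to_world(idx)
    world_mov = inv.apply(world_ref)
    index_mov = moving.world_to_index(world_mov).T.reshape((3,) + reference.shape)

    order = 1 if mode == "intensity" else 0
    out = ndimage.map_coordinates(
        moving.values, index_mov, order=order, mode="constant", cval=0.0,
        prefilter=False,
    )
    if mode == "mask":
        out = (out > 0.5).astype(np.float64)
    return VolumeImage(out, reference.spacing, reference.origin)
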