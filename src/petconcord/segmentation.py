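"""Region-of-interest definition for paired PET/MRI tumor volumes.

Three ROIs are produced per lesion:

* **reference ROI** — three spheres mirrored onto the contralateral
  normal hemisphere, pooled into one mask from which the normal-brain
  maximum (Nmax) and mean (Nmean) SUV are measured;
* **MRI ROI** — the contrast-enhancing volume on post-contrast
  T1-weighted MRI, obtained by a robust intensity threshold (normal-region
  mean + k·sd), seeded connected component and hole filling;
* **PET ROI** — the metabolic tumor volume: voxels with
  SUV > multiple × Nmax (default multiple 3.0, strict inequality),
  cleaned for spatial continuity (seed component, cavity fill) with
  physiological hot structures (venous sinus, choroid plexus) removed
  through caller-supplied exclusion masks.

Connectivity convention: 26-connected foreground components with
6-connected background for cavity filling — the standard complementary
pair that avoids topological paradoxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import SUVMap, VolumeImage

__all__ = [
    "BinaryMask",
    "ReferenceStats",
    "SegmentationConfig",
    "MidlinePlane",
    "place_reference_rois",
    "segment_mri",
    "segment_fby",
    "clean_mask",
]

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} voxel mask aligned to a reference image grid."""

    values: np.ndarray
    reference: VolumeImage

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.shape != self.reference.shape:
            raise ValueError(
                f"mask shape {values.shape} != grid shape {self.reference.shape}"
            )
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, got {uniq[:10]}")
        object.__setattr__(self, "values", values.astype(bool))

    @property
    def count(self) -> int:
        return int(self.values.sum())

    @property
    def empty(self) -> bool:
        return not self.values.any()

    def same_grid(self, other: "BinaryMask") -> bool:
        return self.reference.same_grid(other.reference)

    def to_volume(self) -> VolumeImage:
        return VolumeImage(
            self.values.astype(np.float64),
            self.reference.spacing,
            self.reference.origin,
        )


@dataclass(frozen=True)
class ReferenceStats:
    """Normal-brain SUV statistics from the contralateral reference spheres."""

    n_max: float
    n_mean: float
    sphere_centers: np.ndarray  # (3, 3) world mm
    sphere_radius_mm: float

    def __post_init__(self):
        if not (0 <= self.n_mean <= self.n_max):
            raise ValueError("requires 0 <= n_mean <= n_max")
        centers = np.asarray(self.sphere_centers, dtype=np.float64).reshape(3, 3)
        object.__setattr__(self, "sphere_centers", centers)


@dataclass(frozen=True)
class SegmentationConfig:
    """Free parameters of the segmentation stage.

    fby_threshold_multiple
        PET threshold as a multiple of Nmax (voxels with
        SUV > multiple × Nmax are candidates). Default 3.0.
    mri_k
        Robust threshold multiplier for the MRI ROI
        (threshold = normal mean + k·sd). Default 3.0.
    connectivity
        Foreground connectivity for component analysis (6, 18 or 26).
    sphere_radius_mm
        Radius of each contralateral reference sphere.
    """

    fby_threshold_multiple: float = 3.0
    mri_k: float = 3.0
    connectivity: int = 26
    sphere_radius_mm: float = 5.0

    def __post_init__(self):
        if self.fby_threshold_multiple <= 0:
            raise ValueError("fby_threshold_multiple must be positive")
        if self.sphere_radius_mm <= 0:
            raise ValueError("sphere_radius_mm must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass(frozen=True)
class MidlinePlane:
    """The interhemispheric plane: points x with (x - point)·normal = 0."""

    normal: np.ndarray
    point: np.ndarray

    def __post_init__(self):
        normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(normal)
        if norm == 0:
            raise ValueError("midline normal must be nonzero")
        object.__setattr__(self, "normal", normal / norm)
        object.__setattr__(
            self, "point", np.asarray(self.point, dtype=np.float64).reshape(3)
        )

    def signed_distance(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        return (x - self.point) @ self.normal

    def mirror(self, x: np.ndarray) -> np.ndarray:
        """Reflect world point(s) across the plane."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        d = self.signed_distance(x)
        return np.squeeze(x - 2.0 * d[:, None] * self.normal)


def _sphere_mask(grid: VolumeImage, center_mm: np.ndarray, radius_mm: float) -> np.ndarray:
    ii, jj, kk = grid.index_grids()
    cx, cy, cz = (np.asarray(center_mm) - grid.origin) / grid.spacing
    sx, sy, sz = grid.spacing
    d2 = ((ii - cx) * sx) ** 2 + ((jj - cy) * sy) ** 2 + ((kk - cz) * sz) ** 2
    return d2 <= radius_mm**2


def _seed_index(grid: VolumeImage, seed_mm) -> tuple[int, int, int]:
    idx = np.rint(grid.world_to_index(seed_mm)).astype(int).reshape(3)
    if np.any(idx < 0) or np.any(idx >= np.array(grid.shape)):
        raise ValueError(f"seed {seed_mm} maps outside the image grid")
    return tuple(idx)


def _seed_component(candidate: np.ndarray, seed_idx, connectivity: int) -> np.ndarray:
    labels, _ = ndimage.label(candidate, structure=_STRUCTS[connectivity])
    lab = labels[seed_idx]
    if lab == 0:
        raise ValueError("seed voxel is not in the candidate set")
    return labels == lab


def _fill_cavities(mask: np.ndarray) -> np.ndarray:
    # 6-connected background flood fill from the border; enclosed cavities join.
    return ndimage.binary_fill_holes(mask, structure=_STRUCTS[6])


def place_reference_rois(
    suv: SUVMap,
    tumor_center: np.ndarray,
    midline: MidlinePlane,
    config: SegmentationConfig = SegmentationConfig(),
    *,
    axial_axis: int = 2,
) -> tuple[BinaryMask, ReferenceStats]:
    """Place three contralateral reference spheres and measure Nmax/Nmean.

    The primary sphere sits at the mirror image of ``tumor_center``
    across the midline plane; the other two are offset by ±2 radii along
    the superior–inferior axis so the three never overlap.  Nmax and
    Nmean are pooled over the union of the three spheres.

    Raises if the tumor center lies on the midline or any sphere leaves
    the image or crosses back to the tumor side.
    """
    grid = suv.image
    tumor_center = np.asarray(tumor_center, dtype=np.float64).reshape(3)
    d_tumor = float(midline.signed_distance(tumor_center)[0])
    if abs(d_tumor) < 1e-9:
        raise ValueError("tumor center lies on the midline plane")

    mirrored = np.asarray(midline.mirror(tumor_center), dtype=np.float64).reshape(3)
    r = config.sphere_radius_mm
    offset = np.zeros(3)
    offset[axial_axis] = 2.0 * r
    centers = np.array([mirrored, mirrored - offset, mirrored + offset])

    union = np.zeros(grid.shape, dtype=bool)
    lo = grid.origin - grid.spacing / 2.0
    hi = grid.origin + (np.array(grid.shape) - 0.5) * grid.spacing
    for c in centers:
        if np.any(c - r < lo) or np.any(c + r > hi):
            raise ValueError(f"reference sphere at {c} falls outside the image")
        if np.sign(midline.signed_distance(c)[0]) == np.sign(d_tumor):
            raise ValueError("reference sphere lies on the tumor side of the midline")
        union |= _sphere_mask(grid, c, r)

    vals = suv.values[union]
    stats = ReferenceStats(
        n_max=float(vals.max()),
        n_mean=float(vals.mean()),
        sphere_centers=centers,
        sphere_radius_mm=r,
    )
    return BinaryMask(union, grid), stats


def segment_mri(
    t1c: VolumeImage,
    seed: np.ndarray,
    normal_mask: BinaryMask,
    config: SegmentationConfig = SegmentationConfig(),
) -> BinaryMask:
    """Segment the contrast-enhancing volume on post-contrast T1 MRI.

    Threshold = mean + ``mri_k``·sd of intensities inside ``normal_mask``;
    the mask is the above-threshold connected component containing
    ``seed``, with interior holes filled.
    """
    if normal_mask.empty:
        raise ValueError("normal_mask is empty; cannot estimate a threshold")
    normal_vals = t1c.values[normal_mask.values]
    threshold = float(normal_vals.mean() + config.mri_k * normal_vals.std(ddof=1))
    candidate = t1c.values > threshold
    seed_idx = _seed_index(t1c, seed)
    if not candidate[seed_idx]:
        raise ValueError(
            f"seed voxel intensity {t1c.values[seed_idx]:.4g} is below the "
            f"enhancement threshold {threshold:.4g}"
        )
    comp = _seed_component(candidate, seed_idx, config.connectivity)
    return BinaryMask(_fill_cavities(comp), t1c)


def segment_fby(
    suv: SUVMap,
    ref: ReferenceStats,
    seed: np.ndarray,
    exclusions: list[BinaryMask] | None = None,
    config: SegmentationConfig = SegmentationConfig(),
) -> BinaryMask:
    """Segment the metabolic tumor volume: SUV > multiple × Nmax.

    Candidate voxels (strict inequality) are reduced by the exclusion
    masks (physiological uptake such as venous sinus or choroid plexus),
    then restricted to the connected component containing ``seed`` and
    cavity-filled.
    """
    if ref.n_max <= 0:
        raise ValueError("reference n_max must be positive")
    grid = suv.image
    threshold = config.fby_threshold_multiple * ref.n_max
    candidate = suv.values > threshold
    for excl in exclusions or []:
        if not excl.reference.same_grid(grid):
            raise ValueError("exclusion mask is not on the SUV grid")
        candidate &= ~excl.values
    if not candidate.any():
        raise ValueError(
            f"no voxel exceeds the threshold {threshold:.4g} "
            f"({config.fby_threshold_multiple} x Nmax {ref.n_max:.4g})"
        )
    seed_idx = _seed_index(grid, seed)
    if not candidate[seed_idx]:
        raise ValueError("seed voxel does not exceed the metabolic threshold")
    comp = _seed_component(candidate, seed_idx, config.connectivity)
    filled = _fill_cavities(comp)
    for excl in exclusions or []:
        filled &= ~excl.values
    return BinaryMask(filled, grid)


def clean_mask(mask: BinaryMask, seed: np.ndarray, connectivity: int = 26) -> BinaryMask:
    """Continuity editing: keep the seed's component, fill enclosed cavities."""
    seed_idx = _seed_index(mask.reference, seed)
    if not mask.values[seed_idx]:
        raise ValueError("seed voxel is not set in the mask")
    comp = _seed_component(mask.values, seed_idx, connectivity)
    return BinaryMask(_fill_cavities(comp), mask.reference)
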