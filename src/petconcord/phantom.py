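"""Synthetic paired MRI/PET digital phantoms of contrast-enhanced brain tumors.

Each phantom is a spherical "brain" containing a contrast-enhancing
tumor core and, for diffuse-tumor phantoms, a concentric infiltration
shell with metabolic uptake above the detection threshold but no
contrast enhancement.  The generator emits:

* a post-contrast T1-like volume — Gaussian background with the core
  raised by a fixed enhancement intensity;
* an SUV map — truncated-Gaussian normal-brain background (defaults
  tuned so a contralateral reference measurement yields Nmean ≈ 0.037
  and Nmax ≈ 0.116), a hot core (SUV 2.5) and a margin shell whose
  uptake tapers linearly outward while staying above 3 × the expected
  background maximum;
* optional venous-sinus-like hot blob with its ground-truth exclusion
  mask;
* ground-truth masks for the enhancing core, the PET-positive volume
  and the margin (their set difference).

Circumscribed tumors are the ``margin_width = 0`` limit: the PET-positive
truth coincides with the enhancing core.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .segmentation import BinaryMask, MidlinePlane
from .volume_io import SUVMap, VolumeImage

__all__ = [
    "SinusBlob",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomCase",
    "generate_phantom",
    "generate_cohort",
    "DOSE_MBQ_PER_KG",
]

DOSE_MBQ_PER_KG = 3.7  # injected activity per body weight


@dataclass(frozen=True)
class SinusBlob:
    """A physiological hot structure (venous-sinus-like) on the PET map."""

    center_mm: tuple[float, float, float] = (0.0, -40.0, 0.0)
    radius_mm: float = 6.0
    suv: float = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of one phantom.

    Distances in mm, world coordinates centered on the brain.  The
    midline is the plane x = 0; ``tumor_center`` must be strictly
    off-midline.  ``margin_width = 0`` gives a circumscribed tumor,
    ``margin_width > 0`` a diffuse one.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 1.5
    brain_radius_mm: float = 60.0
    tumor_center_mm: tuple[float, float, float] = (30.0, 10.0, 0.0)
    core_radius_mm: float = 10.0
    margin_width_mm: float = 0.0
    core_suv: float = 2.5
    margin_suv: float = 0.9
    margin_suv_floor: float = 0.45
    background_suv_mean: float = 0.037
    background_suv_sd: float = 0.022
    mri_background: float = 100.0
    enhancement_intensity: float = 80.0
    noise_sd_mri: float = 5.0
    body_weight_kg: float = 70.0
    sinus_blob: SinusBlob | None = field(default_factory=SinusBlob)
    seed: int = 0

    def __post_init__(self):
        if self.core_radius_mm <= 0:
            raise ValueError("core_radius_mm must be positive")
        if self.margin_width_mm < 0:
            raise ValueError("margin_width_mm must be nonnegative")
        if abs(self.tumor_center_mm[0]) < 1e-9:
            raise ValueError("tumor center must lie strictly off the midline")
        reach = float(np.linalg.norm(self.tumor_center_mm)) + self.tumor_outer_radius_mm
        if reach > self.brain_radius_mm:
            raise ValueError(
                f"tumor (reach {reach:.1f} mm) exceeds the brain support "
                f"({self.brain_radius_mm} mm)"
            )

    @property
    def tumor_outer_radius_mm(self) -> float:
        return self.core_radius_mm + self.margin_width_mm

    @property
    def injected_activity_mbq(self) -> float:
        return DOSE_MBQ_PER_KG * self.body_weight_kg

    def grid(self) -> VolumeImage:
        """Empty image on the phantom grid (brain center at world 0)."""
        shape = np.asarray(self.grid_shape)
        spacing = np.full(3, self.spacing_mm)
        origin = -(shape - 1) / 2.0 * spacing
        return VolumeImage(np.zeros(self.grid_shape), spacing, origin)

    def midline(self) -> MidlinePlane:
        return MidlinePlane(normal=(1.0, 0.0, 0.0), point=(0.0, 0.0, 0.0))


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth masks on the phantom grid."""

    enhancement: BinaryMask
    fby_positive: BinaryMask
    margin: BinaryMask
    exclusion: BinaryMask

    def __post_init__(self):
        if (self.enhancement.values & ~self.fby_positive.values).any():
            raise ValueError("enhancement truth must be contained in PET truth")


@dataclass(frozen=True)
class PhantomCase:
    """One synthetic patient: phantom volumes, truth and demographics."""

    id: str
    group: str
    age: float
    sex: str
    spec: PhantomSpec
    t1c: VolumeImage
    suv: SUVMap
    truth: PhantomTruth


def _radial_distance(grid: VolumeImage, center_mm) -> np.ndarray:
    ii, jj, kk = grid.index_grids()
    c = (np.asarray(center_mm, dtype=np.float64) - grid.origin) / grid.spacing
    sx, sy, sz = grid.spacing
    return np.sqrt(
        ((ii - c[0]) * sx) ** 2 + ((jj - c[1]) * sy) ** 2 + ((kk - c[2]) * sz) ** 2
    )


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeImage, SUVMap, PhantomTruth]:
    """Generate one paired T1/PET phantom with ground truth.

    Deterministic under a fixed ``spec.seed``.
    """
    grid = spec.grid()
    rng = np.random.default_rng(spec.seed)

    brain = _radial_distance(grid, (0.0, 0.0, 0.0)) <= spec.brain_radius_mm
    d_tumor = _radial_distance(grid, spec.tumor_center_mm)
    core = d_tumor <= spec.core_radius_mm
    fby_pos = d_tumor <= spec.tumor_outer_radius_mm
    margin = fby_pos & ~core

    # --- SUV map: truncated-Gaussian background, deterministic tumor uptake
    suv_vals = np.zeros(grid.shape)
    suv_vals[brain] = np.clip(
        rng.normal(spec.background_suv_mean, spec.background_suv_sd, int(brain.sum())),
        0.0,
        None,
    )
    suv_vals[core] = spec.core_suv
    if spec.margin_width_mm > 0:
        t = (d_tumor[margin] - spec.core_radius_mm) / spec.margin_width_mm
        suv_vals[margin] = spec.margin_suv + t * (spec.margin_suv_floor - spec.margin_suv)

    exclusion = np.zeros(grid.shape, dtype=bool)
    if spec.sinus_blob is not None:
        blob = _radial_distance(grid, spec.sinus_blob.center_mm) <= spec.sinus_blob.radius_mm
        suv_vals[blob] = spec.sinus_blob.suv
        exclusion = blob

    # --- T1 post-contrast: noisy background, core raised by enhancement
    t1_vals = np.zeros(grid.shape)
    t1_vals[brain] = spec.mri_background
    if spec.noise_sd_mri > 0:
        t1_vals[brain] += rng.normal(0.0, spec.noise_sd_mri, int(brain.sum()))
    t1_vals[core] += spec.enhancement_intensity

    t1c = VolumeImage(t1_vals, grid.spacing, grid.origin)
    suv_image = VolumeImage(suv_vals, grid.spacing, grid.origin)
    suv = SUVMap(suv_image, spec.injected_activity_mbq, spec.body_weight_kg)
    truth = PhantomTruth(
        enhancement=BinaryMask(core, grid),
        fby_positive=BinaryMask(fby_pos, grid),
        margin=BinaryMask(margin, grid),
        exclusion=BinaryMask(exclusion, grid),
    )
    return t1c, suv, truth


def generate_cohort(
    n_diffuse: int = 16,
    n_circumscribed: int = 7,
    margin_width_range_diffuse: tuple[float, float] = (3.0, 9.0),
    margin_width_range_circ: tuple[float, float] = (0.0, 1.0),
    base_spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate a two-group synthetic cohort.

    Group sizes default to 16 diffuse vs 7 circumscribed lesions.  Margin
    widths are drawn uniformly from each group's range; core radii get a
    mild ±10% jitter so per-patient volumes vary.  Per-phantom seeds are
    ``seed + patient index`` so the cohort is reproducible from one
    master seed.  Ages are drawn older for the circumscribed group,
    emulating the typical demographics of metastases versus gliomas.
    """
    if n_diffuse < 1 or n_circumscribed < 1:
        raise ValueError("need at least one patient per group")
    for lo, hi in (margin_width_range_diffuse, margin_width_range_circ):
        if lo < 0 or hi < lo:
            raise ValueError("invalid margin width range")
    rng = np.random.default_rng(seed)
    cases: list[PhantomCase] = []
    plan = [("diffuse", margin_width_range_diffuse)] * n_diffuse + [
        ("circumscribed", margin_width_range_circ)
    ] * n_circumscribed
    for i, (group, (lo, hi)) in enumerate(plan):
        width = float(rng.uniform(lo, hi))
        core_r = float(base_spec.core_radius_mm * rng.uniform(0.9, 1.1))
        age_loc, age_scale = (40.0, 9.0) if group == "diffuse" else (58.0, 16.0)
        age = float(np.clip(rng.normal(age_loc, age_scale), 18.0, 90.0))
        sex = "male" if rng.random() < 0.6 else "female"
        weight = float(np.clip(rng.normal(70.0, 12.0), 45.0, 110.0))
        spec = replace(
            base_spec,
            margin_width_mm=width,
            core_radius_mm=core_r,
            body_weight_kg=weight,
            seed=int(seed + i) % 2**31,
        )
        t1c, suv, truth = generate_phantom(spec)
        cases.append(
            PhantomCase(
                id=f"P{i + 1:02d}",
                group=group,
                age=age,
                sex=sex,
                spec=spec,
                t1c=t1c,
                suv=suv,
                truth=truth,
            )
        )
    return cases
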