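"""Per-lesion volumes, concordance scores and regional SUV statistics.

The two concordance scores compare the MRI-defined and PET-defined
lesion volumes as voxel sets on their shared grid:

    overlap volume = |A ∩ B| / min(|A|, |B|)
    DICE score     = 2 |A ∩ B| / (|A| + |B|)

Both are computed on integer voxel counts (the masks share a grid after
resampling), so the arithmetic is exact.  The *margin region* is the set
difference PET-ROI minus MRI-ROI: voxels with suprathreshold metabolic
uptake but no contrast enhancement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .segmentation import BinaryMask, ReferenceStats
from .volume_io import SUVMap

__all__ = [
    "LesionMetrics",
    "mask_volume_ml",
    "overlap_volume",
    "dice_score",
    "suv_stats",
    "tn_ratio",
    "margin_region",
    "lesion_metrics",
]


@dataclass(frozen=True)
class LesionMetrics:
    """Per-lesion metric bundle.

    ``suv_mean_margin`` and ``margin_over_nmax`` are NaN when the margin
    region is empty (the MRI ROI covers the whole PET ROI); a NaN, not 0,
    so that empty margins never bias cohort averages.
    """

    volume_mri_ml: float
    volume_fby_ml: float
    overlap_volume: float
    dice: float
    suv_max: float
    tn_ratio: float
    suv_mean_mri: float
    suv_mean_fby: float
    suv_mean_margin: float
    margin_over_nmax: float
    margin_volume_ml: float
    n_max: float
    n_mean: float

    @property
    def has_margin(self) -> bool:
        return not math.isnan(self.suv_mean_margin)


def _require_same_grid(a: BinaryMask, b: BinaryMask) -> None:
    if not a.same_grid(b):
        raise ValueError("masks live on different grids")


def mask_volume_ml(mask: BinaryMask) -> float:
    """Mask volume in mL: voxel count × voxel volume (mm³) / 1000."""
    return mask.count * mask.reference.voxel_volume_mm3 / 1000.0


def overlap_volume(a: BinaryMask, b: BinaryMask) -> float:
    """|A ∩ B| / min(|A|, |B|) — 1.0 when one mask contains the other."""
    _require_same_grid(a, b)
    if a.empty or b.empty:
        raise ValueError("overlap volume undefined for an empty mask")
    inter = int((a.values & b.values).sum())
    return inter / min(a.count, b.count)


def dice_score(a: BinaryMask, b: BinaryMask) -> float:
    """2 |A ∩ B| / (|A| + |B|)."""
    _require_same_grid(a, b)
    total = a.count + b.count
    if total == 0:
        raise ValueError("DICE undefined when both masks are empty")
    inter = int((a.values & b.values).sum())
    return 2.0 * inter / total


def suv_stats(suv: SUVMap, mask: BinaryMask) -> tuple[float, float]:
    """(SUVmax, SUVmean) over the set voxels of ``mask``."""
    if not mask.reference.same_grid(suv.image):
        raise ValueError("mask is not on the SUV grid")
    if mask.empty:
        raise ValueError("SUV statistics undefined for an empty mask")
    vals = suv.values[mask.values]
    return float(vals.max()), float(vals.mean())


def tn_ratio(suv_max: float, n_max: float) -> float:
    """Tumor-to-normal ratio: lesion SUVmax over normal-brain Nmax."""
    if n_max <= 0:
        raise ValueError("n_max must be positive")
    return suv_max / n_max


def margin_region(fby: BinaryMask, mri: BinaryMask) -> BinaryMask:
    """Voxels with metabolic uptake but no contrast enhancement: fby \\ mri."""
    _require_same_grid(fby, mri)
    return BinaryMask(fby.values & ~mri.values, fby.reference)


def lesion_metrics(
    suv: SUVMap, mri: BinaryMask, fby: BinaryMask, ref: ReferenceStats
) -> LesionMetrics:
    """Assemble the full per-lesion metric bundle."""
    smax_fby, smean_fby = suv_stats(suv, fby)
    _, smean_mri = suv_stats(suv, mri)
    margin = margin_region(fby, mri)
    if margin.empty:
        smean_margin = float("nan")
        margin_ratio = float("nan")
    else:
        _, smean_margin = suv_stats(suv, margin)
        margin_ratio = smean_margin / ref.n_max
    return LesionMetrics(
        volume_mri_ml=mask_volume_ml(mri),
        volume_fby_ml=mask_volume_ml(fby),
        overlap_volume=overlap_volume(mri, fby),
        dice=dice_score(mri, fby),
        suv_max=smax_fby,
        tn_ratio=tn_ratio(smax_fby, ref.n_max),
        suv_mean_mri=smean_mri,
        suv_mean_fby=smean_fby,
        suv_mean_margin=smean_margin,
        margin_over_nmax=margin_ratio,
        margin_volume_ml=mask_volume_ml(margin),
        n_max=ref.n_max,
        n_mean=ref.n_mean,
    )
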