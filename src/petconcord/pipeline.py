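"""Per-patient and cohort orchestration.

The per-patient flow mirrors the clinical analysis protocol: resample
the PET SUV map onto the T1 grid with the supplied affine, place the
contralateral reference spheres, segment the contrast-enhancing volume
on T1, segment the metabolic tumor volume on PET (threshold relative to
the reference Nmax, physiological structures excluded), then compute
volumes, concordance scores and regional SUV statistics.  The cohort
flow aggregates per-patient rows and runs the group comparisons.

Everything is usable both on in-memory phantom cases (fast, used by the
tests) and on a directory layout of NIfTI volumes plus JSON sidecars
(the CLI path).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_stats
from . import concordance, phantom, segmentation, volume_io
from .cohort import CohortResult, PatientRecord
from .concordance import LesionMetrics
from .phantom import PhantomCase, PhantomSpec
from .segmentation import BinaryMask, MidlinePlane, SegmentationConfig
from .volume_io import AffineTransform, SUVMap, VolumeImage

logger = logging.getLogger("petconcord")

__all__ = [
    "PipelineConfig",
    "PatientResult",
    "analyze_case",
    "run_simulate",
    "run_patient",
    "run_cohort",
    "run_all",
    "cases_to_records",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the whole pipeline (segmentation + cohort design)."""

    fby_threshold_multiple: float = 3.0
    mri_k: float = 3.0
    connectivity: int = 26
    sphere_radius_mm: float = 5.0
    n_diffuse: int = 16
    n_circumscribed: int = 7
    margin_width_range_diffuse: tuple[float, float] = (3.0, 9.0)
    margin_width_range_circ: tuple[float, float] = (0.0, 1.0)
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 1.5
    master_seed: int = 0
    score_decimals: int = 3
    volume_decimals: int = 1

    def segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(
            fby_threshold_multiple=self.fby_threshold_multiple,
            mri_k=self.mri_k,
            connectivity=self.connectivity,
            sphere_radius_mm=self.sphere_radius_mm,
        )

    def base_spec(self) -> PhantomSpec:
        return PhantomSpec(grid_shape=self.grid_shape, spacing_mm=self.spacing_mm)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("margin_width_range_diffuse", "margin_width_range_circ", "grid_shape"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class PatientResult:
    """Segmentation masks and metrics for one patient."""

    metrics: LesionMetrics
    ref_mask: BinaryMask
    ref_stats: segmentation.ReferenceStats
    roi_mri: BinaryMask
    roi_fby: BinaryMask
    margin: BinaryMask


def analyze_case(
    t1c: VolumeImage,
    suv: SUVMap,
    tumor_center: np.ndarray,
    midline: MidlinePlane,
    exclusions: list[BinaryMask] | None = None,
    config: SegmentationConfig = SegmentationConfig(),
    transform: AffineTransform | None = None,
) -> PatientResult:
    """Run the per-patient analysis on in-memory volumes.

    ``transform`` maps PET world coordinates into the T1 frame; the SUV
    map is resampled onto the T1 grid first (skipped when the grids
    already coincide under the identity transform).
    """
    identity = transform is None or (
        np.allclose(transform.linear, np.eye(3)) and np.allclose(transform.translation, 0)
    )
    if not (identity and suv.image.same_grid(t1c)):
        resampled = volume_io.resample_to(suv.image, t1c, transform, mode="intensity")
        suv = SUVMap(resampled, suv.injected_activity_mbq, suv.body_weight_kg)
        exclusions = [
            BinaryMask(
                volume_io.resample_to(e.to_volume(), t1c, transform, mode="mask").values,
                t1c,
            )
            for e in (exclusions or [])
        ]

    ref_mask, ref_stats = segmentation.place_reference_rois(
        suv, tumor_center, midline, config
    )
    logger.info(
        "reference ROI: Nmax=%.4f Nmean=%.4f (3 spheres r=%.1f mm)",
        ref_stats.n_max,
        ref_stats.n_mean,
        config.sphere_radius_mm,
    )
    roi_mri = segmentation.segment_mri(t1c, tumor_center, ref_mask, config)
    roi_fby = segmentation.segment_fby(suv, ref_stats, tumor_center, exclusions, config)
    logger.info(
        "PET threshold %.4f (=%.1f x Nmax); |ROI_MRI|=%d |ROI_FBY|=%d voxels",
        config.fby_threshold_multiple * ref_stats.n_max,
        config.fby_threshold_multiple,
        roi_mri.count,
        roi_fby.count,
    )
    metrics = concordance.lesion_metrics(suv, roi_mri, roi_fby, ref_stats)
    return PatientResult(
        metrics=metrics,
        ref_mask=ref_mask,
        ref_stats=ref_stats,
        roi_mri=roi_mri,
        roi_fby=roi_fby,
        margin=concordance.margin_region(roi_fby, roi_mri),
    )


def cases_to_records(
    cases: list[PhantomCase], config: SegmentationConfig = SegmentationConfig()
) -> list[PatientRecord]:
    """Analyze every phantom case and wrap the results as patient records."""
    records = []
    for case in cases:
        result = analyze_case(
            case.t1c,
            case.suv,
            np.asarray(case.spec.tumor_center_mm),
            case.spec.midline(),
            exclusions=[case.truth.exclusion] if not case.truth.exclusion.empty else None,
            config=config,
        )
        records.append(
            PatientRecord(
                id=case.id,
                group=case.group,
                age=case.age,
                sex=case.sex,
                metrics=result.metrics,
                ref=result.ref_stats,
            )
        )
    return records


# ---------------------------------------------------------------- disk layout


def _write_mask(mask: BinaryMask, path: Path) -> None:
    volume_io.write_volume(mask.to_volume(), path, mask=True)


def run_simulate(out_dir: str | Path, config: PipelineConfig = PipelineConfig()) -> Path:
    """Write the full synthetic cohort (volumes, truths, sidecars, manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cases = phantom.generate_cohort(
        n_diffuse=config.n_diffuse,
        n_circumscribed=config.n_circumscribed,
        margin_width_range_diffuse=config.margin_width_range_diffuse,
        margin_width_range_circ=config.margin_width_range_circ,
        base_spec=config.base_spec(),
        seed=config.master_seed,
    )
    manifest_rows = []
    for case in cases:
        pdir = out / case.id
        pdir.mkdir(exist_ok=True)
        volume_io.write_volume(case.t1c, pdir / "t1c.nii.gz")
        # PET stored as activity concentration (kBq/mL); SUV is recomputed
        # from the sidecar dose and weight at analysis time.
        dose_kbq = case.suv.injected_activity_mbq * 1000.0
        weight_g = case.suv.body_weight_kg * 1000.0
        activity = VolumeImage(
            case.suv.values * (dose_kbq / weight_g),
            case.suv.image.spacing,
            case.suv.image.origin,
        )
        volume_io.write_volume(activity, pdir / "pet_activity.nii.gz")
        _write_mask(case.truth.enhancement, pdir / "truth_enhancement.nii.gz")
        _write_mask(case.truth.fby_positive, pdir / "truth_fby.nii.gz")
        _write_mask(case.truth.margin, pdir / "truth_margin.nii.gz")
        exclusion_files = []
        if not case.truth.exclusion.empty:
            _write_mask(case.truth.exclusion, pdir / "exclusion_sinus.nii.gz")
            exclusion_files.append("exclusion_sinus.nii.gz")
        sidecar = {
            "id": case.id,
            "group": case.group,
            "age": case.age,
            "sex": case.sex,
            "body_weight_kg": case.suv.body_weight_kg,
            "injected_activity_mbq": case.suv.injected_activity_mbq,
            "tumor_center_mm": list(case.spec.tumor_center_mm),
            "midline": {"normal": [1.0, 0.0, 0.0], "point": [0.0, 0.0, 0.0]},
            "pet_to_t1_affine": {
                "linear": np.eye(3).tolist(),
                "translation": [0.0, 0.0, 0.0],
            },
            "exclusion_masks": exclusion_files,
            "seed": case.spec.seed,
            "margin_width_mm": case.spec.margin_width_mm,
        }
        (pdir / "sidecar.json").write_text(json.dumps(sidecar, indent=2))
        manifest_rows.append(
            {
                "id": case.id,
                "group": case.group,
                "age": round(case.age, 1),
                "sex": case.sex,
                "margin_width_mm": round(case.spec.margin_width_mm, 3),
                "dir": case.id,
            }
        )
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    config.to_json(out / "config.json")
    logger.info("simulated %d patients into %s", len(cases), out)
    return out / "manifest.csv"


def run_patient(
    patient_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> dict:
    """Analyze one on-disk patient; write ROI masks and a metrics row."""
    pdir = Path(patient_dir)
    sidecar_path = pdir / "sidecar.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing patient sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for name in ("t1c.nii.gz", "pet_activity.nii.gz"):
        if not (pdir / name).exists():
            raise FileNotFoundError(f"missing input volume: {pdir / name}")

    t1c = volume_io.read_volume(pdir / "t1c.nii.gz")
    activity = volume_io.read_volume(pdir / "pet_activity.nii.gz")
    suv = volume_io.compute_suv(
        activity, sidecar["injected_activity_mbq"], sidecar["body_weight_kg"]
    )
    affine = sidecar.get("pet_to_t1_affine")
    transform = (
        AffineTransform(np.array(affine["linear"]), np.array(affine["translation"]))
        if affine
        else None
    )
    exclusions = []
    for name in sidecar.get("exclusion_masks", []):
        vol = volume_io.read_volume(pdir / name)
        exclusions.append(BinaryMask(vol.values > 0.5, vol))
    midline = MidlinePlane(
        normal=sidecar["midline"]["normal"], point=sidecar["midline"]["point"]
    )
    try:
        result = analyze_case(
            t1c,
            suv,
            np.asarray(sidecar["tumor_center_mm"]),
            midline,
            exclusions=exclusions or None,
            config=config.segmentation_config(),
            transform=transform,
        )
    except ValueError as err:
        raise RuntimeError(f"patient {sidecar['id']}: segmentation failed: {err}") from err

    out = Path(out_dir) if out_dir else pdir
    out.mkdir(parents=True, exist_ok=True)
    _write_mask(result.ref_mask, out / "roi_ref.nii.gz")
    _write_mask(result.roi_mri, out / "roi_mri.nii.gz")
    _write_mask(result.roi_fby, out / "roi_fby.nii.gz")
    _write_mask(result.margin, out / "roi_margin.nii.gz")

    m = result.metrics
    row = {
        "id": sidecar["id"],
        "group": sidecar["group"],
        "age": sidecar["age"],
        "sex": sidecar["sex"],
        **{
            k: getattr(m, k)
            for k in (
                "volume_mri_ml",
                "volume_fby_ml",
                "overlap_volume",
                "dice",
                "suv_max",
                "tn_ratio",
                "suv_mean_mri",
                "suv_mean_fby",
                "suv_mean_margin",
                "margin_over_nmax",
                "margin_volume_ml",
                "n_max",
                "n_mean",
            )
        },
    }
    (out / "metrics.json").write_text(json.dumps(row, indent=2, allow_nan=True))
    return row


def run_cohort(
    dataset_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> CohortResult:
    """Analyze every patient in the manifest and emit the cohort tables."""
    root = Path(dataset_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    if manifest["group"].nunique() < 2:
        raise ValueError("cohort must contain both tumor groups")
    rows = [run_patient(root / rec["dir"], config) for rec in manifest.to_dict("records")]
    frame = pd.DataFrame(rows)
    out = Path(out_dir) if out_dir else root
    out.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out / "metrics.csv", index=False, float_format="%.6g")

    result = cohort_stats.build_cohort_tables_from_frame(frame)
    result.variables.round(6).to_csv(out / "cohort_table.csv")
    (out / "tests.json").write_text(json.dumps(result.to_dict(), indent=2))
    logger.info(
        "cohort analysis: %d diffuse vs %d circumscribed patients",
        result.n_diffuse,
        result.n_circumscribed,
    )
    return result


def run_all(
    out_dir: str | Path, config: PipelineConfig = PipelineConfig()
) -> CohortResult:
    """simulate + per-patient analysis + cohort comparison, in one call."""
    run_simulate(out_dir, config)
    return run_cohort(out_dir, config)
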