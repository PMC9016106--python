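# petconcord

Volumetric concordance of PET metabolic tumor volumes with
contrast-enhanced MRI volumes in brain tumors — a tested pipeline plus
a synthetic digital-phantom cohort that exercises every stage.

## What it computes, and for whom

For neuro-oncology imaging groups comparing a PET tracer's biological
target volume against the contrast-enhancing volume used to plan
surgery and radiotherapy. Per lesion, on a shared voxel grid:

* **Reference ROI** — three spheres mirrored onto the contralateral
  normal hemisphere; their pooled maximum and mean SUV give the
  normal-brain statistics `Nmax`, `Nmean`.
* **ROI_MRI** — the contrast-enhancing volume on post-contrast
  T1-weighted MRI (threshold at normal mean + 3 sd, seeded component,
  hole fill).
* **ROI_FBY** — the metabolic tumor volume: voxels with
  `SUV > 3.0 × Nmax`, continuity-cleaned, with physiological hot
  structures (venous sinus, choroid plexus) excluded.

From the two lesion masks A = ROI_MRI and B = ROI_FBY:

```
overlap volume = |A ∩ B| / min(|A|, |B|)
DICE           = 2 |A ∩ B| / (|A| + |B|)
```

plus volumes (mL), SUVmax, the tumor-to-normal ratio SUVmax/Nmax,
per-ROI SUVmean, and the SUVmean of the *margin region* B \ A (uptake
beyond enhancement). Cohort statistics compare diffuse (infiltrative
glioma) against circumscribed (metastasis/meningioma) lesions: Welch
t-tests, Fisher's exact sex test, Wilcoxon rank-sum for DICE/overlap
and margin variables, Wilcoxon signed-rank for paired per-ROI SUVmean.

Because clinical image data of this kind are not publicly deposited,
the package ships a phantom generator (`petconcord.phantom`) producing
paired T1/PET volumes with ground-truth masks: diffuse phantoms carry a
suprathreshold infiltration shell around the enhancing core,
circumscribed phantoms do not. See `docs/methods.md` for the model and
its limits.

## Worked example

```python
import numpy as np
from petconcord import phantom, pipeline

spec = phantom.PhantomSpec(margin_width_mm=6.0, seed=3)   # a diffuse lesion
t1c, suv, truth = phantom.generate_phantom(spec)
result = pipeline.analyze_case(
    t1c, suv, np.array(spec.tumor_center_mm), spec.midline(),
    exclusions=[truth.exclusion],
)
m = result.metrics
print(f"Nmax={result.ref_stats.n_max:.3f}  V_MRI={m.volume_mri_ml:.1f} mL  "
      f"V_FBY={m.volume_fby_ml:.1f} mL")
print(f"overlap={m.overlap_volume:.3f}  dice={m.dice:.3f}  "
      f"margin SUVmean={m.suv_mean_margin:.3f}")
```

prints

```
Nmax=0.103  V_MRI=4.2 mL  V_FBY=17.1 mL
overlap=1.000  dice=0.393  margin SUVmean=0.643
```

The enhancing volume (4.2 mL) is entirely contained in the metabolic
volume (17.1 mL): overlap is 1.000 while DICE is low because the
infiltration shell lies outside the enhancement; the margin's mean SUV
(0.643 ≈ 6 × Nmax) is far above the 3 × Nmax threshold.

The cohort-scale analysis is scripted:

```
python analysis/01_simulate_cohort.py          # 23 phantoms -> scratch/dataset
python analysis/02_patient_metrics.py          # per-patient rows -> results/metrics.csv
python analysis/03_cohort_comparison.py        # group tables -> results/
python analysis/04_group_contrast_replicates.py
```

A run of step 03 on the default cohort (master seed 7) prints

```
overlap volume: diffuse 1.000 ± 0.000 vs circumscribed 0.999 ± 0.001 (rank-sum p = 0.001)
DICE: diffuse 0.411 ± 0.090 vs circumscribed 0.924 ± 0.048 (rank-sum p = 8.158e-06)
paired SUVmean MRI vs PET ROI (diffuse): W+=136.0, p = 3.052e-05
```

i.e. enhancement is essentially always contained in the metabolic
volume, diffuse lesions have much lower DICE than circumscribed ones
(the infiltration shell), and the PET-ROI SUVmean is systematically
below the MRI-ROI SUVmean. The same flow is available from a shell via
the `petconcord` CLI (`simulate` / `patient` / `cohort` / `all`).

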