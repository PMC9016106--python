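# Methods

## Problem and model

Amino-acid-transport PET tracers accumulate in brain-tumor tissue well
beyond the blood–brain-barrier breakdown that produces contrast
enhancement on T1-weighted MRI. The analysis implemented here asks, per
lesion, how the metabolic tumor volume — voxels whose standardized
uptake value (SUV) exceeds a multiple of the normal-brain maximum —
relates to the contrast-enhancing volume, and whether that relationship
differs between infiltratively growing (diffuse) and sharply bounded
(circumscribed) tumors.

Per patient the pipeline defines three regions of interest on a common
grid:

1. **Reference ROI**: three spheres mirrored from the tumor center onto
   the contralateral hemisphere. The maximum and mean SUV over their
   union give the normal-brain statistics `Nmax` and `Nmean`.
2. **MRI ROI**: the contrast-enhancing volume on post-contrast T1.
3. **PET ROI**: voxels with `SUV > 3.0 × Nmax` (strict inequality),
   restricted to the connected component containing the lesion seed,
   with interior cavities filled and physiological hot structures
   (venous sinus, choroid plexus) removed via exclusion masks.

Concordance is quantified on voxel counts of the shared grid:

    overlap volume = |A ∩ B| / min(|A|, |B|)
    DICE           = 2|A ∩ B| / (|A| + |B|)

and the *margin region* `PET \ MRI` (uptake without enhancement)
carries its own SUVmean and SUVmean/Nmax summary. Cohort-level
comparisons pair each variable with its conventional test: Welch
t-tests for continuous baseline/metabolic variables, Fisher's exact
test for sex, Wilcoxon rank-sum for the concordance and margin
variables, and Wilcoxon signed-rank for the paired MRI-ROI versus
PET-ROI SUVmean within each group. No multiple-testing correction is
applied.

## SUV construction and grid conventions

SUV is computed as tissue activity concentration (kBq/mL) divided by
injected activity per gram of body weight, with density 1 g/mL, so a
concentration numerically equal to dose-per-gram gives SUV 1. Decay
correction of the injected activity to scan time is a scalar factor
applied *before* `compute_suv` — appropriate for a static single-frame
acquisition.

Voxel indices are 0-based; world coordinates are voxel-center positions
in mm on an axis-aligned grid (`world = origin + index × spacing`).
`interpolate_halve` reproduces the clinical preprocessing step that
halves the voxel size in all dimensions: the output has exactly twice
the input dimensions and the fine voxel centers are placed
cell-centered, preserving the physical extent. Intensities are
interpolated trilinearly with edge clamping (constants stay constant;
no value leaves the input range); masks are resampled
nearest-neighbor. PET-to-T1 registration is *accepted as an input*
affine (identity for phantoms); estimating it is out of scope. All
concordance arithmetic happens on the T1-resolution grid after
resampling. On disk, volumes are NIfTI-1 (float32 intensities, uint8
masks).

## Segmentation parameters

| parameter | default | meaning |
|---|---|---|
| `fby_threshold_multiple` | 3.0 | PET threshold as a multiple of Nmax |
| `mri_k` | 3.0 | MRI threshold = normal mean + k·sd |
| `connectivity` | 26 | foreground connectivity (background fill is 6-connected) |
| `sphere_radius_mm` | 5.0 | reference sphere radius |

The threshold multiple 3.0 is the domain constant (it matches the
tumor-to-normal uptake ratio generally required for boron neutron
capture therapy); the other three are this package's own choices for
steps the clinical protocol performed manually or semi-automatically in
interactive software. In particular:

* Reference-sphere placement: the primary sphere is the exact mirror
  image of the tumor center across the midline plane; the two
  companions are offset ±2 radii along the superior–inferior axis.
  Sphere radius and the pooling of the three spheres into a single
  Nmax/Nmean are reproducible stand-ins for manual placement.
* The MRI "covers the contrast-enhanced area" rule is realized as a
  robust z-threshold (mean + 3·sd of the normal-region intensity)
  followed by the seeded connected component and hole fill — the
  simplest reproducible proxy for interactive contouring.
* Continuity editing ("remove discontinuous areas, fill the inside")
  maps to: keep the seed's 26-connected component, fill cavities
  enclosed under 6-connected background. `clean_mask` is idempotent.
* Exclusion masks are inputs; anatomy-based localization of the venous
  sinus or choroid plexus is not re-derived.

## The digital phantom

The generator emulates the features of the clinical data that the
pipeline's logic depends on, at a desk-scale grid (default 96³ voxels,
1.5 mm isotropic — the T1-resolution working grid after interpolation):

* spherical brain (radius 60 mm) with i.i.d. Gaussian background SUV
  truncated at 0, mean 0.037 (the printed cohort normal-brain mean);
  the background sd 0.022 is set so the *maximum* over the ~470
  reference-sphere voxels lands near the printed cohort Nmax ≈ 0.116
  (for n voxels, E[max] ≈ μ + σ√(2 ln n));
* a tumor core (default radius 10 mm, ±10% per-patient jitter) with
  SUV 2.5 (printed cohort SUVmax ≈ 2.5) and MRI enhancement 80 units
  above a background of 100 with noise sd 5;
* for diffuse phantoms, a concentric infiltration shell whose SUV
  tapers linearly from 0.9 at the core edge to 0.45 at the outer edge —
  both ends chosen inside (3 × Nmax, core SUV) so the whole shell
  passes the threshold while diluting the PET-ROI SUVmean below the
  MRI-ROI SUVmean, as observed clinically;
* an optional venous-sinus-like blob (SUV 1.0) with its ground-truth
  exclusion mask, present by default to exercise the exclusion path;
* ground-truth masks satisfying enhancement ⊆ PET-positive, with the
  margin as their set difference.

The default cohort is 16 diffuse phantoms with margin widths drawn
U(3, 9) mm and 7 circumscribed phantoms with U(0, 1) mm — the group
sizes of the clinical cohort. One master seed drives everything;
per-phantom seeds are `master + patient index`. Ages are drawn older
for the circumscribed group (58 ± 16 vs 40 ± 9 years) to mimic the
demographics of metastases versus gliomas; sex is Bernoulli(0.6) male.

What the phantom does **not** model: anatomy, partial-volume/PSF
blurring (no smoothing by default), spatially correlated noise, PET
reconstruction artifacts, registration error. Passing tests therefore
demonstrate the correctness of the segmentation/concordance logic and
the qualitative group mechanism — not clinical segmentation accuracy on
real images. In particular the absolute DICE level of the diffuse group
(~0.41 at these shell widths and a 10 mm core) is a geometric
consequence of the chosen phantom scale and is intentionally not tuned
to reproduce the clinical value; only the *direction and detectability*
of the diffuse-vs-circumscribed contrast carries over.

## Statistical details

* Rank-sum: exact null distribution when n₁+n₂ ≤ 25 without ties,
  otherwise the normal approximation with tie and continuity
  correction (via `scipy.stats.mannwhitneyu`). The reported statistic
  is the rank sum of the first sample.
* Signed-rank: zero differences dropped; for ≤ 50 nonzero differences
  the two-sided p is exact and *conditional on the observed midranks*,
  computed by convolving the distribution of W⁺ over all 2ⁿ sign
  assignments (midranks are half-integers, so 2W⁺ is integer-indexed).
  This hand-rolled exact path exists because the library implementation
  falls back to a normal approximation whenever magnitudes tie.
* t-test: Welch (unequal variances), two-sided; the degenerate case of
  zero variance in both groups with equal means returns p = 1, and
  with unequal means is rejected as an error.
* Fisher: two-sided, summing hypergeometric probabilities ≤ the
  observed table's.
* Margin variables can be undefined for circumscribed patients whose
  MRI ROI covers the whole PET ROI; those patients are excluded from
  margin comparisons (NaN, never 0), and a group with fewer than two
  defined values yields no test rather than an error.

## Numerical and degenerate-input choices

* Concordance scores are exact integer arithmetic on voxel counts;
  volumes in mL are `count × voxel volume / 1000`.
* Strict inequality at both thresholds (`>`), so a noise-free
  background exactly at the normal mean is never segmented.
* Seeds given in world coordinates are rounded to the nearest voxel; a
  seed outside the grid, below threshold, or outside the mask is an
  error naming the condition.
* Empty candidate sets, empty masks in a score denominator, all-zero
  paired differences, and a missing group all raise with messages
  naming the stage.

## Problem sizes used by the tests and the acceptance script

Unit tests run on 12³–64³ grids. The end-to-end checks use the default
96³ cohort once (shared fixture). The replicate study of the group
contrast re-runs the full pipeline on 100 (tests) / 50 (acceptance
script) freshly seeded cohorts at 64³ with 2.25 mm spacing — the same
physical extent and tumor geometry at a coarser sampling, which this
package treats as its standard replicate-study size. At that scale the
two groups' DICE distributions are fully separated and the rank-sum
test rejects in every replicate.

## Known limitations

* The mirrored-sphere placement assumes lateralized lesions; midline
  lesions are rejected rather than handled.
* The MRI threshold rule is a proxy; real contrast enhancement is not
  a clean z-outlier of normal-tissue intensity.
* The exact signed-rank distribution is conditional on observed
  midranks, which is the standard permutation treatment but not the
  only convention.
* `interpolate_halve` documents one specific cell-centered convention;
  scanner consoles may differ.
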