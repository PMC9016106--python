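import numpy as np
import pytest

from petconcord import phantom, pipeline
from petconcord.volume_io import VolumeImage

# Master seed for the study-condition fixtures (cohort, noisy phantoms).
STUDY_SEED = 7


def make_grid(shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return VolumeImage(np.zeros(shape), spacing, origin)


@pytest.fixture
def grid16():
    return make_grid()


@pytest.fixture(scope="session")
def diffuse_phantom():
    """One noisy diffuse phantom (6 mm infiltration margin) with truth."""
    spec = phantom.PhantomSpec(margin_width_mm=6.0, seed=STUDY_SEED)
    t1c, suv, truth = phantom.generate_phantom(spec)
    return spec, t1c, suv, truth


@pytest.fixture(scope="session")
def noisefree_diffuse_phantom():
    spec = phantom.PhantomSpec(
        margin_width_mm=6.0, background_suv_sd=0.0, noise_sd_mri=0.0, seed=STUDY_SEED
    )
    return spec, *phantom.generate_phantom(spec)


@pytest.fixture(scope="session")
def default_cohort_cases():
    """The default synthetic study cohort: 16 diffuse vs 7 circumscribed."""
    return phantom.generate_cohort(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def default_cohort_analyses(default_cohort_cases):
    """Full pipeline run over the default cohort, keeping masks and stats."""
    analyses = []
    for case in default_cohort_cases:
        result = pipeline.analyze_case(
            case.t1c,
            case.suv,
            np.asarray(case.spec.tumor_center_mm),
            case.spec.midline(),
            exclusions=[case.truth.exclusion] if not case.truth.exclusion.empty else None,
        )
        analyses.append((case, result))
    return analyses


@pytest.fixture(scope="session")
def default_cohort_records(default_cohort_analyses):
    from petconcord.cohort import PatientRecord

    return [
        PatientRecord(
            id=case.id,
            group=case.group,
            age=case.age,
            sex=case.sex,
            metrics=result.metrics,
            ref=result.ref_stats,
        )
        for case, result in default_cohort_analyses
    ]
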