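import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from idcgrade import dataset_io as io
from idcgrade.gabor_features import build_bank, extract_cohort_features
from idcgrade.synthetic_phantoms import PhantomSpec, make_cohort, make_patient
from idcgrade.wavelet_segmentation import SegmentationConfig

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_bank():
    return build_bank()


@pytest.fixture(scope="session")
def phantom_patient():
    """One grade-II phantom patient: ROI crops, ROI specs and ground truth."""
    spec = PhantomSpec()
    slices, rois, truth = make_patient(spec, "II", seed=42)
    roi_crops = [io.extract_roi(s, r) for s, r in zip(slices, rois)]
    return spec, roi_crops, truth


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 6-patient (3/class) phantom cohort written to disk."""
    out = tmp_path_factory.mktemp("cohort")
    spec = PhantomSpec()
    manifest, truths = make_cohort(spec, n_per_class=3, seed=123, out_dir=out)
    return spec, out, manifest, truths


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort, default_bank):
    spec, out, manifest, truths = small_cohort
    matrix, masks = extract_cohort_features(
        manifest, SegmentationConfig(seed=7), default_bank, return_masks=True
    )
    return matrix, masks, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
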