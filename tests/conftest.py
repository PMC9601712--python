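"""Shared fixtures: one full-design synthetic study, extracted once per session."""

from __future__ import annotations

import numpy as np
import pytest

from hsidry.hsi_calibration import RoiMask, reflectance_correct, segment_roi
from hsidry.pipeline import extract_tables, model_report
from hsidry.synthetic_data import GeneratorConfig, iter_samples

STUDY_SEED = 11


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down design for fast structural tests (full level layout)."""
    return GeneratorConfig(image_shape=(32, 48), n_echoes=600, seed=3)


@pytest.fixture(scope="session")
def one_sample(small_config):
    """A single generated sample plus its corrected cube and segmented ROI."""
    sample = next(iter_samples(small_config))
    cube = reflectance_correct(sample.cube, sample.white_frame, sample.dark_frame)
    roi = segment_roi(cube)
    return sample, cube, roi


@pytest.fixture(scope="session")
def default_tables():
    """Extraction of the full default study (13 levels x 8 replicates)."""
    return extract_tables(iter_samples(GeneratorConfig(seed=STUDY_SEED)))


@pytest.fixture(scope="session")
def default_report(default_tables):
    """Model evaluations for all feature sets and indicators on the default study."""
    report, models, selections, split = model_report(
        default_tables, seed=STUDY_SEED, cars_runs=60)
    return report, models, selections, split


@pytest.fixture(scope="session")
def noiseless_tables():
    """Deterministic (noise-free) study for the end-to-end calibration oracle."""
    return extract_tables(
        iter_samples(GeneratorConfig(seed=STUDY_SEED, noise_sd=0.0)),
        with_image_features=False, with_nmr=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def truth_roi(sample) -> RoiMask:
    return RoiMask(sample.roi_truth)
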