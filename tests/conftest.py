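"""Shared fixtures: a fixed calibrated cohort and its resampling study.

The cohort emulates the study population (360 patients, in-sample partial
R-squared fixed to exactly 0.11 with a negative lesion-load effect); the
session-scoped bootstrap records (6000 replicates per size) are reused by
every test that summarises the resampling study.
"""

import numpy as np
import pytest

from lesionboot import (
    GeneratorConfig,
    calibrate_generator,
    fix_sample_partial_r2,
    generate_cohort,
    run_resampling_study,
)
from lesionboot.config import COVARIATE_COLUMNS

COHORT_SEED = 11
STUDY_SEED = 5
FULL_R2 = 0.11


@pytest.fixture(scope="session")
def calibrated_config():
    return calibrate_generator(FULL_R2, GeneratorConfig(n_patients=360))


@pytest.fixture(scope="session")
def fixed_cohort(calibrated_config):
    """(cohort, lesion_load) with in-sample partial R2 exactly 0.11."""
    cohort, load = generate_cohort(calibrated_config, seed=COHORT_SEED)
    load = fix_sample_partial_r2(cohort, load, FULL_R2, sign=-1)
    return cohort, load


@pytest.fixture(scope="session")
def covariates(fixed_cohort):
    cohort, _ = fixed_cohort
    return cohort.loc[:, list(COVARIATE_COLUMNS)].to_numpy()


@pytest.fixture(scope="session")
def study_records(fixed_cohort):
    """6000 with-replacement resamples per size from the fixed cohort."""
    cohort, load = fixed_cohort
    return run_resampling_study(cohort, load, B=6000, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_records_without_replacement(fixed_cohort):
    cohort, load = fixed_cohort
    return run_resampling_study(cohort, load, B=6000, seed=STUDY_SEED,
                                with_replacement=False)


@pytest.fixture(scope="session")
def small_grid_config():
    """Desk-scale imaging configuration for volume and GLM tests.

    Coarser 6 mm voxels on a grid with the same physical extent as the
    default 4 mm grid, so even the largest lesions (386 cm^3) still fit and
    can be placed away from the ROI.
    """
    return GeneratorConfig(
        n_patients=120, grid_shape=(26, 32, 26), voxel_size_mm=6.0)


def make_null_design(n, rng):
    """Cohort-like regressor block with no lesion-deficit structure."""
    import pandas as pd

    from lesionboot.config import SCORE_COLUMNS

    data = {c: 50 + 10 * rng.standard_normal(n) for c in SCORE_COLUMNS}
    data["patient_id"] = [f"N{i:03d}" for i in range(n)]
    data["lesion_size_cm3"] = np.exp(4.0 + 0.8 * rng.standard_normal(n))
    return pd.DataFrame(data)
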