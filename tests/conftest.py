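"""Shared fixtures: small geometries and cohorts keep image tests fast."""

import numpy as np
import pytest

from qmrn import AcquisitionGeometry, sample_cohort


@pytest.fixture(scope="session")
def small_geometry() -> AcquisitionGeometry:
    """Reduced matrices / slice counts with the physical FOV preserved.

    Pixel sizes stay close to the full protocol so an ~18 mm^2 nerve is
    still well resolved, while slice counts are trimmed for speed.
    """
    return AcquisitionGeometry(
        matrix_mse=(96, 96), matrix_mt=(96, 96), matrix_ref=(192, 192),
        n_slices_mse=8, n_slices_mt=8, n_slices_ref=9)


@pytest.fixture(scope="session")
def cohort():
    """Three-subject cohort with the default calibrated variance components."""
    return sample_cohort(3, 3, 2, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
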