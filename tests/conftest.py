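import numpy as np
import pytest

from dosiomics.phantom import PhantomParams, generate_patient
from dosiomics.preprocess import preprocess_patient


@pytest.fixture(scope="session")
def small_params():
    return PhantomParams(n_patients=10, seed=7)


@pytest.fixture(scope="session")
def patient(small_params):
    """One deterministic synthetic patient (with its latent BED variance)."""
    rng = np.random.default_rng(42)
    record, bed_var = generate_patient(small_params, rng, patient_id="PFIX")
    return record, bed_var


@pytest.fixture(scope="session")
def preprocessed(patient):
    record, _ = patient
    return preprocess_patient(record)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_roi(rng, shape=(5, 5, 5), n_levels=6, nan_fraction=0.25):
    """A random small discretized ROI with NaN-masked voxels."""
    levels = rng.integers(1, n_levels + 1, size=shape).astype(float)
    mask = rng.uniform(size=shape) < nan_fraction
    levels[mask] = np.nan
    if not np.isfinite(levels).any():
        levels[0, 0, 0] = 1.0
    return levels
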