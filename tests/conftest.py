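import numpy as np
import pytest

from eegage.model import BandPeak, SpectralModelParams
from eegage.simulate import CohortSpec, generate_cohort
from eegage.spectra import FrequencyGrid


@pytest.fixture(scope="session")
def grid() -> FrequencyGrid:
    return FrequencyGrid()


@pytest.fixture(scope="session")
def cohort():
    """Small default-parameter cohort, shared read-only across tests."""
    return generate_cohort(CohortSpec(n_participants=12, seed=42))


def make_params(
    a0=1.0, m=-0.6, k=0.0,
    theta=(0.3, 5.0, 2.0), alpha=(2.0, 10.0, 1.0), beta1=(0.2, 16.0, 2.5),
    beta2=(0.2, 25.0, 3.0), gamma=(0.1, 35.0, 4.0),
) -> SpectralModelParams:
    """Hand-built spectral model parameters for constructed-spectrum tests."""
    bands = [BandPeak(*b) for b in (theta, alpha, beta1, beta2, gamma)]
    return SpectralModelParams(a0=a0, m=m, k=k, bands=bands)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
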