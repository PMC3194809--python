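import numpy as np
import pytest

from peakconcord import SimulationConfig, simulate_dataset
from peakconcord.spectra import Spectrum


@pytest.fixture(scope="session")
def small_config():
    """Fast 7-sample duplicate dataset with 10 resolvable peaks."""
    return SimulationConfig(
        n_cancer=4,
        n_normal=3,
        mz_range=(1000.0, 4000.0),
        n_peaks=10,
        de_fraction=0.2,
        fold_changes=(2.0, 0.5),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-, jitter- and scale-free version of the small dataset."""
    return SimulationConfig(
        n_cancer=4,
        n_normal=3,
        mz_range=(1000.0, 4000.0),
        n_peaks=10,
        de_fraction=0.2,
        fold_changes=(2.0, 0.5),
        noise_sd=0.0,
        scale_sd=0.0,
        mz_jitter_sd=0.0,
        biological_cv=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return simulate_dataset(clean_config)


def make_spectrum(mz, intensity, **kw):
    return Spectrum(np.asarray(mz, float), np.asarray(intensity, float), **kw)


@pytest.fixture
def gaussian_spectrum():
    """One noise-free Gaussian peak on a flat zero baseline."""
    mz = np.linspace(1000.0, 2000.0, 1001)
    y = 50.0 * np.exp(-((mz - 1500.0) ** 2) / (2 * 20.0**2))
    return make_spectrum(mz, y)
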