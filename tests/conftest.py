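import pytest

from anapept import ScreenConfig, SpectrumSimParams, library_default, simulate_spectrum


@pytest.fixture(scope="session")
def library():
    return library_default()


@pytest.fixture(scope="session")
def library_by_name(library):
    return {c.name: c for c in library}


@pytest.fixture
def cfg():
    return ScreenConfig()


@pytest.fixture
def noiseless_params():
    """Degenerate simulation: no jitter, no dropout, no noise peaks."""
    return SpectrumSimParams(mz_sigma=0.0, dropout_p=0.0, n_noise_peaks=0, seed=0)


@pytest.fixture
def noiseless_spectrum(library_by_name, noiseless_params):
    def make(name: str, fraction: str = ""):
        return simulate_spectrum(library_by_name[name], noiseless_params, fraction=fraction)

    return make
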