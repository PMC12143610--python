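import numpy as np
import pytest

from cytofoci import synth


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free, blur-free field parameters with planted focus areas
    spanning both sides of the 5 px cutoff and nucleus-straddling
    plants; the nuclear dsDNA rendering is off so every plant is a
    separate connected component whose rejection reason is checkable."""
    return synth.ImagingTruthParams(
        seed=11,
        psf_sigma=0.0,
        noise_sd=0.0,
        focus_area=(3, 12),
        n_nuclear_foci_per_cell=0.5,
        nuclear_dsdna_level=0.0,
    )


@pytest.fixture(scope="session")
def clean_field(clean_params):
    return synth.generate_field(clean_params, 6.0, "carbon", 0)


@pytest.fixture(scope="session")
def default_params():
    """Generator defaults (realistic SNR, saturated nuclei)."""
    return synth.ImagingTruthParams(seed=7)


@pytest.fixture(scope="session")
def default_field(default_params):
    return synth.generate_field(default_params, 8.0, "carbon", 1)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
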