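import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from stereonmr.synthetic import NoiseSpec, make_study  # noqa: E402


@pytest.fixture(scope="session")
def clean_study():
    """Noise-free 5-center study: 16 candidates, 2 conformers, pops (0.7, 0.3)."""
    return make_study(
        11,
        noise=NoiseSpec(rdc_frac=0.0, noe_frac=0.0, shift_ppm=0.0, j_hz=0.0, rcsa_ppb=0.0),
    )


@pytest.fixture(scope="session")
def noisy_study():
    """Same conditions with 5% RDC noise and mild noise elsewhere."""
    return make_study(
        11,
        noise=NoiseSpec(rdc_frac=0.05, noe_frac=0.05, shift_ppm=0.3, j_hz=0.2, rcsa_ppb=2.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
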