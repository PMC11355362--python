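import numpy as np
import pytest

from hrvband import CohortGenSpec, IbiGenSpec, generate_cohort, generate_ibi


@pytest.fixture(scope="session")
def clean_sinusoid_ibi():
    """Noiseless 3-min series: mean 800 ms, 0.25 Hz modulation, 50 ms amplitude."""
    return generate_ibi(IbiGenSpec(rsa_amp_ms=50.0, noise_sd_ms=0.0))


@pytest.fixture(scope="session")
def noisy_ibi():
    """Realistic resting series with beat-timing jitter."""
    return generate_ibi(IbiGenSpec(rsa_amp_ms=40.0, noise_sd_ms=5.0, seed=42))


@pytest.fixture(scope="session")
def default_cohort():
    """One draw of the default 8-responder / 10-non-responder cohort."""
    return generate_cohort(CohortGenSpec(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
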