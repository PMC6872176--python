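import numpy as np
import pytest

from fmri_seqbench import (
    CONTRAST_DEFINITIONS,
    NoiseProfile,
    generate_paradigm,
    generate_phantom,
)


@pytest.fixture(scope="session")
def small_phantom():
    """16^3 phantom with one ROI per localizer contrast."""
    return generate_phantom(
        (16, 16, 16), 2.0, list(CONTRAST_DEFINITIONS), seed=0
    )


@pytest.fixture(scope="session")
def paradigm():
    """Standard 5:20 min localizer schedule, 3 events per condition."""
    return generate_paradigm(320.0, 3, min_gap=1.0, seed=0)


@pytest.fixture
def silent_profile():
    """Zero-variance profile: the noise-free forward model."""
    return NoiseProfile(
        name="sms_like", thermal_sd=0.0, rho=0.0, n_physio=0, drift_amp=0.0
    )


@pytest.fixture
def thermal_profile():
    """Pure AR(1) thermal noise at 1% of baseline, no drift or physiology."""
    return NoiseProfile(
        name="sms_like", thermal_sd=0.01, rho=0.3, n_physio=0, drift_amp=0.0
    )
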