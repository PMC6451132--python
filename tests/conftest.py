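import numpy as np
import pytest

from ribofret import synthetic_data as sd


@pytest.fixture(scope="session")
def yeast():
    return sd.yeast_model()


@pytest.fixture(scope="session")
def human():
    return sd.human_model()


@pytest.fixture(scope="session")
def thermo():
    """Default simulation thermodynamics: f_c(0)=0.2, plateau 10/11."""
    return sd.ThermoParams(K0=4.0, K2=10.0, KI=10.0)


@pytest.fixture(scope="session")
def photo():
    return sd.PhotophysicsParams()


@pytest.fixture(scope="session")
def quiet_photo():
    """Near-noiseless optics without blinking, for exact-value checks."""
    return sd.PhotophysicsParams(shot_noise_sd=1e-9, background_sd=1e-9,
                                 blink_rate=0.0, bleach_mean_lifetime=1e9)


@pytest.fixture(scope="session")
def small_yeast_dataset(yeast, thermo, photo):
    """60 drug-free yeast traces, reused across read-only tests."""
    return sd.simulate_titration_dataset(yeast, thermo, photo, [0.0], 60, 901)[0]
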