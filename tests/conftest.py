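import numpy as np
import pytest
from hypothesis import settings

import phonomap as pm

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid72():
    """The 8 x 9 = 72-sensor grid at 40 px spacing."""
    return pm.generate_sensor_layout(8, 9, 40.0, (120.0, 140.0))


@pytest.fixture(scope="session")
def schedule():
    return pm.BeatSchedule.regular(5, rr=1.0)


@pytest.fixture(scope="session")
def registration_scene(grid72):
    from phonomap.fixtures import make_registration_scene
    return make_registration_scene(grid72, rotation_deg=8.0, scale=1.25,
                                   translation=(40.0, 30.0))


def snr_vs_clean(x: np.ndarray, clean: np.ndarray) -> float:
    """SNR in dB of x against a known clean reference."""
    return 10 * np.log10(np.mean(clean ** 2) / np.mean((x - clean) ** 2))
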