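import numpy as np
import pytest

from wriststep.simulate import Bout, GaitScenario, simulate_cohort, simulate_recording


@pytest.fixture(scope="session")
def small_cohort():
    """Eight short synthetic participants for pipeline-level tests."""
    return simulate_cohort(8, seed=11, duration=240.0)


@pytest.fixture()
def clean_walk_recording():
    """Single 120 s recording with one clean 100-step bout at 100 steps/min."""
    sc = GaitScenario(duration=120.0, bouts=[Bout(10.0, 100.0, 100)],
                      arm_noise_sd=0.02, seed=5)
    return simulate_recording(sc)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
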