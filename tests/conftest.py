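import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eegduo import (
    OscillationSpec,
    SystemModel,
    generate_session,
    generate_task_schedule,
    gonogo_template,
)
from eegduo.pipeline import preprocess_session

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

FS = 128.0


@pytest.fixture(scope="session")
def small_schedule():
    """Three 20-trial blocks, 70/30 condition split."""
    return generate_task_schedule(3, 20, 0.7, 1.0, seed=11)


@pytest.fixture(scope="session")
def small_session(small_schedule):
    """Paired HQ/LC Go/NoGo session at study noise levels, 95 ms LC delay."""
    template = gonogo_template()
    osc = OscillationSpec(duration_s=small_schedule.end_s + 10.0)
    systems = [SystemModel("HQ", 0.0), SystemModel("LC", 95.0)]
    return generate_session(small_schedule, template, osc, systems, seed=7)


@pytest.fixture(scope="session")
def small_epochs(small_session):
    """Preprocessed epochs of the small paired session."""
    return {name: preprocess_session(rec)[0]
            for name, rec in small_session.items()}


@pytest.fixture(scope="session")
def noisefree_session(small_schedule):
    """Same schedule with all noise sources off and no acquisition filter."""
    template = gonogo_template()
    systems = [
        SystemModel("HQ", 0.0, noise_sd_uV=0.0, pink_sd_uV=0.0,
                    clock_drift_ppm=0.0, acquisition_band_hz=None),
        SystemModel("LC", 95.0, noise_sd_uV=0.0, pink_sd_uV=0.0,
                    clock_drift_ppm=0.0, acquisition_band_hz=None),
    ]
    return generate_session(small_schedule, template, None, systems, seed=3,
                            duration_s=small_schedule.end_s + 5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
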