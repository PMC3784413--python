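import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bulbwave import (
    AttenuationModel,
    CohortDesign,
    ConditionTimeline,
    SegmentSchedule,
    SimulationParams,
    build_gain_envelope,
    simulate_recording,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def fast_params():
    """Desk-scale acquisition: 250 Hz sampling, 100 Hz lowpass (1-50 Hz intact)."""
    return SimulationParams(sampling_rate=250.0, lowpass_cutoff=100.0, seed=11)


@pytest.fixture
def quiet_params(fast_params):
    """Same, but without the slow stability drift (exact scaling checks)."""
    import dataclasses

    return dataclasses.replace(fast_params, drift_log_sd=0.0)


@pytest.fixture
def schedule():
    return SegmentSchedule()


@pytest.fixture
def drug_recording(fast_params, schedule):
    """15-min control + 30-min drug epoch at constant plateau gain 0.25."""
    tl = ConditionTimeline([("control", 0, 15), ("abeta_30nM", 15, 45)])
    model = AttenuationModel({"abeta_30nM": 0.25}, onset_halftime_min=0.0, onset_delay_min=0.0)
    env = build_gain_envelope(tl, model, 8)
    return simulate_recording(fast_params, env, 45, timeline=tl)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
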