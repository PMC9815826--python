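import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from sgcoflux import synthetic as sy  # noqa: E402


@pytest.fixture(scope="session")
def short_lvp():
    """5-minute, 1 kHz LVP trace shared across tests."""
    return sy.generate_lvp(80.0, 300.0, 1000.0, seed=11)


@pytest.fixture(scope="session")
def locked_trains(short_lvp):
    """Strongly phase-locked 4-channel trains on the shared LVP."""
    cfg = sy.CohortConfig(
        n_channels=4,
        session_duration=300.0,
        kappa_mean=2.0,
        kappa_drift_sd=0.0,
        event_rate_true=0.0,
        render_voltage=False,
    )
    trains, truth = sy.generate_spike_trains(short_lvp, cfg, seed=21)
    return trains, truth
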