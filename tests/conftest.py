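import pytest
from hypothesis import HealthCheck, settings

import skifuse as sf
from skifuse.synthgen import generate_session

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

MINI_PROTOCOL_CONFIG = {
    "laps": 3,
    "lap_duration_s": 60,
    "downhill_display_speed_li_kmh": 30.0,
    "downhill_display_speed_hi_kmh": 35.0,
    "segments": [
        {"incline_pct": 5.0, "speed_li_kmh": 15.0, "speed_hi_kmh": 20.0, "duration_s": 20},
        {"incline_pct": 2.0, "speed_li_kmh": 16.0, "speed_hi_kmh": 21.0, "duration_s": 15},
        {"incline_pct": 12.0, "speed_li_kmh": 10.8, "speed_hi_kmh": 14.2, "duration_s": 15},
        {"incline_pct": -10.0, "speed_li_kmh": 20.0, "speed_hi_kmh": 20.0, "duration_s": 10},
    ],
}


@pytest.fixture(scope="session")
def protocol():
    return sf.default_protocol()


@pytest.fixture(scope="session")
def mini_protocol():
    """A shortened 3 x 60 s session with the same terrain structure, used
    where the full 21-min session would only cost time."""
    return sf.build_protocol(MINI_PROTOCOL_CONFIG)


@pytest.fixture(scope="session")
def li_session(protocol):
    """Full low-intensity synthetic session, all streams."""
    return generate_session(protocol, "LI", seed=3)


@pytest.fixture(scope="session")
def li_analysis(li_session):
    return sf.analyze_session(li_session)


@pytest.fixture(scope="session")
def mini_chest_session(mini_protocol):
    return generate_session(mini_protocol, "LI", seed=11, include={"chest"})
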