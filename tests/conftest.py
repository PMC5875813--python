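import numpy as np
import pytest

from ergo import synthetic_data as sd


def noiseless_effects(**overrides) -> sd.ConditionEffects:
    """All noise and session-variability terms zeroed (BFR shifts kept
    unless overridden)."""
    base = dict(
        noise_vo2=0.0, noise_la=0.0, noise_hr=0.0, noise_ve=0.0,
        session_sd_vo2=0.0, session_sd_a1=0.0, session_sd_tau1=0.0,
        session_sd_hr=0.0, session_sd_ve=0.0, session_sd_la=0.0,
    )
    base.update(overrides)
    return sd.ConditionEffects(**base)


SHORT = sd.Durations(rest_s=180.0, exercise_s=360.0, recovery_s=300.0)


@pytest.fixture(scope="session")
def subject():
    return sd.make_population(1, seed=3)[0]


@pytest.fixture(scope="session")
def noiseless_session(subject):
    """Zero-noise LIE session with its ground truth (full durations)."""
    return sd.simulate_breath_series(
        subject, noiseless_effects(), "LIE", seed=5, return_truth=True
    )


@pytest.fixture(scope="session")
def short_durations():
    return SHORT
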