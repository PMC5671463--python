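import numpy as np
import pytest

from sprintnirs import SEA_LEVEL, Protocol, SynthParams, generate_session


def noiseless_params(**overrides) -> SynthParams:
    """Params with every stochastic term switched off and a fixed sprint
    count, so generator output follows the closed-form waveform exactly."""
    defaults = dict(
        seed=42,
        noise_sd=0.0,
        pedal_amp=0.0,
        drift_per_min=0.0,
        subject_sd=0.0,
        power_noise_w=0.0,
        n_sprints_mean=10.0,
        n_sprints_sd=0.0,
        amp_scale=1.0,
        include_cerebral=False,
    )
    defaults.update(overrides)
    return SynthParams(**defaults)


@pytest.fixture(scope="session")
def protocol() -> Protocol:
    return Protocol()


@pytest.fixture(scope="session")
def noiseless_session():
    """A 10-sprint sea-level session with no noise, drift or artifacts."""
    return generate_session(noiseless_params(), 0, SEA_LEVEL)


@pytest.fixture(scope="session")
def noisy_session():
    """Default-noise session (noise_sd = 10% of the muscle HHb amplitude)."""
    params = SynthParams(
        seed=7, n_sprints_mean=12.0, n_sprints_sd=0.0, include_cerebral=False
    )
    return generate_session(params, 0, SEA_LEVEL)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2017)
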