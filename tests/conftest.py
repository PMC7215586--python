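import pytest
from hypothesis import HealthCheck, settings

from ephysync.synth import SynthSpec, generate

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_bundle():
    """20 s synthetic recording at the default SNR of 10."""
    return generate(SynthSpec(duration=20.0, seed=123))


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Same seed and duration but zero noise: identical spike times."""
    return generate(SynthSpec(duration=20.0, noise_sd=0.0, seed=123))
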