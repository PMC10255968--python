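import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from ethylene_kinetics import generate_cycle
from ethylene_kinetics.datasets import load_avocado_hardness
from ethylene_kinetics.signal_model import demo_cycle_config

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_cycle():
    """Noise-free reference cycle: baseline 0, plateau 20.15, max 20.4 ppm,
    70% response crossing 25 s after gas entry."""
    return generate_cycle(demo_cycle_config())


@pytest.fixture(scope="session")
def noisy_cycle():
    cfg = dataclasses.replace(demo_cycle_config(), noise_sd=0.15, seed=7)
    return generate_cycle(cfg)


@pytest.fixture(scope="session")
def hardness_table():
    return load_avocado_hardness()
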