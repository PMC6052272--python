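import pytest
from hypothesis import settings

from n15mats import IncubationScenario

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

NO_NOISE = {"ar": 0.0, "excess15n": 0.0}


@pytest.fixture
def noiseless_scenario() -> IncubationScenario:
    """A leak-free, noise-free incubation where recovery must be exact."""
    return IncubationScenario(
        seed=11,
        leak_constant_per_h=0.0,
        noise_sd=dict(NO_NOISE),
        conversion_efficiency=1.0,
    )


@pytest.fixture
def leaky_scenario() -> IncubationScenario:
    """Noise-free incubation with a wall leak and no post-destruction
    production: the setting in which the argon correction is exact."""
    return IncubationScenario(
        seed=12,
        leak_constant_per_h=0.02,
        epibiont_denitrification_rate=0.0,
        epibiont_dnra_rate=0.0,
        noise_sd=dict(NO_NOISE),
    )
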