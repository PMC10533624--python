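import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from eq5dsim import ScenarioConfig, Tariff, TariffTerm, simulate_trial  # noqa: E402


@pytest.fixture(scope="session")
def fixture_tariff_3l() -> Tariff:
    """Small synthetic 3L tariff with a constant, main effects and an
    any-level-3 term; state 21232 scores 0.49 by hand summation."""
    return Tariff(
        country="FX",
        version="3L",
        terms=[
            TariffTerm("any_level_ge", 0.07, level=2),
            TariffTerm("level_dummy", 0.05, dimension="MO", level=2),
            TariffTerm("level_dummy", 0.12, dimension="MO", level=3),
            TariffTerm("level_dummy", 0.04, dimension="SC", level=2),
            TariffTerm("level_dummy", 0.09, dimension="SC", level=3),
            TariffTerm("level_dummy", 0.03, dimension="UA", level=2),
            TariffTerm("level_dummy", 0.08, dimension="UA", level=3),
            TariffTerm("level_dummy", 0.06, dimension="PD", level=2),
            TariffTerm("level_dummy", 0.20, dimension="PD", level=3),
            TariffTerm("level_dummy", 0.06, dimension="AD", level=2),
            TariffTerm("level_dummy", 0.15, dimension="AD", level=3),
            TariffTerm("any_level_ge", 0.10, level=3),
        ],
        notes="synthetic test fixture",
    )


@pytest.fixture(scope="session")
def small_trial():
    """One simulated trial (n = 150/arm) reused across analysis tests."""
    config = ScenarioConfig(
        condition="low_back_pain", severity="moderate", effect_size="medium", seed=11
    )
    return simulate_trial(config, "3L")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
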