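import numpy as np
import pandas as pd
import pytest

from enviromets.config import SimulationConfig, WeatherArchetype


def small_archetypes(noise_sd: float = 1.5) -> dict[str, WeatherArchetype]:
    """Two well-separated archetypes for fast delineation tests."""
    return {
        "A": WeatherArchetype(latitude=32.0, tmean_base=24.0, trange=8.0,
                              tdew_depression=2.0, precip_mean=5.0,
                              noise_sd=noise_sd),
        "B": WeatherArchetype(latitude=37.0, tmean_base=17.0, trange=12.0,
                              tdew_depression=7.0, precip_mean=2.0,
                              noise_sd=noise_sd),
    }


@pytest.fixture
def small_config() -> SimulationConfig:
    """Compact trial: 6 genotypes, 4 locations in 2 archetypes, 2 years."""
    return SimulationConfig(
        n_genotypes=6, n_locations=4, n_years=2, n_blocks=2,
        me_archetypes={"L01": "A", "L02": "A", "L03": "B", "L04": "B"},
        archetypes=small_archetypes(),
        grand_means={"GY": 11.0, "PH": 260.0},
        variance_components={
            "GY": {"G": 0.5, "GM": 0.1, "GY": 0.05, "MY": 0.1, "GMY": 0.2,
                   "REP": 0.3, "residual": 1.0},
            "PH": {"G": 150.0, "M": 50.0, "GMY": 80.0, "REP": 100.0,
                   "residual": 250.0},
        },
        rng_seed=11,
        n_weather_years=3,
        weather_first_year=2016,
    )


@pytest.fixture
def small_trial(small_config) -> pd.DataFrame:
    from enviromets.synthetic import simulate_trial

    return simulate_trial(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
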