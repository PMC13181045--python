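import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from divetherm import (
    Bbox,
    ModelProductParams,
    OceanTruthParams,
    TurtleSimParams,
    date_range,
    generate_model_field,
    simulate_turtle_dives,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ocean():
    """Noise-relevant truth parameters shared across tests."""
    return OceanTruthParams()


@pytest.fixture(scope="session")
def bbox():
    return Bbox(lat_min=41.0, lat_max=41.5, lon_min=17.0, lon_max=17.5)


@pytest.fixture(scope="session")
def dates():
    return date_range(dt.date(2021, 1, 1), dt.date(2021, 12, 31))


@pytest.fixture(scope="session")
def clean_dives(ocean, bbox, dates):
    """Noise-free dives from two tags, every LQ class exercised."""
    params = TurtleSimParams(n_turtles=2, n_dives_per_turtle=20, temp_noise_sd=0.0, seed=11)
    return simulate_turtle_dives(params, ocean, dates, bbox)


@pytest.fixture(scope="session")
def perfect_field(ocean, bbox, dates):
    """Model product identical to truth (no bias, no noise)."""
    product = ModelProductParams(noise_sd=0.0, bias_profile=0.0)
    return generate_model_field(ocean, product, dates, bbox)
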