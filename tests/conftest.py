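import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from phytoalloc import DesignSpec, default_params, default_ratios

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """The packaged synthetic default organism."""
    return default_params()


@pytest.fixture(scope="session")
def ratios():
    return default_ratios()


@pytest.fixture(scope="session")
def small_design():
    """A reduced chemostat design for fast generator/fitting tests."""
    return DesignSpec(
        light_levels=(25.0, 62.0, 144.0),
        dilution_grid=tuple(round(0.1 * k, 1) for k in range(1, 11)),
        seed=42,
    )


def random_conditions(rng: np.random.Generator, params, ratios, n: int):
    """Draw n random feasible (I, D, n_in, p_in) chemostat conditions."""
    from phytoalloc import mu_max

    lights = rng.uniform(10.0, 300.0, size=n)
    out = []
    for i in lights:
        mx = mu_max(i, params, ratios)
        d = rng.uniform(0.05, 0.95) * mx
        n_in = 0.8 * rng.lognormal(0.0, 0.5)
        p_in = 0.03 * rng.lognormal(0.0, 0.7)
        out.append((i, d, n_in, p_in))
    return out
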