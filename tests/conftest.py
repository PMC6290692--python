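import numpy as np
import pytest

from lifedisp.lifetable import build_lifetable
from lifedisp.synthetic import (
    CEE_MALE_PARAMS,
    HazardParams,
    flat_schedule,
    make_surface,
    single_year_grid,
)


def random_hazard(rng: np.random.Generator) -> HazardParams:
    """Draw a plausible adult-senescent hazard (Siler + young-adult hump)."""
    return HazardParams(
        a1=10 ** rng.uniform(-2.2, -1.3),
        b1=rng.uniform(0.8, 1.5),
        c=10 ** rng.uniform(-4.0, -3.2),
        a2=10 ** rng.uniform(-5.2, -4.4),
        b2=rng.uniform(0.095, 0.120),
        h=10 ** rng.uniform(-3.3, -2.6),
        kappa=rng.uniform(22.0, 35.0),
        sigma=rng.uniform(8.0, 16.0),
    )


def lifetable_from_params(params: HazardParams):
    surf = make_surface(params, flat_schedule(years=[2000]), years=[2000])
    return surf.lifetable(2000)


def random_lifetables(n: int, seed: int = 20240917):
    rng = np.random.default_rng(seed)
    return [lifetable_from_params(random_hazard(rng)) for _ in range(n)]


@pytest.fixture(scope="session")
def cee_lifetable():
    """Baseline CEE-male-like period life table (single-year grid, 110+)."""
    return lifetable_from_params(CEE_MALE_PARAMS)


@pytest.fixture(scope="session")
def cee_surface():
    return make_surface(CEE_MALE_PARAMS, flat_schedule())


@pytest.fixture(scope="session")
def constant_hazard_fine():
    """mu = 0.02 on a 0.1-year grid to age 400 (exponential lifetimes)."""
    ages = np.round(np.arange(0.0, 400.01, 0.1), 10)
    mx = np.full(len(ages), 0.02)
    return build_lifetable(mx, ages, a0_rule="midpoint")


@pytest.fixture(scope="session")
def schedule_bank():
    """A bank of randomized synthetic schedules for identity/property tests."""
    return random_lifetables(20)
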