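import math

import numpy as np
import pytest

from permeq import (
    FixtureSpec,
    FourierRate,
    build_sis,
    build_tasep,
    random_periodic_system,
)

TWO_PI = 2.0 * math.pi


def tasep3_rates():
    """Worked TASEP forcing: alpha(t)=1+cos t, beta(t)=1+cos(t+pi), h1=1/2, h2=1/4."""
    alpha = FourierRate(c0=1.0, terms=((1.0, 1.0, 0.0),), period=TWO_PI)
    beta = FourierRate(c0=1.0, terms=((1.0, 1.0, math.pi),), period=TWO_PI)
    return alpha, beta, [0.5, 0.25]


def sis3_rates():
    """Worked SIS forcing: a=1, b(t)=3+3cos(t+0.5), c(t)=2-2sin(t+0.75)."""
    a = 1.0
    b = FourierRate(c0=3.0, terms=((3.0, 1.0, 0.5),), period=TWO_PI)
    # 2 - 2 sin(t + 0.75) = 2 + (-2) cos(t + 0.75 - pi/2)
    c = FourierRate(c0=2.0, terms=((-2.0, 1.0, 0.75 - math.pi / 2.0),), period=TWO_PI)
    return a, b, c


@pytest.fixture(scope="session")
def tasep3():
    alpha, beta, hs = tasep3_rates()
    return build_tasep(3, alpha, beta, hs, period=TWO_PI)


@pytest.fixture(scope="session")
def tasep2():
    alpha, beta, hs = tasep3_rates()
    return build_tasep(2, alpha, beta, hs[:1], period=TWO_PI)


@pytest.fixture(scope="session")
def sis3():
    a, b, c = sis3_rates()
    return build_sis(3, a, b, c, period=TWO_PI)


@pytest.fixture(scope="session")
def random_fixtures():
    """20 seeded random periodic master systems of mixed size/sparsity."""
    systems = []
    for seed in range(20):
        spec = FixtureSpec(
            n_states=2 + seed % 4,
            period=1.0 + 0.5 * (seed % 3),
            sparsity=1.0 if seed % 2 else 0.7,
            fourier_order=1 + seed % 3,
            seed=seed,
        )
        systems.append(random_periodic_system(spec))
    return systems


def random_two_state_rates(rng, period=TWO_PI):
    """One seeded pair of non-negative periodic Fourier rates."""
    def draw():
        c0 = rng.uniform(0.3, 1.5)
        amp = rng.uniform(0.0, c0)  # c0 >= amp keeps the rate non-negative
        phase = rng.uniform(0.0, TWO_PI)
        harmonic = rng.integers(1, 3)
        return FourierRate(c0=c0, terms=((amp, harmonic * TWO_PI / period, phase),),
                           period=period)

    return draw(), draw()
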