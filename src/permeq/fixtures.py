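"""Seeded generator of random periodic master systems.

Used by the property-based test suite: each fixture is a master equation
whose rates are clipped truncated Fourier series,

    p_ij(t) = max(0, c0 + sum_m a_m cos(2 pi m t / T + phi_m)),

drawn from a seeded stream.  Clipping at zero keeps the rates continuous
(the regularity the theory needs in ``t``) though not smooth at touch
points; rates here are time-only, so differentiability in ``x`` is
trivial.  The same seed always reproduces the same system.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from ._errors import ConfigurationError
from .rates import FourierRate
from .system import MasterSystem

__all__ = ["FixtureSpec", "random_periodic_system"]


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a random periodic master system.

    ``sparsity`` is the fraction of ordered index pairs carrying a nonzero
    rate; ``fourier_order`` the number of cosine harmonics per rate;
    amplitudes (and offsets) are drawn uniformly from ``amplitude_range``.
    """

    n_states: int = 3
    period: float = 1.0
    sparsity: float = 1.0
    fourier_order: int = 2
    amplitude_range: Tuple[float, float] = (0.0, 1.0)
    seed: int = 0


def random_periodic_system(spec: FixtureSpec) -> MasterSystem:
    """Draw a master system from the seeded stream described by ``spec``.

    Every rate is non-negative and T-periodic by construction, so the
    result always passes :func:`permeq.system.validate_system`.
    """
    if spec.n_states < 2:
        raise ConfigurationError("need n_states >= 2")
    if not 0.0 < spec.sparsity <= 1.0:
        raise ConfigurationError("sparsity must be in (0, 1]")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.amplitude_range
    omega0 = 2.0 * np.pi / spec.period
    rates = {}
    for i in range(spec.n_states):
        for j in range(spec.n_states):
            if i == j:
                continue
            if rng.uniform() > spec.sparsity:
                continue
            c0 = rng.uniform(lo, hi)
            terms = tuple(
                (rng.uniform(lo, hi), (m + 1) * omega0, rng.uniform(0.0, 2.0 * np.pi))
                for m in range(spec.fourier_order)
            )
            has_terms = any(a != 0.0 for a, _, _ in terms)
            rates[(i, j)] = FourierRate(
                c0=c0,
                terms=terms if has_terms else (),
                period=spec.period if has_terms else None,
                clip=True,
            )
    return MasterSystem(spec.n_states, rates, spec.period,
                        label=f"fixture(seed={spec.seed})")
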