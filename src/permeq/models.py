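"""Concrete master-equation models.

* **TASEP** — the totally asymmetric simple exclusion process on a chain of
  ``n`` sites.  Particles enter at site 1 with rate ``alpha(t)``, hop from
  site ``k`` to ``k+1`` with rate ``h_k(t)`` when the target site is free,
  and exit from site ``n`` with rate ``beta(t)``.  The configuration space
  is ``{0, 1}^n`` (``N = 2^n`` states) listed in binary-counting order with
  site 1 as the most significant bit: ``C_1 = (0, ..., 0)`` up to
  ``C_N = (1, ..., 1)``.

* **Stochastic SIS** — a birth-death chain on the number of infected
  individuals ``n = 0..N`` in a population of size ``N``.  Infection occurs
  by contact (rate ``a(t)``) or external import (rate ``c(t)``), recovery
  at rate ``b(t)`` per infected; the up-rate from state ``n`` is
  ``(n*a + c) * (1 - n/N)`` and the down-rate is ``n*b``.

* **Two-state system** — the ``N = 2`` master equation, which admits a
  closed-form solution and an explicit formula for its unique periodic
  point; this is the package's exact oracle.

* **Migration model** — mean-field population flow between ``K``
  settlements with state-dependent rates ``p_ij = exp((x_j - x_i) k_ij)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from ._errors import (
    CapacityError,
    ConfigurationError,
    DegenerateSystemError,
    NumericalError,
)
from .rates import CallableRate, MigrationRate, RateFunction, as_rate
from .system import MasterSystem

__all__ = [
    "TASEPModel",
    "SISModel",
    "TwoStateSolution",
    "build_tasep",
    "build_sis",
    "build_two_state",
    "build_migration",
    "enumerate_configurations",
    "two_state_closed_form",
    "two_state_periodic_point",
    "two_state_solution",
    "occupation_density",
    "expected_infected",
]

#: default cap on the TASEP chain length (N = 2^12 = 4096 states)
TASEP_MAX_SITES = 12


# ---------------------------------------------------------------------------
# TASEP
# ---------------------------------------------------------------------------

def enumerate_configurations(n: int) -> List[Tuple[int, ...]]:
    """All ``2^n`` occupation patterns of an ``n``-site chain.

    Binary-counting order with site 1 as the most significant bit, so the
    list starts at the empty chain and ends at the full chain.
    """
    if n < 1:
        raise ConfigurationError(f"chain length must be >= 1, got {n}")
    return list(itertools.product((0, 1), repeat=n))


@dataclass
class TASEPModel:
    """A TASEP chain and its induced master-equation system."""

    n_sites: int
    entry_rate: RateFunction
    exit_rate: RateFunction
    hop_rates: List[RateFunction]
    configurations: List[Tuple[int, ...]]
    system: MasterSystem


def _require_time_only(name: str, rate: RateFunction) -> RateFunction:
    if rate.depends_on_state:
        raise ConfigurationError(f"TASEP rate {name} must not depend on the state")
    return rate


def build_tasep(
    n: int,
    alpha,
    beta,
    h_list: Sequence,
    period: Optional[float] = None,
    max_sites: int = TASEP_MAX_SITES,
) -> TASEPModel:
    """Build the TASEP master equation on ``2^n`` configurations.

    Transitions: particle entry at site 1 (rate ``alpha``, requires site 1
    free), exit at site ``n`` (rate ``beta``, requires site ``n``
    occupied), and hops ``k -> k+1`` (rate ``h_k``, requires site ``k``
    occupied and ``k+1`` free).  All rates are functions of time only.
    """
    if n < 1:
        raise ConfigurationError(f"chain length must be >= 1, got {n}")
    if n > max_sites:
        raise CapacityError(
            f"TASEP with n={n} sites needs 2^{n} states; cap is n <= {max_sites}"
        )
    alpha = _require_time_only("alpha", as_rate(alpha))
    beta = _require_time_only("beta", as_rate(beta))
    hops = [as_rate(h) for h in h_list]
    if len(hops) != n - 1:
        raise ConfigurationError(f"expected {n - 1} hop rates for n={n}, got {len(hops)}")
    for k, h in enumerate(hops):
        _require_time_only(f"h{k + 1}", h)

    configs = enumerate_configurations(n)
    index = {c: i for i, c in enumerate(configs)}
    rates = {}
    for i, c in enumerate(configs):
        if c[0] == 0:  # entry at site 1
            target = (1,) + c[1:]
            rates[(i, index[target])] = alpha
        if c[-1] == 1:  # exit from site n
            target = c[:-1] + (0,)
            rates[(i, index[target])] = beta
        for k in range(n - 1):  # hop k -> k+1 under exclusion
            if c[k] == 1 and c[k + 1] == 0:
                target = c[:k] + (0, 1) + c[k + 2:]
                rates[(i, index[target])] = hops[k]

    if period is None:
        declared = [r.period for r in [alpha, beta, *hops] if r.period is not None]
        period = declared[0] if declared else 1.0
    system = MasterSystem(2 ** n, rates, period, label=f"tasep(n={n})")
    return TASEPModel(n, alpha, beta, hops, configs, system)


def occupation_density(model: TASEPModel, x) -> np.ndarray:
    """Site occupation probabilities ``<tau_k> = sum_i C_{i,k} x_i``."""
    x = np.asarray(x, dtype=float)
    if x.shape != (len(model.configurations),):
        raise ConfigurationError(
            f"state vector has shape {x.shape}, expected ({len(model.configurations)},)"
        )
    C = np.asarray(model.configurations, dtype=float)  # (2^n, n)
    return C.T @ x


# ---------------------------------------------------------------------------
# Stochastic SIS
# ---------------------------------------------------------------------------

@dataclass
class SISModel:
    """A stochastic SIS birth-death chain on infected counts ``0..N``."""

    population: int
    contact_rate: RateFunction
    recovery_rate: RateFunction
    import_rate: RateFunction
    system: MasterSystem

    @property
    def occupancy_factors(self) -> np.ndarray:
        """``q_i = 1 - i/N`` for ``i = 0..N``."""
        N = self.population
        return 1.0 - np.arange(N + 1) / N


def _sis_up_rate(n: int, a: RateFunction, c: RateFunction, q: float, T: float):
    fn = lambda t: (n * a(t, None) + c(t, None)) * q
    dep = a.depends_on_time or c.depends_on_time
    return CallableRate(fn=fn, period=T if dep else None, depends_on_time=dep,
                        label=f"({n}a+c)q{n}")


def _sis_down_rate(n: int, b: RateFunction, T: float):
    fn = lambda t: n * b(t, None)
    dep = b.depends_on_time
    return CallableRate(fn=fn, period=T if dep else None, depends_on_time=dep,
                        label=f"{n}b")


def build_sis(N: int, a, b, c, period: Optional[float] = None) -> SISModel:
    """Build the stochastic SIS master equation on ``N + 1`` states.

    State ``n`` is the number of infected individuals.  The generator is
    tridiagonal: up-transitions ``n -> n+1`` at rate ``(n*a + c) q_n`` with
    ``q_n = 1 - n/N``, down-transitions ``n -> n-1`` at rate ``n*b``.
    """
    if N < 1:
        raise ConfigurationError(f"population must be >= 1, got {N}")
    a, b, c = as_rate(a), as_rate(b), as_rate(c)
    for name, r in (("a", a), ("b", b), ("c", c)):
        if r.depends_on_state:
            raise ConfigurationError(f"SIS rate {name} must not depend on the state")
    if period is None:
        declared = [r.period for r in (a, b, c) if r.period is not None]
        period = declared[0] if declared else 1.0

    rates = {}
    for n in range(N + 1):
        q = 1.0 - n / N
        if n < N:
            rates[(n, n + 1)] = _sis_up_rate(n, a, c, q, period)
        if n > 0:
            rates[(n, n - 1)] = _sis_down_rate(n, b, period)
    system = MasterSystem(N + 1, rates, period, label=f"sis(N={N})")
    return SISModel(N, a, b, c, system)


def expected_infected(model: SISModel, x) -> float:
    """Mean infected count ``sum_n n * x_n`` of a distribution ``x``."""
    x = np.asarray(x, dtype=float)
    N = model.population
    if x.shape != (N + 1,):
        raise ConfigurationError(f"state vector has shape {x.shape}, expected ({N + 1},)")
    return float(np.arange(N + 1) @ x)


# ---------------------------------------------------------------------------
# Two-state system and its closed form
# ---------------------------------------------------------------------------

def build_two_state(p12, p21, period: Optional[float] = None) -> MasterSystem:
    """The ``N = 2`` master equation with time-only rates ``p12, p21``."""
    p12, p21 = as_rate(p12), as_rate(p21)
    for name, r in (("p12", p12), ("p21", p21)):
        if r.depends_on_state:
            raise ConfigurationError(f"two-state rate {name} must not depend on the state")
    if period is None:
        declared = [r.period for r in (p12, p21) if r.period is not None]
        period = declared[0] if declared else 1.0
    return MasterSystem(2, {(0, 1): p12, (1, 0): p21}, period, label="two_state")


def _two_state_quadrature(p12: RateFunction, p21: RateFunction, t: float,
                          rtol: float = 1e-12, atol: float = 1e-14):
    """Compute ``E(t) = int_0^t (p12 + p21)`` and the quadrature
    ``c(t) = int_0^t p21(tau) exp(E(tau)) dtau`` by one auxiliary IVP.

    Solving the pair as an initial-value problem avoids nested quadrature:
    ``E' = p12 + p21`` and ``c' = p21 * exp(E)``.
    """
    if t == 0.0:
        return 0.0, 0.0

    def rhs(s, y):
        s12, s21 = p12(s, None), p21(s, None)
        return [s12 + s21, s21 * math.exp(y[0])]

    sol = solve_ivp(rhs, (0.0, t), [0.0, 0.0], rtol=rtol, atol=atol,
                    method="DOP853", dense_output=False)
    if not sol.success:
        raise NumericalError(f"two-state quadrature failed: {sol.message}")
    return float(sol.y[0, -1]), float(sol.y[1, -1])


def two_state_closed_form(p12, p21, x1_0: float, t: float) -> np.ndarray:
    """Exact solution of the two-state master equation.

    ``x1(t) = exp(-int_0^t (p12 + p21)) * (x1(0) + c(t))`` with
    ``c(t) = int_0^t p21(tau) exp(int_0^tau (p12 + p21) ds) dtau`` and
    ``x2 = 1 - x1``.
    """
    if not 0.0 <= x1_0 <= 1.0:
        raise ConfigurationError(f"x1(0) must be in [0, 1], got {x1_0}")
    p12, p21 = as_rate(p12), as_rate(p21)
    E, c = _two_state_quadrature(p12, p21, t)
    x1 = math.exp(-E) * (x1_0 + c)
    return np.array([x1, 1.0 - x1])


def two_state_periodic_point(p12, p21, T: float) -> float:
    """Initial value ``x1(0)`` of the unique T-periodic two-state solution.

    ``x1(0) = exp(-E(T)) c(T) / (1 - exp(-E(T)))``, defined whenever the
    total rate ``p12 + p21`` is positive somewhere in the period.  If the
    rates vanish identically the system is degenerate — every point is
    periodic — and :class:`DegenerateSystemError` is raised.
    """
    p12, p21 = as_rate(p12), as_rate(p21)
    E, c = _two_state_quadrature(p12, p21, T)
    if E <= 1e-14:
        raise DegenerateSystemError(
            "p12 + p21 vanishes identically over the period: every point is periodic"
        )
    x1 = math.exp(-E) * c / (1.0 - math.exp(-E))
    # analytically in [0,1]; guard roundoff at the endpoints
    return float(min(1.0, max(0.0, x1)))


@dataclass
class TwoStateSolution:
    """Closed-form solution bundle for one two-state system."""

    p12: RateFunction
    p21: RateFunction
    period: float
    periodic_point: float

    def x1_of_t(self, x1_0: float, t: float) -> float:
        return two_state_closed_form(self.p12, self.p21, x1_0, t)[0]

    def c_of_t(self, t: float) -> float:
        return _two_state_quadrature(self.p12, self.p21, t)[1]


def two_state_solution(p12, p21, T: float) -> TwoStateSolution:
    """Bundle the closed form and the periodic point of a two-state system."""
    p12, p21 = as_rate(p12), as_rate(p21)
    return TwoStateSolution(p12, p21, T, two_state_periodic_point(p12, p21, T))


# ---------------------------------------------------------------------------
# Migration model
# ---------------------------------------------------------------------------

def build_migration(K: int, k_params, period: Optional[float] = None) -> MasterSystem:
    """Mean-field migration between ``K`` settlements.

    ``p_ij(t, x) = exp((x_j - x_i) * k_ij(t))`` with ``k_ij > 0``; the rate
    of moving ``i -> j`` grows with the density surplus of the destination.
    ``k_params`` is a scalar (shared by all pairs), a ``K x K`` array, or a
    dict ``(i, j) -> k`` of positive constants or periodic time functions.
    Analytic state derivatives are attached so the cooperativity check can
    run in analytic mode.
    """
    if K < 2:
        raise ConfigurationError(f"need at least 2 settlements, got {K}")

    def k_for(i, j):
        if np.isscalar(k_params):
            return k_params
        if isinstance(k_params, dict):
            return k_params[(i, j)]
        return np.asarray(k_params)[i, j]

    rates = {}
    any_time = False
    for i in range(K):
        for j in range(K):
            if i == j:
                continue
            r = MigrationRate(i, j, k_for(i, j), period=period)
            any_time = any_time or r.depends_on_time
            rates[(i, j)] = r
    if period is None:
        declared = [r.period for r in rates.values() if r.period is not None]
        period = declared[0] if declared else 1.0
    return MasterSystem(K, rates, period, label=f"migration(K={K})")
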