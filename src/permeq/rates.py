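"""Transition-rate functions.

A master equation on ``N`` configurations is specified by non-negative
transition rates ``p_ij(t, x)`` — the probability flux per unit time from
configuration ``i`` to configuration ``j`` — that are jointly periodic in
time with a common period ``T``.  Rates may additionally depend on the
probability vector ``x`` itself (a mean-field coupling), in which case the
master equation is nonlinear.

This module defines the small algebra of rate functions the rest of the
package consumes:

* :class:`ConstantRate` — a constant (periodic with every period);
* :class:`FourierRate` — a truncated Fourier cosine series, optionally
  clipped at zero to stay non-negative;
* :class:`CallableRate` — an arbitrary time-only callable with a declared
  period (used internally to compose model rates);
* :class:`MigrationRate` — the state-dependent population-migration rate
  ``p_ij = exp((x_j - x_i) * k_ij(t))`` with its analytic state derivative.

Every rate exposes ``__call__(t, x) -> float``, a ``period`` (``None``
means "any period", i.e. time-invariant), and the flags
``depends_on_state`` / ``depends_on_time``.  State-dependent rates that
support analytic Jacobians also expose
``state_derivative(t, x, j) -> d p / d x_j``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "RateFunction",
    "ConstantRate",
    "FourierRate",
    "CallableRate",
    "MigrationRate",
    "as_rate",
]


class RateFunction:
    """Abstract non-negative transition rate ``p(t, x)``.

    Attributes
    ----------
    period : float or None
        Common period ``T``; ``None`` for time-invariant rates, which are
        periodic with every period.
    depends_on_state : bool
        Whether the rate reads the state vector ``x``.
    depends_on_time : bool
        Whether the rate varies with ``t``.
    """

    period: Optional[float] = None
    depends_on_state: bool = False
    depends_on_time: bool = False

    def __call__(self, t: float, x: np.ndarray) -> float:  # pragma: no cover
        raise NotImplementedError

    def state_derivative(self, t: float, x: np.ndarray, j: int) -> float:
        """Partial derivative ``d p(t, x) / d x_j`` (zero if state-free)."""
        if not self.depends_on_state:
            return 0.0
        raise NotImplementedError(
            f"{type(self).__name__} does not provide an analytic state derivative"
        )

    @property
    def has_state_derivative(self) -> bool:
        if not self.depends_on_state:
            return True
        return type(self).state_derivative is not RateFunction.state_derivative


@dataclass(frozen=True)
class ConstantRate(RateFunction):
    """A constant rate ``p(t, x) = value`` (units: 1/time)."""

    value: float = 0.0

    def __post_init__(self):
        if self.value < 0:
            raise ValueError(f"constant rate must be non-negative, got {self.value}")

    period = None
    depends_on_state = False
    depends_on_time = False

    def __call__(self, t: float, x: np.ndarray) -> float:
        return self.value


@dataclass(frozen=True)
class FourierRate(RateFunction):
    """Truncated Fourier series ``c0 + sum_m a_m cos(w_m t + phi_m)``.

    Parameters
    ----------
    c0 : float
        Constant offset.
    terms : sequence of (amplitude, angular_frequency, phase)
        Cosine terms.  Negative amplitudes are allowed; they are equivalent
        to a phase shift of pi.
    period : float, optional
        Declared common period.  If omitted it is inferred as ``2*pi/w`` of
        the smallest nonzero angular frequency; all frequencies must then be
        integer multiples of that fundamental.
    clip : bool
        If true, the series is clipped at zero: ``max(0, series)``.  This
        keeps randomly drawn rates non-negative while preserving continuity.
    """

    c0: float = 0.0
    terms: tuple = ()
    period: Optional[float] = None
    clip: bool = False

    def __post_init__(self):
        terms = tuple((float(a), float(w), float(p)) for a, w, p in self.terms)
        object.__setattr__(self, "terms", terms)
        freqs = [w for _, w, _ in terms if w != 0.0]
        if self.period is None and freqs:
            base = 2.0 * math.pi / min(abs(w) for w in freqs)
            object.__setattr__(self, "period", base)
        object.__setattr__(self, "depends_on_time", bool(freqs))
        if not freqs:
            object.__setattr__(self, "period", None)

    depends_on_state = False

    def __call__(self, t: float, x: np.ndarray = None) -> float:
        v = self.c0
        for a, w, p in self.terms:
            v += a * math.cos(w * t + p)
        return max(0.0, v) if self.clip else v


@dataclass(frozen=True)
class CallableRate(RateFunction):
    """Wrap an arbitrary time-only callable ``f(t)`` with a declared period."""

    fn: Callable[[float], float] = None
    period: Optional[float] = None
    depends_on_time: bool = True
    label: str = ""

    depends_on_state = False

    def __call__(self, t: float, x: np.ndarray = None) -> float:
        return self.fn(t)


class MigrationRate(RateFunction):
    """Mean-field migration rate ``p_ij(t, x) = exp((x_j - x_i) * k_ij(t))``.

    Models the flow of individuals from settlement ``i`` to settlement
    ``j``: the rate grows when the destination density exceeds the origin
    density (attraction to larger cities), scaled by ``k_ij > 0``.  ``k``
    may be a positive constant or a time-periodic positive function
    (seasonal migration).

    The analytic state derivative is
    ``d p_ij / d x_l = (delta_jl - delta_il) * k_ij(t) * p_ij(t, x)``.
    """

    depends_on_state = True

    def __init__(self, i: int, j: int, k, period: Optional[float] = None):
        self.i, self.j = i, j
        if callable(k):
            self.k = k
            self.period = period if period is not None else getattr(k, "period", None)
            self.depends_on_time = getattr(k, "depends_on_time", True)
        else:
            k = float(k)
            if k <= 0:
                raise ValueError(f"migration scale k must be positive, got {k}")
            self.k = lambda t: k
            self.period = None
            self.depends_on_time = False

    def _kval(self, t: float) -> float:
        k = self.k(t)
        if k <= 0:
            raise ValueError(f"migration scale k({t}) = {k} must be positive")
        return k

    def __call__(self, t: float, x: np.ndarray) -> float:
        return math.exp((x[self.j] - x[self.i]) * self._kval(t))

    def state_derivative(self, t: float, x: np.ndarray, l: int) -> float:
        if l != self.i and l != self.j:
            return 0.0
        sign = 1.0 if l == self.j else -1.0
        k = self._kval(t)
        return sign * k * math.exp((x[self.j] - x[self.i]) * k)


def as_rate(value) -> RateFunction:
    """Coerce a number or RateFunction into a RateFunction."""
    if isinstance(value, RateFunction):
        return value
    if isinstance(value, (int, float)):
        return ConstantRate(float(value))
    raise TypeError(f"cannot interpret {value!r} as a rate function")
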