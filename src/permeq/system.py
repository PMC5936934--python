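"""Master-equation systems and their generators.

The master equation on ``N`` configurations reads, in matrix form,

    dx/dt = A(t, x) x,

where the generator ``A`` has entries ``a_ij = p_ji(t, x)`` for ``i != j``
(probability flowing from configuration ``j`` into ``i``) and
``a_ii = -sum_{k != i} p_ik(t, x)`` (total outflow from ``i``).  By
construction ``A`` is Metzler (non-negative off-diagonal) and every column
sums to zero, which makes ``H(x) = sum_i x_i`` a first integral: the
probability simplex is invariant under the flow.

The Jacobian of the vector field ``f(t, x) = A(t, x) x`` splits as

    J(t, x) = A(t, x) + B(t, x),    b_ij = sum_k x_k * da_ik/dx_j,

with ``B = 0`` whenever no rate depends on the state.  This decomposition
is what the entrainment conditions in :mod:`permeq.conditions` inspect.

Configurations are indexed 0..N-1 internally and reported 1-based
(``C_1`` ... ``C_N``) in user-facing messages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from ._errors import ConfigurationError, RateValidationError
from .rates import RateFunction

__all__ = [
    "MasterSystem",
    "GeneratorMatrix",
    "JacobianResult",
    "ValidationReport",
    "build_generator",
    "vector_field",
    "jacobian",
    "validate_system",
    "sample_simplex",
]

#: above this state count the generator is assembled as a sparse matrix
SPARSE_THRESHOLD = 256


class MasterSystem:
    """``N`` configurations plus the full map of transition rates.

    Parameters
    ----------
    n_states : int
        Number of configurations ``N``.
    rates : dict[(int, int) -> RateFunction]
        Map from the ordered pair ``(i, j)``, ``i != j`` (0-based), to the
        rate ``p_ij`` of the transition ``i -> j``.  Absent pairs have rate
        zero.
    period : float
        Common period ``T`` of all time-dependent rates.
    label : str
        Free-text model label for reports.
    """

    def __init__(
        self,
        n_states: int,
        rates: Dict[Tuple[int, int], RateFunction],
        period: float,
        label: str = "",
    ):
        if n_states < 1:
            raise ConfigurationError(f"n_states must be >= 1, got {n_states}")
        if period <= 0:
            raise ConfigurationError(f"period must be positive, got {period}")
        self.n_states = int(n_states)
        self.period = float(period)
        self.label = label
        self.rates = dict(rates)
        for (i, j), r in self.rates.items():
            if i == j or not (0 <= i < n_states and 0 <= j < n_states):
                raise ConfigurationError(f"invalid transition pair ({i}, {j})")
            if r.period is not None and not np.isclose(r.period, period, rtol=1e-12):
                raise ConfigurationError(
                    f"rate p_{i + 1},{j + 1} declares period {r.period}, "
                    f"system declares {period}"
                )
        # flat structure arrays for fast generator assembly
        self._src = np.array([i for i, _ in self.rates], dtype=np.intp)
        self._dst = np.array([j for _, j in self.rates], dtype=np.intp)
        self._fns = list(self.rates.values())
        self.sparse = self.n_states > SPARSE_THRESHOLD

    # -- structural properties -------------------------------------------
    @property
    def depends_on_state(self) -> bool:
        return any(r.depends_on_state for r in self._fns)

    @property
    def depends_on_time(self) -> bool:
        return any(r.depends_on_time for r in self._fns)

    @property
    def has_analytic_derivatives(self) -> bool:
        return all(r.has_state_derivative for r in self._fns)

    # -- evaluation ------------------------------------------------------
    def rate_values(self, t: float, x: np.ndarray) -> np.ndarray:
        """Evaluate every stored rate at ``(t, x)``; raises on negatives."""
        vals = np.empty(len(self._fns))
        for m, fn in enumerate(self._fns):
            v = fn(t, x)
            if v < 0 or not np.isfinite(v):
                raise RateValidationError(int(self._src[m]), int(self._dst[m]), t, v)
            vals[m] = v
        return vals

    def generator(self, t: float, x: np.ndarray):
        """Assemble ``A(t, x)``; dense ndarray, or CSR for large ``N``."""
        n = self.n_states
        vals = self.rate_values(t, x)
        diag = np.zeros(n)
        np.add.at(diag, self._src, vals)
        if self.sparse:
            rows = np.concatenate([self._dst, np.arange(n)])
            cols = np.concatenate([self._src, np.arange(n)])
            data = np.concatenate([vals, -diag])
            return sp.csr_matrix((data, (rows, cols)), shape=(n, n))
        A = np.zeros((n, n))
        A[self._dst, self._src] += vals
        A[np.arange(n), np.arange(n)] = -diag
        return A

    def vector_field(self, t: float, x: np.ndarray) -> np.ndarray:
        return self.generator(t, x) @ np.asarray(x, dtype=float)

    def __repr__(self):
        return (
            f"MasterSystem(N={self.n_states}, n_rates={len(self.rates)}, "
            f"T={self.period}, label={self.label!r})"
        )


@dataclass
class GeneratorMatrix:
    """The generator ``A(t, x)`` frozen at one evaluation point."""

    entries: np.ndarray
    eval_time: float
    eval_state: np.ndarray

    def column_sum_defect(self) -> float:
        A = self.entries.toarray() if sp.issparse(self.entries) else self.entries
        return float(np.max(np.abs(A.sum(axis=0))))


@dataclass
class JacobianResult:
    """Decomposition ``J = A + B`` of the vector-field Jacobian."""

    A_part: GeneratorMatrix
    B_part: np.ndarray
    J: np.ndarray
    method: str


@dataclass
class ValidationReport:
    """Sampled check of rate non-negativity and joint periodicity."""

    passed: bool
    min_rate: float
    min_rate_at: Optional[Tuple[int, int, float]]  # (i, j, t), 0-based pair
    max_periodicity_violation: float
    n_time_samples: int
    n_state_samples: int
    seed: int
    failures: list = field(default_factory=list)


def _check_state(system: MasterSystem, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (system.n_states,):
        raise ConfigurationError(
            f"state vector has shape {x.shape}, expected ({system.n_states},)"
        )
    if np.any(x < -1e-12):
        raise ConfigurationError("state vector must lie in the non-negative orthant")
    return x


def build_generator(system: MasterSystem, t: float, x) -> GeneratorMatrix:
    """Evaluate the generator ``A(t, x)`` of the master equation.

    ``a_ij = p_ji(t, x)`` for ``i != j`` and ``a_ii = -sum_{k != i} p_ik``.
    The result is Metzler with zero column sums.
    """
    x = _check_state(system, x)
    return GeneratorMatrix(system.generator(t, x), t, x.copy())


def vector_field(system: MasterSystem, t: float, x) -> np.ndarray:
    """Evaluate ``f(t, x) = A(t, x) x``; components sum to zero."""
    x = _check_state(system, x)
    return system.vector_field(t, x)


def _analytic_B(system: MasterSystem, t: float, x: np.ndarray) -> np.ndarray:
    n = system.n_states
    B = np.zeros((n, n))
    for (u, v), fn in system.rates.items():
        if not fn.depends_on_state:
            continue
        xu = x[u]
        if xu == 0.0:
            # derivative terms are weighted by x_u; skip exact zeros
            continue
        for l in range(n):
            g = fn.state_derivative(t, x, l)
            if g != 0.0:
                # rate (u -> v) appears in a_{v,u} (+) and a_{u,u} (-)
                B[v, l] += xu * g
                B[u, l] -= xu * g
    return B


def _finite_difference_B(system: MasterSystem, t: float, x: np.ndarray, A) -> np.ndarray:
    n = system.n_states
    Ad = A.toarray() if sp.issparse(A) else A
    J = np.zeros((n, n))
    for j in range(n):
        h = 1e-6 * max(1.0, abs(x[j]))
        if x[j] - h >= 0.0:
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            J[:, j] = (system.vector_field(t, xp) - system.vector_field(t, xm)) / (2 * h)
        else:
            # one-sided at the orthant boundary: rates need not exist for x < 0
            xp = x.copy()
            xp[j] += h
            J[:, j] = (system.vector_field(t, xp) - system.vector_field(t, x)) / h
    return J - Ad


def jacobian(system: MasterSystem, t: float, x, method: str = "auto") -> JacobianResult:
    """Jacobian ``J = A + B`` of the vector field at ``(t, x)``.

    ``method`` is ``"analytic"`` (requires every state-dependent rate to
    supply ``state_derivative``), ``"finite_difference"`` (central
    differences with step ``1e-6 * max(1, |x_j|)``, one-sided at the
    boundary of the orthant), or ``"auto"`` (analytic when available).
    """
    x = _check_state(system, x)
    A = build_generator(system, t, x)
    if not system.depends_on_state:
        Ad = A.entries.toarray() if sp.issparse(A.entries) else A.entries
        B = np.zeros_like(Ad)
        return JacobianResult(A, B, Ad + B, "analytic")
    if method == "auto":
        method = "analytic" if system.has_analytic_derivatives else "finite_difference"
    if method == "analytic":
        if not system.has_analytic_derivatives:
            raise ConfigurationError(
                "analytic Jacobian requested but some state-dependent rates "
                "do not provide state_derivative"
            )
        B = _analytic_B(system, t, x)
    elif method == "finite_difference":
        B = _finite_difference_B(system, t, x, A.entries)
    else:
        raise ConfigurationError(f"unknown jacobian method {method!r}")
    Ad = A.entries.toarray() if sp.issparse(A.entries) else A.entries
    return JacobianResult(A, B, Ad + B, method)


def sample_simplex(n: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform samples on the probability simplex via exponential spacings."""
    e = rng.exponential(size=(size, n))
    return e / e.sum(axis=1, keepdims=True)


def validate_system(
    system: MasterSystem,
    n_time_samples: int = 25,
    n_state_samples: int = 50,
    seed: int = 0,
    periodicity_tol: float = 1e-12,
) -> ValidationReport:
    """Spot-check rate non-negativity and joint periodicity by sampling.

    Rates are evaluated on a uniform time grid over one period crossed with
    seeded uniform simplex samples; negativity anywhere sampled fails the
    report, as does a periodicity defect ``|p(t + T, x) - p(t, x)|`` above
    ``periodicity_tol``.  Sampling cannot prove either property; the report
    discloses the grids and seed used.
    """
    rng = np.random.default_rng(seed)
    T = system.period
    ts = np.linspace(0.0, T, n_time_samples, endpoint=False)
    xs = sample_simplex(system.n_states, n_state_samples, rng)
    min_rate = np.inf
    min_at = None
    max_viol = 0.0
    failures = []
    for (i, j), fn in system.rates.items():
        for t in ts:
            for x in xs:
                v = fn(t, x)
                if v < min_rate:
                    min_rate, min_at = v, (i, j, float(t))
                if v < 0:
                    failures.append((i, j, float(t), float(v)))
                viol = abs(fn(t + T, x) - v)
                max_viol = max(max_viol, viol)
    passed = not failures and max_viol <= periodicity_tol
    return ValidationReport(
        passed=passed,
        min_rate=float(min_rate) if np.isfinite(min_rate) else 0.0,
        min_rate_at=min_at,
        max_periodicity_violation=float(max_viol),
        n_time_samples=n_time_samples,
        n_state_samples=n_state_samples,
        seed=seed,
        failures=failures,
    )
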