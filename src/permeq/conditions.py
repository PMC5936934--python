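"""Numerical certificates for entrainment of the periodic master equation.

The theory gives a ladder of sufficient conditions:

* **Cooperativity** — if every off-diagonal entry of the Jacobian
  ``J = A + B`` is non-negative on the simplex, i.e.

      p_ji(t, x) + sum_k x_k * da_ik/dx_j >= 0   for all i != j,

  the flow preserves the componentwise order, and together with the first
  integral ``sum_i x_i`` this forces every solution to converge to some
  T-periodic solution (entrainment).  When no rate depends on the state the
  condition holds automatically (the off-diagonals of ``J = A`` are the
  rates themselves).

* **Irreducibility** — if additionally there is a single time ``t*`` at
  which ``A(t*, x) + B(t*, x)`` is irreducible (its directed graph is
  strongly connected) for every ``x`` on the simplex, the T-periodic
  solution is unique and attracts every trajectory at an exponential rate.

* **l1 boundary property** — every master-equation generator has
  logarithmic norm ``mu_1(A) = 0`` exactly (columns sum to zero,
  off-diagonals non-negative): the flow is on the verge of contraction in
  the l1 norm, so distances between solutions never grow.

"for all x on the simplex" is undecidable numerically; the checks here
sample a deterministic grid (vertices, edge midpoints, barycenter) plus
seeded uniform simplex draws, and the report always discloses the sampling
spec.  Certificates assert that the *hypotheses* were numerically
satisfied on the samples — convergence itself is verified independently by
:mod:`permeq.dynamics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .system import MasterSystem, jacobian, sample_simplex

__all__ = [
    "CooperativityReport",
    "IrreducibilityVerdict",
    "ConditionReport",
    "SamplingSpec",
    "check_cooperativity",
    "check_irreducibility",
    "l1_matrix_measure",
    "entrainment_certificate",
    "simplex_sample_set",
]

#: Jacobian off-diagonal dips beyond this are real violations, below it noise
DEFAULT_MARGIN_TOL = 1e-9


@dataclass
class SamplingSpec:
    """Grids and seed used by the sampled condition checks."""

    n_time: int = 25
    n_state: int = 200
    seed: int = 0
    include_vertices: bool = True


def simplex_sample_set(n: int, spec: SamplingSpec) -> np.ndarray:
    """Deterministic simplex grid plus seeded uniform draws.

    The deterministic part contains every vertex ``e_i`` (the boundary
    faces matter for irreducibility), all edge midpoints, and the
    barycenter; the random part is uniform on the simplex.
    """
    rng = np.random.default_rng(spec.seed)
    pts = []
    if spec.include_vertices:
        eye = np.eye(n)
        pts.append(eye)
        mids = [(eye[i] + eye[j]) / 2.0 for i in range(n) for j in range(i + 1, n)]
        if mids:
            pts.append(np.array(mids))
        pts.append(np.full((1, n), 1.0 / n))
    n_det = sum(p.shape[0] for p in pts)
    n_rand = max(0, spec.n_state - n_det)
    if n_rand:
        pts.append(sample_simplex(n, n_rand, rng))
    return np.vstack(pts)


@dataclass
class CooperativityReport:
    """Minimum sampled off-diagonal Jacobian entry and where it occurred."""

    passed: bool
    margin: float
    argmin: Optional[Tuple[int, int, float, np.ndarray]]  # (i, j, t, x)
    automatic: bool  # True when no rate depends on the state
    tol: float
    n_samples: int


@dataclass
class IrreducibilityVerdict:
    """Strong connectivity of the graph of ``A + B`` at one time."""

    irreducible: bool
    t_star: Optional[float]
    threshold: float
    per_sample: List[bool] = field(default_factory=list)


@dataclass
class ConditionReport:
    """Outcome of all three checks plus the strongest certificate tier.

    ``certificate`` is one of ``none``, ``entrains``, ``entrains_time_only``,
    ``converges_to_steady_state``, ``unique_orbit``.  Tiers certify
    hypotheses, not conclusions.
    """

    cooperativity: CooperativityReport
    irreducibility: IrreducibilityVerdict
    l1_measure_max: float
    certificate: str
    sampling: SamplingSpec

    def to_dict(self) -> dict:
        c = self.cooperativity
        arg = None
        if c.argmin is not None:
            i, j, t, x = c.argmin
            arg = {"i": i + 1, "j": j + 1, "t": t, "x": list(map(float, x))}
        return {
            "certificate": self.certificate,
            "cooperativity": {
                "passed": c.passed,
                "margin": c.margin,
                "automatic": c.automatic,
                "argmin": arg,
                "tol": c.tol,
                "n_samples": c.n_samples,
            },
            "irreducibility": {
                "irreducible": self.irreducibility.irreducible,
                "t_star": self.irreducibility.t_star,
                "threshold": self.irreducibility.threshold,
            },
            "l1_measure_max": self.l1_measure_max,
            "sampling": {
                "n_time": self.sampling.n_time,
                "n_state": self.sampling.n_state,
                "seed": self.sampling.seed,
            },
        }


def l1_matrix_measure(M) -> float:
    """Logarithmic norm of ``M`` induced by the l1 vector norm.

    ``mu_1(M) = max_j (m_jj + sum_{i != j} |m_ij|)``.  For every
    master-equation generator this is exactly zero: columns sum to zero and
    off-diagonals are non-negative, so each column term cancels.
    """
    M = M.toarray() if sp.issparse(M) else np.asarray(M, dtype=float)
    d = np.diag(M)
    col_abs = np.abs(M).sum(axis=0) - np.abs(d)
    return float(np.max(d + col_abs))


def check_cooperativity(
    system: MasterSystem,
    t_samples: Optional[Sequence[float]] = None,
    x_samples: Optional[np.ndarray] = None,
    tol: float = DEFAULT_MARGIN_TOL,
    sampling: Optional[SamplingSpec] = None,
) -> CooperativityReport:
    """Sampled check of the cooperativity inequality.

    Evaluates the off-diagonal entries of ``J(t, x) = A + B`` — equal to
    ``p_ji + sum_k x_k da_ik/dx_j`` — over the sample set and passes iff
    the minimum is ``>= -tol``.  For systems whose rates are all time-only
    the inequality holds structurally and the margin is the minimum sampled
    rate.
    """
    sampling = sampling or SamplingSpec()
    if t_samples is None:
        t_samples = np.linspace(0.0, system.period, sampling.n_time, endpoint=False)
    if x_samples is None:
        x_samples = simplex_sample_set(system.n_states, sampling)
    automatic = not system.depends_on_state
    if automatic:
        # J = A is independent of x: one state sample suffices
        x_samples = np.asarray(x_samples)[:1]
    off = ~np.eye(system.n_states, dtype=bool)
    margin = np.inf
    argmin = None
    count = 0
    for t in t_samples:
        for x in x_samples:
            J = jacobian(system, t, x).J
            count += 1
            vals = np.where(off, J, np.inf)
            k = np.unravel_index(np.argmin(vals), vals.shape)
            if vals[k] < margin:
                margin = float(vals[k])
                argmin = (int(k[0]), int(k[1]), float(t), x.copy())
    if not np.isfinite(margin):  # N == 1: no off-diagonal entries
        margin, argmin = 0.0, None
    return CooperativityReport(
        passed=margin >= -tol,
        margin=margin,
        argmin=argmin,
        automatic=automatic,
        tol=tol,
        n_samples=count,
    )


def check_irreducibility(
    system: MasterSystem,
    t: float,
    x_samples: Optional[np.ndarray] = None,
    threshold: float = 1e-12,
    sampling: Optional[SamplingSpec] = None,
) -> IrreducibilityVerdict:
    """Is ``A(t, x) + B(t, x)`` irreducible for every sampled ``x``?

    The matrix is irreducible iff the directed graph with an edge
    ``j -> i`` whenever ``(A + B)_ij > threshold`` (``i != j``) is strongly
    connected; ``threshold`` separates structural zeros from numerical
    noise.
    """
    sampling = sampling or SamplingSpec()
    if x_samples is None:
        x_samples = simplex_sample_set(system.n_states, sampling)
    if system.n_states == 1:
        return IrreducibilityVerdict(True, t, threshold, [True])
    per_sample = []
    # time-only systems: A is independent of x and B = 0 — one check suffices
    if not system.depends_on_state:
        x_samples = x_samples[:1]
    for x in x_samples:
        M = jacobian(system, t, x).J
        G = nx.DiGraph()
        G.add_nodes_from(range(system.n_states))
        src, dst = np.nonzero(M > threshold)
        for i, j in zip(src, dst):
            if i != j:
                G.add_edge(int(j), int(i))
        per_sample.append(nx.is_strongly_connected(G))
    ok = all(per_sample)
    return IrreducibilityVerdict(ok, t if ok else None, threshold, per_sample)


def entrainment_certificate(
    system: MasterSystem,
    sampling: Optional[SamplingSpec] = None,
    seed: Optional[int] = None,
    tol: float = DEFAULT_MARGIN_TOL,
) -> ConditionReport:
    """Run all three checks and assign the strongest certified tier.

    Tier logic (hypotheses sampled, never proven):

    * cooperativity fails -> ``none``;
    * cooperativity holds and some scanned ``t*`` gives an irreducible
      ``A + B`` on all samples -> ``unique_orbit``;
    * otherwise, time-only rates -> ``entrains_time_only``; state-only
      (time-invariant) rates -> ``converges_to_steady_state``; mixed
      dependence -> ``entrains``.
    """
    sampling = sampling or SamplingSpec()
    if seed is not None:
        sampling = SamplingSpec(sampling.n_time, sampling.n_state, seed,
                                sampling.include_vertices)
    x_samples = simplex_sample_set(system.n_states, sampling)
    t_grid = np.linspace(0.0, system.period, sampling.n_time, endpoint=False)

    coop = check_cooperativity(system, t_grid, x_samples, tol=tol, sampling=sampling)

    # scan candidate t* over one period; a single common t* must work for all x
    irr = IrreducibilityVerdict(False, None, 1e-12)
    for t in t_grid:
        v = check_irreducibility(system, float(t), x_samples, sampling=sampling)
        if v.irreducible:
            irr = v
            break

    mu_max = max(
        l1_matrix_measure(system.generator(t, x)) for t in t_grid for x in x_samples[:20]
    )

    if not coop.passed:
        cert = "none"
    elif not system.depends_on_time and system.depends_on_state:
        # time-invariant rates: entrainment with every period, i.e. a steady state
        cert = "converges_to_steady_state"
    elif irr.irreducible:
        cert = "unique_orbit"
    elif not system.depends_on_state:
        cert = "entrains_time_only"
    else:
        cert = "entrains"
    return ConditionReport(coop, irr, float(mu_max), cert, sampling)
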