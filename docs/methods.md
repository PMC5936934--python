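# Methods

## Model and assumptions

The object throughout is the master equation `dx/dt = A(t, x) x` on the
probability simplex `Ω ⊂ R^N`, with generator entries built from
transition rates `p_ij(t, x)`: `a_ij = p_ji` for `i ≠ j` and
`a_ii = −Σ_{k≠i} p_ik`.  Rates must be

* non-negative and continuous on `[0, T] × R₊^N`,
* continuously differentiable in `x` on the interior with a continuous
  extension to the boundary (needed for the Jacobian decomposition), and
* jointly periodic with a declared common period `T` (time-invariant
  rates count as periodic with every period and carry `period = None`).

Rates are required to be well defined on a neighbourhood of `Ω` inside
the non-negative orthant; the package does not wrap user rates in a
cut-off extension — rate authors supply functions valid off the simplex,
which the monodromy construction and the order-preservation tests rely
on.  Continuity and differentiability can only be spot-checked by
sampling (`validate_system`), never proven; the validation report always
discloses its grids and seed.

## Generator, Jacobian, and indexing

The generator is assembled from flat `(source, destination)` index arrays
for speed; it is dense up to `N = 256` states and CSR-sparse beyond
(TASEP chains longer than 8 sites).  Column sums are zero by
construction, which is what conserves `H(x) = Σ x_i`.

The Jacobian splits as `J = A + B` with `b_ij = Σ_k x_k ∂a_ik/∂x_j`.
Analytic mode uses per-rate `state_derivative` hooks (the migration model
ships `∂p_ij/∂x_l = (δ_jl − δ_il) k_ij p_ij`); finite-difference mode
uses central differences with step `h = 1e−6 · max(1, |x_j|)`, falling
back to a one-sided difference when `x_j − h` would leave the orthant,
and defines `B := J_fd − A` so the decomposition identity holds exactly.
Configurations are 0-based internally and 1-based (`C_1 … C_N`) in every
user-facing message, matching the usual labelling of the worked models.

TASEP configurations are enumerated in binary-counting order with site 1
as the most significant bit (`C_1` = empty chain, `C_N` = full chain);
any other ordering silently breaks the published small-chain generator
matrices that the tests pin entry-for-entry.  TASEP rates are restricted
to time-only dependence and chains are capped at `n = 12` sites
(`N = 4096`) by default.  The SIS chain indexes states by infected count
`0..N`.

## Condition checks

"For all `x ∈ Ω`" is not decidable numerically.  The cooperativity
inequality (off-diagonals of `J` non-negative) and irreducibility are
therefore evaluated on a disclosed sample set: a deterministic part —
all vertices `e_i` (boundary faces are exactly where irreducibility can
degenerate), all edge midpoints, the barycenter — plus seeded uniform
simplex draws via exponential spacings, 200 points and 25 time points per
period by default.  Violations smaller than `1e−9` in magnitude are
treated as numerical noise (finite-difference Jacobians carry `O(1e−10)`
error).  Irreducibility follows the theory's quantifier order: one common
`t*` must work for every sampled `x`; candidate `t*` values are scanned
over a uniform grid of one period, and the graph of `A + B` uses a
`1e−12` threshold to separate structural zeros from roundoff.

Certificate tiers certify *hypotheses*, not conclusions, and are ordered:
failed cooperativity → `none`; time-invariant state-dependent rates with
cooperativity → `converges_to_steady_state` (entrainment with every
period is a steady state, so this subsumes the periodic statement even
when irreducibility also holds); otherwise irreducibility at some `t*` →
`unique_orbit`; time-only rates → `entrains_time_only`; mixed dependence
→ `entrains`.  Convergence itself is verified independently by the
dynamics layer.

Note that state-dependent models need not be cooperative: the
two-settlement migration model satisfies the off-diagonal inequality only
for weak enough coupling (at `k = 1` the entry
`p_21 − k(x_1 p_12 + x_2 p_21)` dips to ≈ −0.26 on the simplex; at
`k = 0.5` it stays positive).  The certificate reports exactly this.

## Integration and orbits

`solve_ivp` does the integration with defaults `rtol = 1e−9`,
`atol = 1e−12`; the explicit high-order method (DOP853) is used unless
the generator's diagonal spread exceeds `1e3`, in which case the
stiff-capable Radau method is selected.  The state is never projected
back onto the simplex: conservation is structural, and the observed drift
(flagged above `1e−8`) is a solver diagnostic that projection would mask.

The attracting T-periodic orbit is a fixed point of the period map
`x ↦ x(t₀ + T; t₀, x)`.  Two routes:

* **iteration** — repeat the map until the ℓ1 displacement falls below
  `tol` (`1e−9` default).  A start that never moves triggers an identity
  probe (vertices plus seeded points); if the map is the identity the
  result is flagged `degenerate` — every point periodic, as with all-zero
  rates — rather than claimed as an orbit.  Budget exhaustion returns a
  `not_converged` signal with the last displacement, never an orbit.
* **monodromy** (time-only rates, where the system is linear) — integrate
  the `N` canonical basis vectors over one period to form `Φ`, then solve
  the least-squares system `(Φ − I)γ = 0` augmented with `Σγ = 1`.
  Columns of `Φ` sum to one, so `Φ − I` always has one null direction; a
  second singular value below `1e−10` signals a degenerate/non-unique
  fixed-point set.  The dominant non-unit Floquet multiplier `λ₂` gives
  the exponential convergence rate `−log|λ₂|/T`.

Both routes re-verify the returned residual with one extra period-map
application, and `confirm_uniqueness` integrates from several seeded
starts (always including two simplex vertices); agreement within `1e−7`
is reported as evidence of uniqueness, never proof.

Steady states of time-invariant systems come from the SVD null space of
the constant generator (a kernel of dimension above one is returned as a
non-uniqueness signal, e.g. the absorbing SIS chain with `b = c ≡ 0`),
or, for state-dependent rates, from damped period-map iteration with the
declared pseudo-period.

## Entrainment diagnostics

`verify_entrainment` integrates each start for `n_periods` forcing
periods (20 for the worked runs) and reports, per start:

* the period residual `r = max_t ‖x(t + T) − x(t)‖₁` over the last
  period;
* an estimated attractor period: the shift `s ∈ [0.5T, 1.5T]` on a
  `T/1000` grid minimizing the sup discrepancy over the last period.
  This is diagnostic only — the theory asserts entrainment at the forcing
  period without requiring minimality, so the declared `T` is what is
  verified;
* an exponential decay fit of the period-map displacements (below).

Pairwise ℓ1 distances at matched times quantify collapse of all starts
onto a single orbit.

### Decay-rate fitting and its precision limit

Displacements `d_k = ‖x_{k+1} − x_k‖₁` of the period map decay
geometrically until they reach the integrator's accuracy floor, after
which they fluctuate on a noise plateau that measures solver error, not
dynamics.  The fit keeps the initial strictly decreasing segment above
the plateau (estimated as 10× the median of the tail beyond the global
minimum), cuts again where the per-step decay ratio bends to more than
5× its median (runs that end mid-plateau), discards the first 20% of the
kept iterates as transient, and regresses `log d_k` on `kT`.  Fewer than
three usable points cannot support a goodness-of-fit statistic: the
two-point slope is still reported, with `r2 = None`.

This limit is reached in practice.  The worked TASEP run contracts by a
factor ≈ 0.055 per period, leaving ~9 usable displacements and a fit with
`R² > 0.999`.  The worked SIS run contracts by `|λ₂| ≈ 5.8e−10` — nine
decades per forcing period — so only two displacements are measurable
above the double-precision floor regardless of tolerances; its
exponential convergence is instead evidenced by the monodromy spectrum,
whose rate `−log|λ₂|/T ≈ 3.38` agrees with the two-point displacement
slope ≈ 3.30.

## Exact two-state oracle

The `N = 2` system `x̊₁ = p₂₁ − (p₁₂ + p₂₁)x₁` has the closed form
`x₁(t) = e^{−E(t)}(x₁(0) + c(t))` with `E(t) = ∫₀ᵗ(p₁₂ + p₂₁)` and
`c(t) = ∫₀ᵗ p₂₁(τ) e^{E(τ)} dτ`, and the unique periodic point
`x₁(0) = e^{−E(T)} c(T) / (1 − e^{−E(T)})` whenever the total rate is
positive somewhere in the period (otherwise every point is periodic and a
degenerate-case error is raised).  The nested quadrature is computed as
one auxiliary initial-value problem (`E' = p₁₂ + p₂₁`,
`c' = p₂₁ e^E`) at `rtol = 1e−12`, which is both cheaper and more
accurate than nested adaptive quadrature.  This closed form cross-checks
the generic integrator and the period map on 50 seeded random systems in
the test suite.

## Random fixtures

The fixture generator draws rates
`p_ij(t) = max(0, c₀ + Σ_m a_m cos(2πmt/T + φ_m))` with coefficients from
a seeded stream (defaults: 2 harmonics, amplitudes in `[0, 1]`, all rates
in units of 1/time).  Clipping at zero preserves continuity in `t`
(differentiability is only needed in `x`, and these rates are time-only).
One seed determines the whole system, so every property run is
reproducible.  These fixtures emulate the *regularity* of admissible rate
families — smooth seasonal forcing of otherwise unstructured transition
graphs — not any particular physical model: passing the property suite on
them demonstrates the structural invariants (zero column sums, Metzler
sign, `μ1 = 0`, ℓ1 non-expansiveness), and says nothing about, e.g.,
stiff rate separations or near-reducible graphs beyond what the worked
models and the absorbing-chain cases cover.

## Problem sizes and runtime

The shipped analyses use the worked models at their published sizes
(TASEP `n = 3`, `N = 8`; SIS `N = 3`, 4 states), 20 forcing periods for
the entrainment runs, 50 seeded systems for the oracle comparisons and 20
random fixtures for the property sweep — enough for every reported digit
to be stable at the stated tolerances while the whole acceptance script
completes in well under a minute.

## Known limitations

* All condition checks are sampled; a rate family that violates
  cooperativity or irreducibility only on an unsampled sliver of `Ω`
  can be mis-certified.  Certificates are labelled as hypothesis checks
  for this reason.
* Only attracting orbits are sought (fixed-point iteration and the
  monodromy solve); there is no shooting/Newton machinery for unstable
  periodic orbits, and no Floquet spectrum beyond the dominant rate.
* The decay-rate fit degrades gracefully but inevitably for systems that
  contract faster than ~6 decades per period (see above).
* Fourier-string configs cover time dependence only; state dependence
  enters exclusively through the built-in migration form.
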