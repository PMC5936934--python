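import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from permeq import (
    ConstantRate,
    MigrationRate,
    build_migration,
    build_sis,
    build_tasep,
    build_two_state,
    enumerate_configurations,
    expected_infected,
    integrate,
    occupation_density,
    two_state_closed_form,
    two_state_periodic_point,
    two_state_solution,
    vector_field,
)
from permeq._errors import (
    CapacityError,
    ConfigurationError,
    DegenerateSystemError,
)

from conftest import random_two_state_rates, sis3_rates

TWO_PI = 2.0 * math.pi


class TestEnumerateConfigurations:
    def test_two_sites(self):
        assert enumerate_configurations(2) == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_three_sites_ordering(self):
        c = enumerate_configurations(3)
        assert c[:4] == [(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1)]
        assert c[-1] == (1, 1, 1)

    def test_single_site(self):
        assert enumerate_configurations(1) == [(0,), (1,)]

    @given(st.integers(1, 8))
    @settings(deadline=None)
    def test_counting_order_with_site_one_most_significant(self, n):
        c = enumerate_configurations(n)
        assert len(c) == 2 ** n
        values = [int("".join(map(str, cfg)), 2) for cfg in c]
        assert values == list(range(2 ** n))


def symbolic_tasep_generator(n, alpha, beta, hs):
    """Independent oracle: assemble the generator from the transition rules
    by brute force over configuration pairs."""
    configs = enumerate_configurations(n)
    N = len(configs)
    A = np.zeros((N, N))
    for i, c in enumerate(configs):
        out = 0.0
        for j, d in enumerate(configs):
            if i == j:
                continue
            rate = 0.0
            if c[0] == 0 and d == (1,) + c[1:]:
                rate += alpha
            if c[-1] == 1 and d == c[:-1] + (0,):
                rate += beta
            for k in range(n - 1):
                if c[k] == 1 and c[k + 1] == 0 and d == c[:k] + (0, 1) + c[k + 2:]:
                    rate += hs[k]
            A[j, i] += rate
            out += rate
        A[i, i] = -out
    return A


class TestTASEP:
    def test_two_site_generator_matches_printed_matrix(self):
        a, b, h1 = 2.0, 3.0, 5.0
        model = build_tasep(2, a, b, [h1], period=1.0)
        A = model.system.generator(0.0, np.full(4, 0.25))
        expected = np.array([
            [-a, b, 0, 0],
            [0, -a - b, h1, 0],
            [a, 0, -h1, b],
            [0, a, 0, -b],
        ])
        np.testing.assert_array_equal(A, expected)

    def test_three_site_generator_matches_printed_matrix(self):
        a, b, h1, h2 = 2.0, 3.0, 5.0, 7.0
        model = build_tasep(3, a, b, [h1, h2], period=1.0)
        A = model.system.generator(0.0, np.full(8, 0.125))
        expected = np.array([
            [-a, b, 0, 0, 0, 0, 0, 0],
            [0, -a - b, h2, 0, 0, 0, 0, 0],
            [0, 0, -a - h2, b, h1, 0, 0, 0],
            [0, 0, 0, -a - b, 0, h1, 0, 0],
            [a, 0, 0, 0, -h1, b, 0, 0],
            [0, a, 0, 0, 0, -h1 - b, h2, 0],
            [0, 0, a, 0, 0, 0, -h2, b],
            [0, 0, 0, a, 0, 0, 0, -b],
        ])
        np.testing.assert_array_equal(A, expected)

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_generator_matches_brute_force_rules(self, n):
        rng = np.random.default_rng(n)
        a, b = rng.uniform(0.5, 2, 2)
        hs = list(rng.uniform(0.5, 2, n - 1))
        model = build_tasep(n, a, b, hs, period=1.0)
        A = model.system.generator(0.0, np.full(2 ** n, 2.0 ** -n))
        np.testing.assert_allclose(A, symbolic_tasep_generator(n, a, b, hs),
                                   atol=1e-15)
        assert np.allclose(A.sum(axis=0), 0.0, atol=1e-12)

    def test_capacity_cap(self):
        with pytest.raises(CapacityError):
            build_tasep(13, 1.0, 1.0, [1.0] * 12)

    def test_wrong_hop_count(self):
        with pytest.raises(ConfigurationError):
            build_tasep(3, 1.0, 1.0, [1.0])

    def test_state_dependent_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            build_tasep(2, MigrationRate(0, 1, 1.0), 1.0, [1.0])


class TestOccupationDensity:
    def test_full_chain_indicator(self):
        model = build_tasep(3, 1.0, 1.0, [1.0, 1.0], period=1.0)
        x = np.zeros(8)
        x[-1] = 1.0  # all-ones configuration
        np.testing.assert_allclose(occupation_density(model, x), np.ones(3))

    def test_uniform_distribution_gives_half(self):
        for n in (2, 3, 4):
            model = build_tasep(n, 1.0, 1.0, [1.0] * (n - 1), period=1.0)
            x = np.full(2 ** n, 2.0 ** -n)
            np.testing.assert_allclose(occupation_density(model, x), 0.5)

    def test_reads_off_single_configuration(self):
        model = build_tasep(2, 1.0, 1.0, [1.0], period=1.0)
        x = np.zeros(4)
        x[2] = 1.0  # C_3 = (1, 0)
        np.testing.assert_allclose(occupation_density(model, x), [1.0, 0.0])

    def test_linear_in_the_distribution(self):
        model = build_tasep(3, 1.0, 1.0, [1.0, 1.0], period=1.0)
        rng = np.random.default_rng(5)
        x, y = rng.dirichlet(np.ones(8), size=2)
        lam = 0.3
        lhs = occupation_density(model, lam * x + (1 - lam) * y)
        rhs = lam * occupation_density(model, x) + (1 - lam) * occupation_density(model, y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-14)
        assert np.all(lhs >= 0) and np.all(lhs <= 1)


class TestSIS:
    def test_tridiagonal_with_printed_corner_entries(self, sis3):
        a, b, c = sis3_rates()
        for t in (0.0, 1.0, 2.5):
            A = sis3.system.generator(t, np.full(4, 0.25))
            bt = b(t, None)
            ct = c(t, None)
            assert A[0, 1] == pytest.approx(bt)       # down-rate from n=1 is b
            assert A[1, 0] == pytest.approx(ct)       # up-rate from n=0 is c*q0 = c
            # no transitions beyond nearest neighbours
            for i in range(4):
                for j in range(4):
                    if abs(i - j) > 1:
                        assert A[i, j] == 0.0

    def test_up_and_down_rates_match_birth_death_rules(self):
        N = 5
        a, b, c = sis3_rates()
        model = build_sis(N, a, b, c, period=TWO_PI)
        for t in (0.0, 0.7, 4.0):
            A = model.system.generator(t, np.full(N + 1, 1.0 / (N + 1)))
            at, bt, ct = 1.0, b(t, None), c(t, None)
            for n in range(N + 1):
                if n < N:
                    assert A[n + 1, n] == pytest.approx((n * at + ct) * (1 - n / N))
                if n > 0:
                    assert A[n - 1, n] == pytest.approx(n * bt)

    def test_equals_P_minus_D_decomposition(self):
        """The generator is M = P - D with D = diag(0, b, 2b, ..., Nb)."""
        N = 3
        a, b, c = sis3_rates()
        model = build_sis(N, a, b, c, period=TWO_PI)
        t = 1.3
        at, bt, ct = 1.0, b(t, None), c(t, None)
        q = 1.0 - np.arange(N + 1) / N
        D = np.diag(bt * np.arange(N + 1))
        P = np.zeros((N + 1, N + 1))
        for n in range(N):
            up = (n * at + ct) * q[n]
            P[n + 1, n] = up
            P[n, n] -= up
        for n in range(1, N + 1):
            P[n - 1, n] = n * bt  # recovery inflow sits in P's superdiagonal
        M = model.system.generator(t, np.full(N + 1, 0.25))
        np.testing.assert_allclose(M, P - D, atol=1e-14)

    def test_up_rate_from_zero_at_t0(self):
        a, b, c = sis3_rates()
        model = build_sis(3, a, b, c, period=TWO_PI)
        A = model.system.generator(0.0, np.full(4, 0.25))
        assert A[1, 0] == pytest.approx(2.0 - 2.0 * math.sin(0.75))

    def test_no_recovery_no_import_gives_two_absorbing_states(self):
        N = 3
        model = build_sis(N, 1.0, 0.0, 0.0, period=1.0)
        A = model.system.generator(0.0, np.full(N + 1, 0.25))
        assert np.all(A[:, 0] == 0.0)
        assert np.all(A[:, N] == 0.0)
        e1 = np.zeros(N + 1)
        e1[0] = 1.0
        eN = np.zeros(N + 1)
        eN[N] = 1.0
        assert np.linalg.norm(vector_field(model.system, 0.0, e1), 1) < 1e-12
        assert np.linalg.norm(vector_field(model.system, 0.0, eN), 1) < 1e-12

    def test_rejects_empty_population(self):
        with pytest.raises(ConfigurationError):
            build_sis(0, 1.0, 1.0, 1.0)


class TestExpectedInfected:
    def test_extremes_and_uniform(self):
        model = build_sis(3, 1.0, 1.0, 1.0, period=1.0)
        e0 = np.array([1.0, 0, 0, 0])
        e3 = np.array([0, 0, 0, 1.0])
        assert expected_infected(model, e0) == 0.0
        assert expected_infected(model, e3) == 3.0
        assert expected_infected(model, np.full(4, 0.25)) == pytest.approx(1.5)


class TestTwoStateClosedForm:
    def test_time_zero_returns_initial_condition(self):
        x = two_state_closed_form(1.0, 2.0, 0.3, 0.0)
        np.testing.assert_allclose(x, [0.3, 0.7])

    def test_symmetric_constant_rates(self):
        # x1' = 1 - 2 x1 from x1(0) = 1: x1(1) = 1/2 + (1/2) e^{-2}
        x = two_state_closed_form(1.0, 1.0, 1.0, 1.0)
        assert x[0] == pytest.approx(0.5 + 0.5 * math.exp(-2.0), abs=1e-10)
        assert x[1] == pytest.approx(1.0 - x[0])

    def test_pure_decay_when_backflow_vanishes(self):
        for t in (0.5, 1.0, 3.0):
            x = two_state_closed_form(1.0, 0.0, 1.0, t)
            assert x[0] == pytest.approx(math.exp(-t), abs=1e-10)

    def test_matches_generic_integrator_on_seeded_rates(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            p12, p21 = random_two_state_rates(rng)
            system = build_two_state(p12, p21, period=TWO_PI)
            x0 = rng.uniform(0, 1)
            traj = integrate(system, np.array([x0, 1 - x0]), 0.0, TWO_PI,
                             rtol=1e-10, atol=1e-13)
            for t in np.linspace(0.0, TWO_PI, 9)[1:]:
                exact = two_state_closed_form(p12, p21, x0, float(t))
                np.testing.assert_allclose(traj(float(t)), exact, atol=1e-8)


class TestTwoStatePeriodicPoint:
    def test_symmetric_constant_rates_give_half(self):
        for T in (1.0, TWO_PI):
            assert two_state_periodic_point(1.0, 1.0, T) == pytest.approx(0.5, abs=1e-12)

    def test_zero_backflow_gives_zero(self):
        assert two_state_periodic_point(1.0, 0.0, 3.0) == pytest.approx(0.0, abs=1e-12)

    def test_always_in_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            p12, p21 = random_two_state_rates(rng)
            assert 0.0 <= two_state_periodic_point(p12, p21, TWO_PI) <= 1.0

    def test_degenerate_zero_rates_signalled(self):
        with pytest.raises(DegenerateSystemError):
            two_state_periodic_point(0.0, 0.0, 1.0)

    def test_solution_bundle_reports_quadrature(self):
        sol = two_state_solution(1.0, 1.0, 1.0)
        assert sol.periodic_point == pytest.approx(0.5, abs=1e-12)
        assert sol.c_of_t(1.0) == pytest.approx((math.exp(2.0) - 1.0) / 2.0, rel=1e-9)
        assert sol.x1_of_t(1.0, 1.0) == pytest.approx(0.5 + 0.5 * math.exp(-2.0))


class TestMigration:
    def test_equal_densities_give_unit_rates(self):
        system = build_migration(2, 1.0)
        x = np.array([0.5, 0.5])
        for (i, j), r in system.rates.items():
            assert r(0.0, x) == pytest.approx(1.0)

    def test_uniform_density_is_equilibrium(self):
        for K in (2, 3, 4):
            system = build_migration(K, 2.0)
            f = vector_field(system, 0.0, np.full(K, 1.0 / K))
            np.testing.assert_allclose(f, 0.0, atol=1e-14)

    def test_seasonal_scaling_passes_validation(self):
        from permeq import FourierRate, validate_system

        k = FourierRate(c0=2.0, terms=((0.5, TWO_PI, 0.0),), period=1.0)
        system = build_migration(2, {(0, 1): k, (1, 0): k}, period=1.0)
        rep = validate_system(system, seed=0)
        assert rep.passed

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            build_migration(2, -1.0)
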