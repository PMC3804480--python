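"""Gain/loss/nonconservative operators, thermostat and transport."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_spec, random_state
from ktap.model import (
    ActivityGrid,
    GeneralTransition,
    StateDistribution,
    fixture_scenario,
    make_gaussian_transition,
)
from ktap.moments import moment_pq
from ktap.operators import (
    full_rhs,
    gain,
    loss,
    nonconservative,
    thermostat_term,
    transport_rhs,
)


def brute_force_operators(f, spec):
    """Independent triple-loop evaluation of gain, loss and nonconservative."""
    n, M = f.values.shape
    du = spec.grid.du
    G = np.zeros((n, M))
    L = np.zeros((n, M))
    N = np.zeros((n, M))
    for i in range(n):
        for j in range(n):
            for k1 in range(M):
                for k2 in range(M):
                    col = spec.kernels.A.column(k1, k2)
                    G[i] += (
                        spec.kernels.iota[i, j, k1, k2]
                        * col
                        * f.values[i, k1]
                        * f.values[j, k2]
                        * du
                        * du
                    )
            for k in range(M):
                for k2 in range(M):
                    L[i, k] += (
                        f.values[i, k]
                        * spec.kernels.iota[i, j, k, k2]
                        * f.values[j, k2]
                        * du
                    )
                    N[i, k] += (
                        f.values[i, k]
                        * spec.kernels.iota[i, j, k, k2]
                        * spec.kernels.pi[i, j, k, k2]
                        * f.values[j, k2]
                        * du
                    )
    return G, L, N


class TestInteractionOperators:
    def test_uniform_equilibrium_gain_equals_loss(self, conservative_uniform):
        spec, f0 = conservative_uniform
        g = gain(f0, spec).values
        l = loss(f0, spec).values
        np.testing.assert_allclose(g, 0.5, rtol=1e-12)
        np.testing.assert_allclose(l, 0.5, rtol=1e-12)
        assert np.abs(g - l).max() <= 1e-13

    def test_zero_state_annihilates_everything(self):
        spec = make_spec(M=10, pi=0.3)
        f = StateDistribution(np.zeros((1, 10)))
        assert np.all(gain(f, spec).values == 0)
        assert np.all(loss(f, spec).values == 0)
        assert np.all(nonconservative(f, spec).values == 0)
        assert np.all(full_rhs(f, spec).values == 0)

    def test_empty_field_population_contributes_nothing(self):
        spec = make_spec(M=10, velocities=(1.0, 2.0))
        f_pair = random_state(spec, seed=3)
        f_pair.values[1] = 0.0
        spec1 = make_spec(M=10, velocities=(1.0,))
        f_single = StateDistribution(f_pair.values[:1].copy())
        g_pair = gain(f_pair, spec)
        g_single = gain(f_single, spec1)
        np.testing.assert_allclose(g_pair.values[0], g_single.values[0], atol=1e-14)

    @pytest.mark.parametrize("pi,expected", [(0.5, 0.25), (-0.2, -0.1), (0.0, 0.0)])
    def test_nonconservative_constant_rates(self, pi, expected):
        spec = make_spec(M=100, pi=pi)
        f = StateDistribution(np.full((1, 100), 0.5))
        N = nonconservative(f, spec).values
        np.testing.assert_allclose(N, expected, atol=1e-12)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_conservative_mass_cancellation(self, seed):
        """Gain and loss masses cancel per population for arbitrary f >= 0."""
        spec = make_spec(M=17, velocities=(1.0, -0.5), iota=0.8)
        f = random_state(spec, seed=seed)
        du = spec.grid.du
        g_mass = gain(f, spec).values.sum(axis=1) * du
        l_mass = loss(f, spec).values.sum(axis=1) * du
        np.testing.assert_allclose(g_mass, l_mass, rtol=1e-12)

    def test_mass_production_identity(self):
        """Total nonconservative mass rate equals iota*pi*mu^2 for constants."""
        spec = make_spec(M=23, iota=1.3, pi=0.4)
        f = random_state(spec, seed=11)
        mu = moment_pq(f, spec, 0, 0)
        total = nonconservative(f, spec).values.sum() * spec.grid.du
        assert total == pytest.approx(1.3 * 0.4 * mu * mu, rel=1e-12)

    @pytest.mark.parametrize("s", [0.5, 2.0])
    def test_quadratic_homogeneity(self, s):
        spec = make_spec(M=12, iota=1.1, pi=0.25, F=1.0, thermostat=True)
        f = random_state(spec, seed=7)
        fs = StateDistribution(f.values * s)
        for op in (gain, loss, nonconservative):
            np.testing.assert_allclose(
                op(fs, spec).values, s * s * op(f, spec).values, rtol=1e-12
            )
        E1 = moment_pq(f, spec, 1, 1)
        np.testing.assert_allclose(
            thermostat_term(fs, spec, s * E1).values,
            s * s * thermostat_term(f, spec, E1).values,
            rtol=1e-12,
        )


class TestBruteForceOracle:
    @pytest.mark.parametrize("general_A", [False, True])
    def test_matches_triple_loop(self, general_A):
        grid = ActivityGrid(-1.0, 1.0, 8)
        A = (
            make_gaussian_transition(grid, lambda u1, u2: 0.3 * u1 - 0.2 * u2, 0.4)
            if general_A
            else None
        )
        spec = make_spec(
            M=8,
            velocities=(1.0, 2.0),
            iota=lambda u1, u2: 1.0 + 0.5 * u1 * u2,
            pi=lambda u1, u2: 0.3 * u1 - 0.1,
            A=A,
        )
        f = random_state(spec, seed=5)
        G, L, N = brute_force_operators(f, spec)
        np.testing.assert_allclose(gain(f, spec).values, G, atol=1e-13)
        np.testing.assert_allclose(loss(f, spec).values, L, atol=1e-13)
        np.testing.assert_allclose(nonconservative(f, spec).values, N, atol=1e-13)

    def test_separable_and_general_paths_agree(self):
        """The O(M^2) separable factorization equals the full contraction."""
        grid = ActivityGrid(-1.0, 1.0, 10)
        sep = make_gaussian_transition(grid, 0.0, 0.5)
        full = GeneralTransition(
            grid, np.broadcast_to(sep.values, (10, 10, 10)).copy()
        )
        spec_sep = make_spec(M=10, iota=1.2, A=sep)
        spec_full = make_spec(M=10, iota=1.2, A=full)
        f = random_state(spec_sep, seed=9)
        np.testing.assert_allclose(
            gain(f, spec_sep).values, gain(f, spec_full).values, atol=1e-12
        )


class TestThermostat:
    def test_even_profile_zero_moment_gives_zero(self):
        spec = make_spec(M=20, F=1.0, thermostat=True)
        u = spec.grid.centers
        f = StateDistribution((1 - u**2)[None, :])
        assert np.all(thermostat_term(f, spec, 0.0).values == 0)

    def test_pointwise_value_against_hand_arithmetic(self):
        # f(u) = (1+u)/2 has E1 = 1/3; at the cell center u = 0.5 the damping
        # is u * F * f * E1 = 0.5 * 1 * 0.75 * (1/3) = 0.125
        spec = make_spec(M=10, F=1.0, thermostat=True)
        u = spec.grid.centers
        f = StateDistribution(((1 + u) / 2)[None, :])
        T = thermostat_term(f, spec, 1.0 / 3.0).values
        k = np.argmin(np.abs(u - 0.5))
        assert u[k] == pytest.approx(0.5, abs=1e-15)
        assert T[0, k] == pytest.approx(0.125, rel=1e-12)

    def test_zero_force_gives_zero(self):
        spec = make_spec(M=10, F=0.0, thermostat=True)
        f = random_state(spec, seed=1)
        assert np.all(thermostat_term(f, spec, 0.7).values == 0)


class TestTransport:
    def test_constant_state_constant_force_zero_interior(self):
        spec = make_spec(M=30, F=1.5)
        f = StateDistribution(np.full((1, 30), 0.8))
        rhs = transport_rhs(f, spec, 0.0).values[0]
        assert np.abs(rhs[1:-1]).max() <= 1e-13

    def test_first_order_convergence_to_analytic_derivative(self):
        """-d/du [F f] with F=1 converges to -f' at order >= 0.9 in du."""
        c = 0.7
        errs = {}
        for M in (100, 200):
            spec = make_spec(M=M, F=1.0)
            u = spec.grid.centers
            f = StateDistribution((c * (1 - u**2))[None, :])
            rhs = transport_rhs(f, spec, 0.0).values[0]
            exact = 2 * c * u
            errs[M] = np.abs(rhs[2:-2] - exact[2:-2]).max()
        order = np.log2(errs[100] / errs[200])
        assert order >= 0.9

    def test_mass_change_telescopes_to_boundary_flux(self):
        spec = make_spec(M=40, F=1.0, thermostat=True)
        f = random_state(spec, seed=13, zero_boundary_cells=2)
        rhs = transport_rhs(f, spec, 0.4).values
        assert abs(rhs.sum() * spec.grid.du) <= 1e-12


class TestFullRhs:
    def test_uniform_equilibrium_is_stationary(self, conservative_uniform):
        spec, f0 = conservative_uniform
        assert np.abs(full_rhs(f0, spec).values).max() <= 1e-13

    def test_parabolic_profile_relaxation_rate_at_center(self):
        # f = 0.75(1-u^2): gain = A*mu^2 exactly (uniform A), loss = f*mu,
        # so at u=0 the rhs is 0.5*mu^2 - 0.75*mu ~= -0.25 for mu ~= 1
        spec = make_spec(M=201, F=0.0)
        u = spec.grid.centers
        f = StateDistribution((0.75 * (1 - u**2))[None, :])
        mu = moment_pq(f, spec, 0, 0)
        rhs = full_rhs(f, spec).values[0]
        k = np.argmin(np.abs(u))
        A0 = spec.kernels.A.values[k]
        assert rhs[k] == pytest.approx(A0 * mu * mu - 0.75 * mu, rel=1e-12)
        assert rhs[k] == pytest.approx(-0.25, abs=2e-3)
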