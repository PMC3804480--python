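"""Riccati moment layer: fixed points, closed form, ODE solver, adjudication."""

import math

import numpy as np
import pytest

from ktap.errors import (
    MissingDependencyError,
    ParameterError,
    SingularityError,
    UnsupportedRegimeError,
)
from ktap.model import fixture_scenario
from ktap.riccati import (
    MomentODEParams,
    adjudicate_sign,
    check_preconditions,
    closed_form_E1,
    constant_solution,
    riccati_rhs_E1,
    solve_moment_ode_E1,
    solve_moment_ode_pq,
)
from ktap.simulator import RunConfig


def sweep_params(n=100, seed=2024):
    """Seeded random sweep of (F, c, mu_bar) with c realized as iota*mu."""
    rng = np.random.default_rng(seed)
    for _ in range(n):
        F = rng.uniform(0.1, 5.0)
        c = rng.uniform(0.0, 5.0)
        mu_bar = rng.uniform(0.0, 5.0)
        yield F, c, mu_bar


class TestRhsAndFixedPoint:
    @pytest.mark.parametrize(
        "F,mu_bar,iota,pi,mu,E1,expected",
        [
            (1.0, 1.0, 0.0, 0.0, 1.0, 1.0, 0.0),
            (0.0, 1.0, 1.0, 0.0, 1.0, 1.0, -1.0),
            (1.0, 2.0, 1.0, 0.0, 1.0, 1.0, 0.0),
        ],
    )
    def test_hand_values(self, F, mu_bar, iota, pi, mu, E1, expected):
        params = MomentODEParams(F=F, iota=iota, pi_rate=pi, mu_fn=mu, mu_bar_fn=mu_bar)
        assert riccati_rhs_E1(E1, 0.0, params) == pytest.approx(expected, abs=1e-14)

    @pytest.mark.parametrize(
        "F,c,mu_bar,expected",
        [(1.0, 0.0, 1.0, 1.0), (1.0, 1.0, 2.0, 1.0), (2.0, 1.5, 0.0, 0.0)],
    )
    def test_constant_solution_hand_values(self, F, c, mu_bar, expected):
        assert constant_solution(F, c, 0.0, 1.0, mu_bar) == pytest.approx(expected)

    def test_zero_force_raises_with_guidance(self):
        with pytest.raises(ParameterError, match="F = 0"):
            constant_solution(0.0, 1.0, 0.0, 1.0, 1.0)

    def test_negative_discriminant_raises(self):
        with pytest.raises(ParameterError, match="discriminant"):
            constant_solution(1.0, 0.1, 0.0, 1.0, -10.0)

    def test_fixed_point_sweep(self):
        """rhs evaluated at the constant solution vanishes across the sweep."""
        for F, c, mu_bar in sweep_params():
            E_bar = constant_solution(F, c, 0.0, 1.0, mu_bar)
            params = MomentODEParams(F=F, iota=c, pi_rate=0.0, mu_fn=1.0, mu_bar_fn=mu_bar)
            assert abs(riccati_rhs_E1(E_bar, 0.0, params)) <= 1e-12


class TestClosedForm:
    def _params(self, F, c, mu_bar):
        return MomentODEParams(F=F, iota=c, pi_rate=0.0, mu_fn=1.0, mu_bar_fn=mu_bar)

    def test_initial_condition_exact(self):
        params = self._params(1.0, 0.5, 1.5)
        assert closed_form_E1(0.0, 0.3, params) == 0.3

    def test_fixed_point_invariant(self):
        params = self._params(1.0, 1.0, 2.0)
        E_bar = constant_solution(1.0, 1.0, 0.0, 1.0, 2.0)
        for t in (0.0, 1.0, 7.5):
            assert closed_form_E1(t, E_bar, params) == pytest.approx(E_bar, rel=1e-14)

    def test_long_time_convergence(self):
        params = self._params(1.0, 1.0, 1.0)
        E_bar = constant_solution(1.0, 1.0, 0.0, 1.0, 1.0)
        assert closed_form_E1(40.0, 0.0, params) == pytest.approx(E_bar, rel=1e-12)

    def test_against_numerical_ode(self):
        params = self._params(1.0, 0.0, 1.0)
        t = np.linspace(0.0, 3.0, 31)
        num = solve_moment_ode_E1(0.0, t, params)
        closed = np.array([closed_form_E1(ti, 0.0, params) for ti in t])
        assert np.abs(num - closed).max() <= 1e-6

    def test_sweep_against_numerical_ode(self):
        """Closed form == high-accuracy ODE solve; singular cases raise."""
        t = np.linspace(0.0, 5.0, 26)
        rng = np.random.default_rng(7)
        n_sing = 0
        for F, c, mu_bar in sweep_params(n=100, seed=99):
            E1_0 = rng.uniform(-3.0, 3.0)
            params = self._params(F, c, mu_bar)
            try:
                closed = np.array([closed_form_E1(ti, E1_0, params) for ti in t])
            except SingularityError as exc:
                assert 0.0 < exc.singular_time <= 5.0
                n_sing += 1
                continue
            num = solve_moment_ode_E1(E1_0, t, params)
            assert np.abs(num - closed).max() <= 1e-6
        assert n_sing > 0  # the sweep must exercise the singular branch

    def test_singularity_raises_with_time(self):
        # start below the repelling root: finite-time escape to -infinity
        params = self._params(1.0, 0.0, 1.0)
        with pytest.raises(SingularityError) as ei:
            closed_form_E1(3.0, -1.5, params)
        assert ei.value.singular_time == pytest.approx(math.log(5.0) / 2.0, rel=1e-10)

    def test_time_dependent_coefficients_refused(self):
        params = MomentODEParams(
            F=1.0, iota=1.0, pi_rate=0.0, mu_fn=lambda t: 1.0 + t, mu_bar_fn=1.0
        )
        with pytest.raises(UnsupportedRegimeError, match="solve_moment_ode_E1"):
            closed_form_E1(1.0, 0.0, params)


class TestMomentOdes:
    def test_linear_decay_no_force(self):
        params = MomentODEParams(F=0.0, iota=1.0, pi_rate=0.0, mu_fn=1.0, mu_bar_fn=1.0)
        traj = solve_moment_ode_E1(1.0, [0.0, 1.0], params)
        assert traj[-1] == pytest.approx(math.exp(-1.0), abs=1e-6)

    def test_pi_one_no_force_is_constant(self):
        params = MomentODEParams(F=0.0, iota=1.0, pi_rate=1.0, mu_fn=1.0, mu_bar_fn=1.0)
        traj = solve_moment_ode_E1(0.7, [0.0, 2.0, 4.0], params)
        np.testing.assert_allclose(traj, 0.7, rtol=1e-9)

    @pytest.mark.parametrize(
        "mode,expected", [("growth", math.e), ("damping", math.exp(-1))]
    )
    def test_pq_sign_variants_linear_regime(self, mode, expected):
        params = MomentODEParams(
            F=0.0, iota=1.0, pi_rate=0.0, mu_fn=1.0, mu_bar_fn=1.0, sign_mode=mode
        )
        traj = solve_moment_ode_pq(1.0, [0.0, 1.0], params)
        assert traj[-1] == pytest.approx(expected, rel=1e-6)

    def test_pq_constant_when_rhs_vanishes(self):
        for mode in ("growth", "damping"):
            params = MomentODEParams(
                F=0.0, iota=1.0, pi_rate=1.0, mu_fn=1.0, sign_mode=mode
            )
            traj = solve_moment_ode_pq(0.4, [0.0, 3.0], params)
            np.testing.assert_allclose(traj, 0.4, rtol=1e-9)

    def test_missing_lower_moment_raises(self):
        params = MomentODEParams(F=1.0, iota=1.0, pi_rate=0.0, p=1, q=0)
        with pytest.raises(MissingDependencyError):
            solve_moment_ode_pq(1.0, [0.0, 1.0], params)


class TestHarness:
    def test_preconditions_on_thermostated_fixture(self):
        spec, _ = fixture_scenario("thermostated", M=60)
        pre = check_preconditions(spec)
        assert pre["all_passed"]
        assert pre["A_outgoing_mean_max"] <= 1e-10

    def test_preconditions_flag_biased_transition(self):
        from conftest import make_spec
        from ktap.model import ActivityGrid, make_gaussian_transition

        A = make_gaussian_transition(ActivityGrid(-1.0, 1.0, 30), 0.3, 0.2)
        spec = make_spec(M=30, A=A)
        pre = check_preconditions(spec)
        assert not pre["all_passed"]
        assert not pre["A_zero_mean"]

    def test_sign_adjudication_prefers_damping_variant(self):
        """The kinetic E1 decays without forcing; only the damping sign tracks it."""
        spec, f0 = fixture_scenario("skewed-decay", M=60)
        cfg = RunConfig(t_end=3.0, dt_max=0.02, record_every=10)
        report = adjudicate_sign(spec, f0, cfg)
        assert report["matching_mode"] == "damping"
        assert report["damping_max_rel_discrepancy"] <= 0.01
        assert report["growth_max_rel_discrepancy"] > 0.1
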