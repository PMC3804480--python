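"""Right-hand-side operators of the controlled hybrid kinetic equation.

For each population i the density f_i evolves under

    d_t f_i + d_u( F_i(u) f_i - T_i[F_i, f] ) = sum_j ( G_ij - L_ij + N_ij )

with the gain G, loss L and nonconservative N interaction operators and the
isokinetic-thermostat damping T_i = u F_i(u) f_i(u) E1[f], where E1 is the
instantaneous first velocity-activity moment.  The left-side divergence is
discretized in conservative finite-volume form with first-order upwind
fluxes and zero ghost states (densities vanish at the domain boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericalError
from .model import GeneralTransition, ModelSpec, StateDistribution
from .moments import moment_pq


@dataclass
class OperatorField:
    """An operator evaluated at all (population, cell) points."""

    values: np.ndarray  # (n, M)
    label: str


def _loss_weights(f: StateDistribution, spec: ModelSpec) -> np.ndarray:
    """W[i, k] = sum_j sum_k2 iota[i,j,k,k2] f_j(k2) du — encounter frequency."""
    return np.einsum("ijab,jb->ia", spec.kernels.iota, f.values) * spec.grid.du


def gain(f: StateDistribution, spec: ModelSpec) -> OperatorField:
    """Gain operator: candidate cells transitioning into activity u_k.

    G_i(u_k) = sum_j sum_{k1,k2} iota(u_k1,u_k2) A(u_k1,u_k2,u_k)
               f_i(u_k1) f_j(u_k2) du^2.

    When the transition density is separable the double sum factorizes into
    the outgoing profile times the per-population interaction mass
    (O(M^2) per pair); the general path evaluates the full contraction.
    Both paths agree to roundoff.
    """
    spec.check_state(f)
    du = spec.grid.du
    A = spec.kernels.A
    if A.is_separable:
        W = _loss_weights(f, spec)
        g_i = (f.values * W).sum(axis=1) * du  # total interaction mass per i
        vals = np.outer(g_i, A.values)
        return OperatorField(vals, "gain")
    assert isinstance(A, GeneralTransition)
    n = spec.n
    vals = np.zeros_like(f.values)
    for i in range(n):
        # weight over incoming pairs, summed across field populations j
        w = np.einsum(
            "jab,a,jb->ab", spec.kernels.iota[i], f.values[i], f.values
        )
        vals[i] = np.einsum("ab,abk->k", w, A.values) * du * du
    return OperatorField(vals, "gain")


def loss(f: StateDistribution, spec: ModelSpec) -> OperatorField:
    """Loss operator: L_i(u_k) = f_i(u_k) sum_j integral iota(u_k, u2) f_j(u2) du2."""
    spec.check_state(f)
    return OperatorField(f.values * _loss_weights(f, spec), "loss")


def nonconservative(f: StateDistribution, spec: ModelSpec) -> OperatorField:
    """Net proliferation/destruction at rate pi during encounters.

    N_i(u_k) = f_i(u_k) sum_j integral iota(u_k,u2) pi(u_k,u2) f_j(u2) du2.
    """
    spec.check_state(f)
    W = (
        np.einsum("ijab,jb->ia", spec.kernels.iota * spec.kernels.pi, f.values)
        * spec.grid.du
    )
    return OperatorField(f.values * W, "nonconservative")


def thermostat_term(f: StateDistribution, spec: ModelSpec, E1: float) -> OperatorField:
    """Pointwise thermostat damping T_i(u) = u F_i(u) f_i(u) E1.

    The caller supplies the instantaneous moment E1 so that all operator
    evaluations within one time-step stage share the same value.
    """
    spec.check_state(f)
    u = spec.grid.centers
    vals = np.empty_like(f.values)
    for i in range(spec.n):
        vals[i] = u * spec.force(i, u) * f.values[i] * E1
    return OperatorField(vals, "transport")


def transport_rhs(f: StateDistribution, spec: ModelSpec, E1: float) -> OperatorField:
    """Minus the divergence of the advective flux, in finite-volume form.

    The flux is Phi_i(u) = a_i(u) f_i(u) with face speed
    a_i(u) = F_i(u) (1 - u E1) when the thermostat is on and
    a_i(u) = F_i(u) otherwise.  First-order upwind fluxes with zero ghost
    states preserve total mass up to the (zero-state) boundary flux exactly.
    """
    spec.check_state(f)
    grid = spec.grid
    theta = 1.0 if spec.thermostat_on else 0.0
    vals = np.empty_like(f.values)
    for i in range(spec.n):
        a = spec.force(i, grid.faces) * (1.0 - grid.faces * E1 * theta)
        if not np.all(np.isfinite(a)):
            raise NumericalError(f"non-finite face speed for population {i}")
        fext = np.concatenate(([0.0], f.values[i], [0.0]))
        upwind = np.where(a > 0, fext[:-1], fext[1:])
        flux = a * upwind
        vals[i] = -(flux[1:] - flux[:-1]) / grid.du
    return OperatorField(vals, "transport")


def full_rhs(f: StateDistribution, spec: ModelSpec) -> OperatorField:
    """Complete right-hand side: gain - loss + nonconservative + transport.

    E1 is recomputed from the instantaneous state, so the thermostat acts
    as a state-dependent nonlinearity inside every integrator stage.  With
    F = 0 the transport term vanishes and the equilibrium (unforced)
    framework is recovered; with the thermostat off the forced,
    uncontrolled framework results.
    """
    spec.check_state(f)
    vals = gain(f, spec).values - loss(f, spec).values
    vals += nonconservative(f, spec).values
    if not spec.force.is_zero:
        E1 = moment_pq(f, spec, 1, 1)
        vals += transport_rhs(f, spec, E1).values
    return OperatorField(vals, "full")
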