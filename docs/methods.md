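# Methods

## Model and assumptions

The package integrates a hybrid kinetic framework for interacting cell
populations: velocity is restricted to finitely many scalar values
`v_1..v_n` while the activity variable `u` stays continuous on a bounded
interval `D_u = [u_min, u_max]`.  Space homogeneity is assumed throughout,
so the state is the family `f_i(t, u)` and all observables are activity
moments weighted by powers of the `v_i`.  Binary interactions are
quadratic in `f` and enter through three kernels: the encounter rate
`ι(u₁, u₂) ≥ 0`, the outgoing-activity transition density `𝒜(u₁, u₂, u)`
(unit integral in `u`), and the net birth/death rate `π(u₁, u₂)`.  An
external field `F_i(u)` adds an advective flux in activity; the isokinetic
thermostat multiplies that flux by `(1 − u·E₁[f])`, damping precisely the
component that feeds the activation moment `E₁ = Σ_i v_i ∫ u f_i du`.

The thermostat is implemented exactly in its product form
`T_i = u F_i f_i E₁`, i.e. the advective speed is
`a_i(u) = F_i(u)(1 − u E₁)`.  Other thermostated kinetic formulations
normalize the damping by an energy moment instead; the product form is the
one whose moment identities close into the Riccati equation used here, and
it is what the whole cross-validation layer is built around.

## Discretization

* **Grid.** Uniform cell-centered finite volumes, `M` cells of width `du`;
  midpoint quadrature is used for *every* integral (operators and
  moments), so identities proved by integration by parts hold discretely
  up to the advection scheme's truncation error only.
* **Transition densities** are stored discretely (a length-`M` profile
  when independent of the incoming pair, an `(M, M, M)` table otherwise)
  and renormalized per incoming pair so the discrete unit-integral holds
  to roundoff (≈1e−16, well inside the 1e−12 contract).  This makes the
  gain/loss mass cancellation of conservative interactions exact by
  construction, which is what lets long conservative runs hold `μ` to
  1e−10.
* **Gain evaluation.** For separable densities the double integral
  factorizes into (outgoing profile) × (interaction mass), `O(n²M²)` per
  evaluation; the general path performs the full `O(n²M³)` contraction.
  Both paths agree to roundoff and are cross-checked against a literal
  triple-loop transcription of the operator definitions.
* **Transport.** Conservative finite-volume divergence with first-order
  upwind fluxes selected by the sign of the face speed, and zero ghost
  states outside the domain (the boundary-vanishing hypothesis of the
  moment reduction).  Total mass change telescopes exactly to the
  boundary flux.  First order was chosen deliberately: it is positivity
  friendly, its `O(du)` bias is the quantity the refinement criterion
  measures, and higher-order limiters are out of scope.
* **Time stepping.** Classical RK4 with the thermostat moment `E₁`
  recomputed inside every stage (the thermostat is a state-dependent
  nonlinearity, not a frozen coefficient).  The step size is
  `dt = min(dt_max, cfl·du/max|a|, safety/(ι_max·μ·(1+|π|_max)))`,
  defaults `cfl = 0.8`, `safety = 0.5`: the first bound is the advective
  CFL condition, the second keeps the explicit quadratic-interaction
  update contractive as `μ` grows.

## Degenerate and pathological regimes

* **Blow-up.** With constant `ι, π > 0` the total mass obeys
  `dμ/dt = ιπμ²`, singular at `t* = 1/(ιπμ₀)`.  The integrator detects the
  crossing of a configurable mass threshold and reports `t*` by linear
  extrapolation of the last two samples in `1/μ` (exactly linear for the
  quadratic law); it never regularizes.
* **Negativity.** Transient undershoot below `−1e−10` aborts the run
  (status `negativity_abort`) rather than clipping — clipping would
  silently break the conservation diagnostics.
* **Riccati singularities.** The explicit constant-coefficient trajectory
  `E₁(t) = Ē + 1/λ(t)` is obtained from the integrating-factor solution of
  `λ′ − βλ = F`, `β = c + 2FĒ = √(c² + 4F²μ̄)`.  Initial data below the
  repelling root escape to −∞ in finite time; the singular time is located
  analytically and a `SingularityError` is raised for any requested time
  at or past it.  Time-dependent `μ(t)` (the `π ≠ 0` regime, where the
  "constant solution" premise is internally inconsistent) is refused by
  the closed form and routed to the adaptive ODE solver, which accepts
  arbitrary callables (e.g. interpolants of a simulation's mass series).

## Validity preconditions of the moment reduction

The reduction of the kinetic dynamics to the `E₁` Riccati equation needs,
besides constant `ι, π, F`:

1. **Zero outgoing mean of `𝒜`.**  The gain term contributes
   `(∫u𝒜 du)·(interaction mass)` to `dE₁/dt`; only a zero-mean transition
   density removes it.  The harness checks the discrete mean (≤1e−10)
   before asserting agreement.
2. **Boundary-vanishing densities — dynamically, not just at `t = 0`.**
   The integration by parts behind the `E₁` equation drops the boundary
   term `[u·a_i(u)·f_i]_{∂D_u}`.  The thermostated flux
   `a(u) = F(1 − uE₁)` has its stagnation point at `u* = 1/E₁`; if `u*`
   lies outside `D_u` the advection drains mass through the outflow
   boundary, the term is `O(1)` relative to the retained ones, and the
   reduction fails *at the continuum level* (the measured PDE/ODE gap is
   then grid-independent).  The shipped `thermostated` scenario therefore
   lives on `D_u = [−3, 3]` — comfortably containing `u* = 1/Ē ≈ 1.618`
   for its parameters — with the initial parabola supported on `[−1, 1]`
   and a zero-mean Gaussian `𝒜` (σ = 0.5) whose outgoing support is
   effectively interior, so no gain mass is deposited at the boundary
   during the early transient while the boundary speed is still outward.
   Under these conditions the measured mass leak is ~1e−9 over `t ∈ [0,5]`
   and the PDE/ODE discrepancy is pure first-order truncation error
   (0.67 % at `M = 200`, halving at `M = 400`).

## Scenario catalogue (the synthetic study conditions)

All scenarios use one velocity `v = 1`, constant kernels and `μ₀ = 1`:

| name | domain | ι | π | F | thermostat | f₀ ∝ | exercises |
|---|---|---|---|---|---|---|---|
| conservative-uniform | [−1,1] | 1 | 0 | 0 | off | 1 | interaction equilibrium, exact mass conservation |
| proliferative | [−1,1] | 1 | 0.5 | 0 | off | 1 | quadratic blow-up law, singular-time estimate |
| thermostated | [−3,3] | 1 | 0 | 1 | on | (1−u²)₊ | Riccati cross-validation, fixed-point control |
| skewed-decay | [−1,1] | 1 | 0 | 0 | off | (1−u²)(1+u/2) | exponential `E₁` decay, sign adjudication |

These are deterministic desk-scale configurations, not data emulators: they
isolate regimes with exact or closed-form behavior.  They do not probe
multi-population coupling at scale, strongly pair-dependent transition
kernels, or fields with sign changes; passing tests certify the numerics
and the moment identities under the stated hypotheses, not fidelity to any
particular biological dataset.

## The (p, q)-moment equation and its sign

The companion equation for higher moments,
`dE_pq/dt = pF·E_{p,q−1}(μ̃ − E_pq) ± ιμ(1−π)E_pq`, is shipped with both
signs of the interaction term (`sign_mode`): the `growth` variant uses
`+`, the `damping` variant uses the damping `−` of the `E₁`
equation.  The two cannot both be right, and the hierarchy itself does not
decide.  We adjudicate empirically: with `F = 0`, `π = 0` and zero-mean
`𝒜` the kinetic `E₁` decays exactly like `E₁(0)e^{−ιμt}` (the identity is
discretely exact in this regime, agreement ~1e−9); the damping variant
reproduces this and the `+` variant grows as `e^{+ιμt}` (measured
divergence factor ≈ e^{2t}).  The default is therefore
`damping`, with the growth variant retained for completeness.

## Problem sizes

Default test and validation runs use `M = 100–400` cells, `t_end = 5–10`,
and one or two populations — sizes at which every closed-form comparison
resolves well below its tolerance while the whole suite stays desk-scale.
The separable gain path makes the flagship `M = 400` cross-validation run
in seconds; the `O(M³)` general path is reserved for small oracle grids.

## Known limitations

* First-order advection dominates the error budget; the `E₁` bias at the
  thermostated fixed point is `O(du)` (≈0.7 % at `du = 0.03`).
* `steady_state` approximates stationary profiles by long-time relaxation
  only; no direct nonlinear solve of the stationary problem is attempted.
* Transition densities are shared across population pairs; per-pair
  densities would need the `(i, j)`-indexed general table.
* Velocities are scalars; vector-valued velocity sets and space-dependent
  states are out of scope.
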