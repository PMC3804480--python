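"""Domain types for the hybrid kinetic state space.

A population of cells ("active particles") is described by a distribution
over a microscopic state that couples a *discrete* velocity value with a
*continuous* activity variable u.  Under space homogeneity the state reduces
to a finite family of one-dimensional densities f_i(t, u), one per velocity
value v_i, discretized here by finite volumes on a uniform activity grid.

Binary interactions are parameterized by three kernels:

* ``iota(u1, u2)`` — nonnegative encounter rate between a candidate cell at
  activity u1 and a field cell at activity u2;
* ``A(u1, u2, u)`` — transition probability density over the outgoing
  activity u of the candidate cell, normalized so that its integral over u
  is exactly 1 for every incoming pair;
* ``pi(u1, u2)`` — net birth/death rate (may be negative) of the
  nonconservative part of the encounter.

An external field F_i(u) drives the system away from equilibrium; a
Gaussian-type isokinetic thermostat (a damping term proportional to the
first activity moment) can be switched on to control the activation moment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Callable, Sequence

import numpy as np

from .errors import (
    CatalogueError,
    DimensionError,
    InvalidGridError,
    ParameterError,
)

#: Tolerance for transient negative undershoot of the discrete density.
#: Values below ``-TOL_NEG`` abort a simulation rather than being clipped.
TOL_NEG = 1e-10


@dataclass(frozen=True)
class ActivityGrid:
    """Uniform cell-centered grid on the bounded activity domain [u_min, u_max].

    Cell k spans ``[u_min + k*du, u_min + (k+1)*du]`` with midpoint
    ``centers[k] = u_min + (k + 1/2) * du``.  Midpoint (cell-center)
    quadrature is used throughout the library, so all moment and operator
    integrals share the same discrete measure ``du``.
    """

    u_min: float
    u_max: float
    M: int

    def __post_init__(self):
        if self.M < 1:
            raise InvalidGridError(f"grid needs at least one cell, got M={self.M}")
        if not (self.u_min < self.u_max):
            raise InvalidGridError(
                f"degenerate activity domain [{self.u_min}, {self.u_max}]"
            )
        if not (math.isfinite(self.u_min) and math.isfinite(self.u_max)):
            raise InvalidGridError("activity domain bounds must be finite")

    @property
    def du(self) -> float:
        return (self.u_max - self.u_min) / self.M

    @property
    def width(self) -> float:
        return self.u_max - self.u_min

    @cached_property
    def centers(self) -> np.ndarray:
        return self.u_min + (np.arange(self.M) + 0.5) * self.du

    @cached_property
    def faces(self) -> np.ndarray:
        """The M+1 cell interfaces, including the two domain boundaries."""
        return self.u_min + np.arange(self.M + 1) * self.du


@dataclass(frozen=True)
class VelocitySet:
    """The discrete velocity values v_1..v_n (scalars).

    Only powers v_i^p of the values enter the moment functionals, so the
    velocities are represented as scalars even though the underlying
    microscopic velocity may live in a higher-dimensional space.
    """

    values: np.ndarray

    def __init__(self, values: Sequence[float]):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ParameterError("velocity set must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(arr)):
            raise ParameterError("velocity values must be finite")
        if len(np.unique(arr)) < arr.size:
            warnings.warn("duplicate velocity values", stacklevel=2)
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return self.values.size


def _renormalize_columns(values: np.ndarray, du: float, axis: int = -1) -> np.ndarray:
    """Scale so the discrete integral over the outgoing axis is 1 exactly.

    Two normalization passes push the residual |sum*du - 1| to the level of
    a single rounding error, which makes the gain/loss mass cancellation of
    conservative interactions exact to roundoff.
    """
    out = np.array(values, dtype=float)
    if np.any(out < 0):
        raise ParameterError("transition density must be nonnegative")
    for _ in range(3):
        s = out.sum(axis=axis, keepdims=True) * du
        if np.any(s <= 0):
            raise ParameterError("transition density column integrates to zero")
        out = out / s
        err = np.max(np.abs(out.sum(axis=axis, keepdims=True) * du - 1.0))
        if err < 1e-15:
            break
    return out


class TransitionDensity:
    """Discrete transition probability density over the outgoing activity.

    For every incoming pair (u1, u2) the density is a vector of length M on
    the activity grid with ``sum_k A[k] * du == 1`` exactly (to roundoff).
    """

    grid: ActivityGrid
    is_separable: bool

    def column(self, k1: int, k2: int) -> np.ndarray:
        """Density vector for incoming cell indices (k1, k2)."""
        raise NotImplementedError

    def normalization_error(self) -> float:
        """Max over incoming pairs of |sum_k A[k] du - 1|."""
        raise NotImplementedError

    def outgoing_mean_max(self) -> float:
        """Max over incoming pairs of |sum_k u_k A[k] du|.

        A zero outgoing mean is the validity precondition under which the
        gain operator contributes nothing to the first activity moment —
        the hypothesis behind the Riccati moment equation.
        """
        raise NotImplementedError

    def min_value(self) -> float:
        raise NotImplementedError


class SeparableTransition(TransitionDensity):
    """Transition density independent of the incoming pair (u1, u2).

    Stores a single length-M vector shared by all incoming pairs; the gain
    operator then factorizes into (outgoing profile) x (interaction mass),
    reducing its cost from O(M^3) to O(M^2) per population pair.
    """

    is_separable = True

    def __init__(self, grid: ActivityGrid, values: np.ndarray):
        self.grid = grid
        vals = np.asarray(values, dtype=float)
        if vals.shape != (grid.M,):
            raise DimensionError(
                f"separable transition needs shape ({grid.M},), got {vals.shape}"
            )
        self.values = _renormalize_columns(vals, grid.du)
        self.values.flags.writeable = False

    def column(self, k1: int, k2: int) -> np.ndarray:
        return self.values

    def normalization_error(self) -> float:
        return abs(math.fsum(self.values) * self.grid.du - 1.0)

    def outgoing_mean_max(self) -> float:
        return abs(math.fsum(self.values * self.grid.centers) * self.grid.du)

    def min_value(self) -> float:
        return float(self.values.min())


class GeneralTransition(TransitionDensity):
    """Transition density with full (u1, u2) dependence.

    Stores an (M, M, M) array ``values[k1, k2, k]``; memory grows as M^3,
    so this representation is intended for modest grids.
    """

    is_separable = False

    def __init__(self, grid: ActivityGrid, values: np.ndarray):
        self.grid = grid
        vals = np.asarray(values, dtype=float)
        if vals.shape != (grid.M, grid.M, grid.M):
            raise DimensionError(
                f"general transition needs shape {(grid.M,) * 3}, got {vals.shape}"
            )
        self.values = _renormalize_columns(vals, grid.du, axis=2)
        self.values.flags.writeable = False

    def column(self, k1: int, k2: int) -> np.ndarray:
        return self.values[k1, k2]

    def normalization_error(self) -> float:
        return float(np.abs(self.values.sum(axis=2) * self.grid.du - 1.0).max())

    def outgoing_mean_max(self) -> float:
        means = (self.values * self.grid.centers).sum(axis=2) * self.grid.du
        return float(np.abs(means).max())

    def min_value(self) -> float:
        return float(self.values.min())


def make_uniform_transition(grid: ActivityGrid) -> SeparableTransition:
    """Constant transition density 1/(u_max - u_min) in every cell.

    On a symmetric domain its discrete outgoing mean vanishes, which is the
    canonical zero-mean kernel used by the moment-equation cross-checks.
    """
    return SeparableTransition(grid, np.full(grid.M, 1.0 / grid.width))


def make_gaussian_transition(
    grid: ActivityGrid,
    center_map: float | Callable[[np.ndarray, np.ndarray], np.ndarray] = 0.0,
    sigma: float = 0.25,
) -> TransitionDensity:
    """Truncated bell-shaped transition density, renormalized per column.

    ``center_map`` is either a constant (yielding a separable density) or a
    callable ``(u1, u2) -> center`` evaluated on the grid (yielding a full
    (M, M, M) density).  ``sigma`` is the pre-truncation standard deviation
    in activity units.
    """
    if not (sigma > 0):
        raise ParameterError(f"sigma must be positive, got {sigma}")
    u = grid.centers
    if callable(center_map):
        u1 = u[:, None]
        u2 = u[None, :]
        c = np.broadcast_to(np.asarray(center_map(u1, u2), dtype=float), (grid.M, grid.M))
        if np.any(c < grid.u_min) or np.any(c > grid.u_max):
            warnings.warn(
                "transition center outside the activity domain; "
                "density is renormalized on the truncated support",
                stacklevel=2,
            )
        vals = np.exp(-0.5 * ((u[None, None, :] - c[:, :, None]) / sigma) ** 2)
        return GeneralTransition(grid, vals)
    c0 = float(center_map)
    if not (grid.u_min <= c0 <= grid.u_max):
        warnings.warn(
            "transition center outside the activity domain; "
            "density is renormalized on the truncated support",
            stacklevel=2,
        )
    vals = np.exp(-0.5 * ((u - c0) / sigma) ** 2)
    return SeparableTransition(grid, vals)


def _kernel_table(
    grid: ActivityGrid,
    n: int,
    value: float | Callable[[np.ndarray, np.ndarray], np.ndarray] | np.ndarray,
) -> tuple[np.ndarray, float | None]:
    """Tabulate a scalar kernel on the (n, n, M, M) incoming-pair grid.

    Returns the table and, when the kernel is a constant, that constant
    (used by the moment layer to check the constant-coefficient hypothesis).
    """
    M = grid.M
    if np.isscalar(value):
        v = float(value)
        return np.full((n, n, M, M), v), v
    if callable(value):
        u1 = grid.centers[:, None]
        u2 = grid.centers[None, :]
        tab = np.broadcast_to(np.asarray(value(u1, u2), dtype=float), (M, M))
        out = np.broadcast_to(tab, (n, n, M, M)).copy()
        const = float(tab.flat[0]) if np.all(tab == tab.flat[0]) else None
        return out, const
    arr = np.asarray(value, dtype=float)
    if arr.shape != (n, n, M, M):
        raise DimensionError(
            f"kernel table needs shape {(n, n, M, M)}, got {arr.shape}"
        )
    const = float(arr.flat[0]) if np.all(arr == arr.flat[0]) else None
    return arr.copy(), const


@dataclass
class InteractionKernels:
    """Tabulated interaction kernels on the activity grid.

    ``iota`` and ``pi`` are (n, n, M, M) tables indexed by (i, j, k1, k2);
    ``A`` is a :class:`TransitionDensity` shared across population pairs.
    ``iota_constant`` / ``pi_constant`` record the constant value when the
    kernel is constant, else None.
    """

    iota: np.ndarray
    A: TransitionDensity
    pi: np.ndarray
    iota_constant: float | None = None
    pi_constant: float | None = None

    @classmethod
    def build(
        cls,
        grid: ActivityGrid,
        n: int,
        iota: float | Callable | np.ndarray = 1.0,
        A: TransitionDensity | None = None,
        pi: float | Callable | np.ndarray = 0.0,
    ) -> "InteractionKernels":
        iota_tab, iota_const = _kernel_table(grid, n, iota)
        pi_tab, pi_const = _kernel_table(grid, n, pi)
        if A is None:
            A = make_uniform_transition(grid)
        if A.grid.M != grid.M:
            raise DimensionError("transition density grid does not match model grid")
        return cls(iota_tab, A, pi_tab, iota_const, pi_const)


@dataclass
class ForceField:
    """External field F_i(u) acting on population i."""

    fn: Callable[[int, np.ndarray], np.ndarray]
    is_constant: bool = False
    constant_value: float = 0.0

    @classmethod
    def constant(cls, value: float) -> "ForceField":
        v = float(value)

        def fn(i: int, u: np.ndarray) -> np.ndarray:
            return np.full_like(np.asarray(u, dtype=float), v)

        return cls(fn, is_constant=True, constant_value=v)

    @classmethod
    def from_callable(cls, fn: Callable[[int, np.ndarray], np.ndarray]) -> "ForceField":
        return cls(fn, is_constant=False)

    def __call__(self, i: int, u: np.ndarray) -> np.ndarray:
        out = np.asarray(self.fn(i, np.asarray(u, dtype=float)), dtype=float)
        if not np.all(np.isfinite(out)):
            raise ParameterError(f"force field non-finite for population {i}")
        return out

    @property
    def is_zero(self) -> bool:
        return self.is_constant and self.constant_value == 0.0


@dataclass
class StateDistribution:
    """Cell-averaged values of the densities f_i(t, u) on the activity grid.

    ``values`` has shape (n, M); entry (i, k) approximates f_i(t, u_k) at
    the cell midpoint u_k.
    """

    values: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("state values must be a 2-d (n, M) array")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "StateDistribution":
        return StateDistribution(self.values.copy(), self.time)

    def min(self) -> float:
        return float(self.values.min())


@dataclass
class ModelSpec:
    """Complete parameterization of the controlled hybrid kinetic model."""

    grid: ActivityGrid
    velocities: VelocitySet
    kernels: InteractionKernels
    force: ForceField
    thermostat_on: bool = False

    def __post_init__(self):
        n, M = self.velocities.n, self.grid.M
        if self.kernels.iota.shape != (n, n, M, M):
            raise DimensionError(
                f"iota table shape {self.kernels.iota.shape} inconsistent with "
                f"n={n}, M={M}"
            )
        if self.kernels.pi.shape != (n, n, M, M):
            raise DimensionError(
                f"pi table shape {self.kernels.pi.shape} inconsistent with "
                f"n={n}, M={M}"
            )
        if self.kernels.A.grid.M != M:
            raise DimensionError("transition density grid inconsistent with model grid")
        # force must be evaluable and finite at centers and faces
        for i in range(n):
            self.force(i, self.grid.centers)
            self.force(i, self.grid.faces)

    @property
    def n(self) -> int:
        return self.velocities.n

    @property
    def M(self) -> int:
        return self.grid.M

    def check_state(self, f: StateDistribution) -> None:
        if f.values.shape != (self.n, self.M):
            raise DimensionError(
                f"state shape {f.values.shape} does not match model "
                f"({self.n}, {self.M})"
            )


@dataclass
class ValidationReport:
    """Outcome of sampled kernel checks (normalization, nonnegativity)."""

    n_samples: int
    max_normalization_error: float
    min_iota: float
    min_A: float
    failures: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failures


def validate_model(spec: ModelSpec, n_samples: int = 20, seed: int = 0) -> ValidationReport:
    """Sampled check of the kernel contracts.

    Draws ``n_samples`` seeded (i, j, k1, k2) tuples and verifies, for each,
    the discrete unit-integral of the transition density (tolerance 1e-12)
    and the nonnegativity of iota and A.  Failures are listed in the report
    rather than raised.
    """
    rng = np.random.default_rng(seed)
    du = spec.grid.du
    max_err = 0.0
    min_iota = math.inf
    min_A = math.inf
    for _ in range(n_samples):
        i = int(rng.integers(spec.n))
        j = int(rng.integers(spec.n))
        k1 = int(rng.integers(spec.M))
        k2 = int(rng.integers(spec.M))
        col = spec.kernels.A.column(k1, k2)
        max_err = max(max_err, abs(math.fsum(col) * du - 1.0))
        min_A = min(min_A, float(col.min()))
        min_iota = min(min_iota, float(spec.kernels.iota[i, j, k1, k2]))
    failures = []
    if max_err > 1e-12:
        failures.append(
            f"transition density normalization error {max_err:.3e} exceeds 1e-12"
        )
    if min_A < 0:
        failures.append(f"negative transition density value {min_A:.3e}")
    if min_iota < 0:
        failures.append(f"negative interaction rate {min_iota:.3e}")
    return ValidationReport(n_samples, max_err, min_iota, min_A, failures)


def _normalized_profile(grid: ActivityGrid, raw: np.ndarray, mass: float = 1.0) -> np.ndarray:
    """Scale a nonnegative profile so its discrete integral equals ``mass``."""
    total = math.fsum(raw) * grid.du
    if total <= 0:
        raise ParameterError("initial profile has nonpositive mass")
    return raw * (mass / total)


#: Names accepted by :func:`fixture_scenario`.
FIXTURE_NAMES = (
    "conservative-uniform",
    "proliferative",
    "thermostated",
    "skewed-decay",
)


def fixture_scenario(name: str, M: int = 100) -> tuple[ModelSpec, StateDistribution]:
    """Canonical, analytically tractable scenarios used across the test bed.

    All scenarios use a single velocity v = 1, constant kernels and a
    zero-mean transition density:

    * ``conservative-uniform`` — D_u=[-1,1], iota=1, pi=0, F=0, f(u)=0.5
      (an interaction equilibrium with total mass mu = 1);
    * ``proliferative`` — same but pi=0.5, so the total mass obeys the
      quadratic blow-up law mu(t) = 1/(1 - 0.5 t);
    * ``thermostated`` — iota=1, pi=0, F=1 with the thermostat on, the even
      initial profile f(u) ∝ (1 - u²)₊ (supported on [-1, 1]) normalized to
      mu = 1, and a zero-mean Gaussian transition density (sigma = 0.5,
      centered at 0) on the wider domain D_u=[-3,3]; the setting of the
      Riccati moment cross-validation.  The domain must contain the
      thermostat's stagnation point u* = 1/E1 (≈ 1.618 at the fixed point
      here) and both the initial data and the transition support must stay
      interior, otherwise mass drains through the boundary and the
      boundary-vanishing hypothesis behind the moment reduction fails;
    * ``skewed-decay`` — D_u=[-1,1], iota=1, pi=0, F=0 with the skewed
      profile f(u) ∝ (1 - u²)(1 + u/2) normalized to mu = 1, whose first
      moment decays exponentially under conservative interactions.

    Scenario construction is pure arithmetic, hence bit-for-bit
    deterministic.
    """
    if name == "thermostated":
        grid = ActivityGrid(-3.0, 3.0, M)
    else:
        grid = ActivityGrid(-1.0, 1.0, M)
    vel = VelocitySet([1.0])
    u = grid.centers
    if name == "conservative-uniform":
        kern = InteractionKernels.build(grid, 1, iota=1.0, pi=0.0)
        spec = ModelSpec(grid, vel, kern, ForceField.constant(0.0), thermostat_on=False)
        f0 = np.full((1, M), 0.5)
    elif name == "proliferative":
        kern = InteractionKernels.build(grid, 1, iota=1.0, pi=0.5)
        spec = ModelSpec(grid, vel, kern, ForceField.constant(0.0), thermostat_on=False)
        f0 = np.full((1, M), 0.5)
    elif name == "thermostated":
        A = make_gaussian_transition(grid, 0.0, sigma=0.5)
        kern = InteractionKernels.build(grid, 1, iota=1.0, A=A, pi=0.0)
        spec = ModelSpec(grid, vel, kern, ForceField.constant(1.0), thermostat_on=True)
        raw = np.where(np.abs(u) <= 1.0, 1.0 - u**2, 0.0)
        f0 = _normalized_profile(grid, raw)[None, :]
    elif name == "skewed-decay":
        kern = InteractionKernels.build(grid, 1, iota=1.0, pi=0.0)
        spec = ModelSpec(grid, vel, kern, ForceField.constant(0.0), thermostat_on=False)
        f0 = _normalized_profile(grid, (1.0 - u**2) * (1.0 + 0.5 * u))[None, :]
    else:
        raise CatalogueError(
            f"unknown scenario {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        )
    return spec, StateDistribution(f0, time=0.0)
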