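import numpy as np
import pytest

from ktap.model import (
    ActivityGrid,
    ForceField,
    InteractionKernels,
    ModelSpec,
    StateDistribution,
    TransitionDensity,
    VelocitySet,
)


def make_spec(
    u_min=-1.0,
    u_max=1.0,
    M=8,
    velocities=(1.0,),
    iota=1.0,
    pi=0.0,
    F=0.0,
    A: TransitionDensity | None = None,
    thermostat=False,
) -> ModelSpec:
    """Small custom model for operator-level tests."""
    grid = ActivityGrid(u_min, u_max, M)
    vel = VelocitySet(list(velocities))
    kern = InteractionKernels.build(grid, vel.n, iota=iota, A=A, pi=pi)
    force = F if isinstance(F, ForceField) else ForceField.constant(F)
    return ModelSpec(grid, vel, kern, force, thermostat_on=thermostat)


def random_state(spec: ModelSpec, seed=0, zero_boundary_cells=0) -> StateDistribution:
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0.1, 1.0, size=(spec.n, spec.M))
    if zero_boundary_cells:
        vals[:, :zero_boundary_cells] = 0.0
        vals[:, -zero_boundary_cells:] = 0.0
    return StateDistribution(vals, time=0.0)


@pytest.fixture
def conservative_uniform():
    from ktap.model import fixture_scenario

    return fixture_scenario("conservative-uniform")
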