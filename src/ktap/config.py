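"""Config-file parsing and validation.

Model runs are described by a YAML document with the sections ``grid``,
``velocities``, ``kernels``, ``force``, ``thermostat``, ``initial`` and
``run``.  Scalar kernels accept either a number or an expression in the
mini-language of :mod:`ktap._expr` (variables ``u1``, ``u2`` for kernels,
``u`` for the force and the initial profile).  Unknown keys are rejected;
every validation failure names the offending key path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any

import numpy as np
import yaml

from ._expr import compile_expression
from .errors import ConfigError
from .model import (
    ActivityGrid,
    ForceField,
    InteractionKernels,
    ModelSpec,
    StateDistribution,
    TransitionDensity,
    VelocitySet,
    make_gaussian_transition,
    make_uniform_transition,
    _normalized_profile,
)
from .simulator import RunConfig

_RUN_DEFAULTS: dict[str, Any] = {
    "t_end": 5.0,
    "dt_max": 0.1,
    "cfl": 0.8,
    "record_every": 10,
    "blowup_mass": 1e6,
    "seed": 0,
    "safety": 0.5,
}

_INITIAL_KINDS = ("uniform", "parabolic", "expression")


@dataclass
class LoadedConfig:
    """Fully validated run description."""

    spec: ModelSpec
    initial: StateDistribution
    run: RunConfig
    tree: dict


def _require_mapping(node: Any, path: str) -> dict:
    if node is None:
        return {}
    if not isinstance(node, dict):
        raise ConfigError("type-mismatch", path, "expected a mapping")
    return node


def _reject_unknown(node: dict, allowed: set[str], path: str) -> None:
    for key in node:
        if key not in allowed:
            raise ConfigError("unknown-key", f"{path}.{key}" if path else str(key))


def _number(node: Any, path: str) -> float:
    if isinstance(node, bool) or not isinstance(node, (int, float)):
        raise ConfigError("type-mismatch", path, f"expected a number, got {node!r}")
    if not math.isfinite(float(node)):
        raise ConfigError("range-violation", path, "must be finite")
    return float(node)


def _integer(node: Any, path: str) -> int:
    if isinstance(node, bool) or not isinstance(node, int):
        raise ConfigError("type-mismatch", path, f"expected an integer, got {node!r}")
    return node


def _scalar_or_expr(node: Any, variables: tuple[str, ...], path: str):
    """A kernel entry: plain number or mini-language expression string."""
    if isinstance(node, str):
        return compile_expression(node, variables, path)
    return _number(node, path)


def _parse_grid(node: Any) -> ActivityGrid:
    node = _require_mapping(node, "grid")
    _reject_unknown(node, {"u_min", "u_max", "M"}, "grid")
    for key in ("u_min", "u_max", "M"):
        if key not in node:
            raise ConfigError("missing-key", f"grid.{key}")
    u_min = _number(node["u_min"], "grid.u_min")
    u_max = _number(node["u_max"], "grid.u_max")
    M = _integer(node["M"], "grid.M")
    if M < 4:
        raise ConfigError("range-violation", "grid.M", f"must be >= 4, got {M}")
    if not (u_min < u_max):
        raise ConfigError("range-violation", "grid.u_min", "u_min must be < u_max")
    return ActivityGrid(u_min, u_max, M)


def _parse_velocities(node: Any) -> VelocitySet:
    if not isinstance(node, list) or not node:
        raise ConfigError("type-mismatch", "velocities", "expected a non-empty list")
    return VelocitySet([_number(v, f"velocities[{i}]") for i, v in enumerate(node)])


def _parse_transition(node: Any, grid: ActivityGrid) -> TransitionDensity:
    if node is None or node == "uniform":
        return make_uniform_transition(grid)
    node = _require_mapping(node, "kernels.A")
    _reject_unknown(node, {"kind", "sigma", "center"}, "kernels.A")
    kind = node.get("kind")
    if kind == "uniform":
        return make_uniform_transition(grid)
    if kind == "gaussian":
        if "sigma" not in node:
            raise ConfigError("missing-key", "kernels.A.sigma")
        sigma = _number(node["sigma"], "kernels.A.sigma")
        if sigma <= 0:
            raise ConfigError("range-violation", "kernels.A.sigma", "must be > 0")
        center = node.get("center", 0.0)
        if isinstance(center, str):
            cfun = compile_expression(center, ("u1", "u2"), "kernels.A.center")
            return make_gaussian_transition(
                grid, lambda u1, u2: cfun(u1=u1, u2=u2), sigma
            )
        return make_gaussian_transition(grid, _number(center, "kernels.A.center"), sigma)
    raise ConfigError(
        "range-violation", "kernels.A.kind", f"must be uniform or gaussian, got {kind!r}"
    )


def _parse_kernels(node: Any, grid: ActivityGrid, n: int) -> InteractionKernels:
    node = _require_mapping(node, "kernels")
    _reject_unknown(node, {"iota", "A", "pi"}, "kernels")
    iota = _scalar_or_expr(node.get("iota", 1.0), ("u1", "u2"), "kernels.iota")
    pi_rate = _scalar_or_expr(node.get("pi", 0.0), ("u1", "u2"), "kernels.pi")
    A = _parse_transition(node.get("A"), grid)

    def wrap(val):
        if callable(val):
            return lambda u1, u2: val(u1=u1, u2=u2)
        return val

    return InteractionKernels.build(grid, n, iota=wrap(iota), A=A, pi=wrap(pi_rate))


def _parse_force(node: Any) -> ForceField:
    if node is None:
        return ForceField.constant(0.0)
    if isinstance(node, str):
        fn = compile_expression(node, ("u",), "force")
        return ForceField.from_callable(lambda i, u: fn(u=u))
    return ForceField.constant(_number(node, "force"))


def _parse_thermostat(node: Any) -> bool:
    if node is None:
        return False
    if isinstance(node, bool):
        return node
    if node in ("on", "off"):
        return node == "on"
    raise ConfigError("type-mismatch", "thermostat", "expected on/off or boolean")


def _parse_initial(node: Any, grid: ActivityGrid, n: int) -> StateDistribution:
    node = _require_mapping(node, "initial")
    _reject_unknown(
        node, {"kind", "mass", "expr", "support_min", "support_max"}, "initial"
    )
    kind = node.get("kind", "uniform")
    if kind not in _INITIAL_KINDS:
        raise ConfigError(
            "range-violation",
            "initial.kind",
            f"must be one of {', '.join(_INITIAL_KINDS)}, got {kind!r}",
        )
    mass = _number(node.get("mass", 1.0), "initial.mass")
    if mass <= 0:
        raise ConfigError("range-violation", "initial.mass", "must be > 0")
    u = grid.centers
    if kind == "uniform":
        raw = np.ones(grid.M)
    elif kind == "parabolic":
        # parabola vanishing at the support edges (defaults: the domain
        # boundaries), zero outside — respects the zero-boundary hypothesis
        lo = _number(node.get("support_min", grid.u_min), "initial.support_min")
        hi = _number(node.get("support_max", grid.u_max), "initial.support_max")
        if not (grid.u_min <= lo < hi <= grid.u_max):
            raise ConfigError(
                "range-violation", "initial.support_min",
                "support must be a nondegenerate subinterval of the domain",
            )
        s = (2.0 * u - (lo + hi)) / (hi - lo)
        raw = np.maximum(1.0 - s * s, 0.0)
    else:
        if "expr" not in node:
            raise ConfigError("missing-key", "initial.expr")
        fn = compile_expression(node["expr"], ("u",), "initial.expr")
        raw = np.asarray(fn(u=u), dtype=float)
        if np.any(raw < 0):
            raise ConfigError("range-violation", "initial.expr", "profile must be >= 0")
    per_pop = _normalized_profile(grid, raw, mass / n)
    return StateDistribution(np.tile(per_pop, (n, 1)), time=0.0)


def _parse_run(node: Any) -> RunConfig:
    node = _require_mapping(node, "run")
    _reject_unknown(node, set(_RUN_DEFAULTS), "run")
    merged = dict(_RUN_DEFAULTS)
    merged.update(node)
    t_end = _number(merged["t_end"], "run.t_end")
    if t_end <= 0:
        raise ConfigError("range-violation", "run.t_end", "must be > 0")
    dt_max = merged["dt_max"]
    dt_max = None if dt_max is None else _number(dt_max, "run.dt_max")
    cfl = _number(merged["cfl"], "run.cfl")
    if not (0 < cfl <= 1):
        raise ConfigError("range-violation", "run.cfl", f"must be in (0, 1], got {cfl}")
    record_every = _integer(merged["record_every"], "run.record_every")
    if record_every < 1:
        raise ConfigError("range-violation", "run.record_every", "must be >= 1")
    return RunConfig(
        t_end=t_end,
        dt_max=dt_max,
        cfl=cfl,
        record_every=record_every,
        blowup_mass=_number(merged["blowup_mass"], "run.blowup_mass"),
        seed=_integer(merged["seed"], "run.seed"),
        safety=_number(merged["safety"], "run.safety"),
    )


_TOP_KEYS = {"grid", "velocities", "kernels", "force", "thermostat", "initial", "run"}


def parse_config_tree(tree: dict) -> LoadedConfig:
    """Validate a raw key-value tree and build the model objects."""
    tree = _require_mapping(tree, "")
    _reject_unknown(tree, _TOP_KEYS, "")
    for key in ("grid", "velocities"):
        if key not in tree:
            raise ConfigError("missing-key", key)
    grid = _parse_grid(tree["grid"])
    vel = _parse_velocities(tree["velocities"])
    kern = _parse_kernels(tree.get("kernels"), grid, vel.n)
    force = _parse_force(tree.get("force"))
    thermo = _parse_thermostat(tree.get("thermostat"))
    spec = ModelSpec(grid, vel, kern, force, thermostat_on=thermo)
    initial = _parse_initial(tree.get("initial"), grid, vel.n)
    run_cfg = _parse_run(tree.get("run"))
    return LoadedConfig(spec=spec, initial=initial, run=run_cfg, tree=tree)


def load_config(path) -> LoadedConfig:
    """Load and validate a YAML model configuration file."""
    with open(path) as fh:
        try:
            tree = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError("parse-error", str(path), str(exc)) from None
    return parse_config_tree(tree)


def serialize_config(tree: dict) -> str:
    """Canonical YAML rendering of a config tree (round-trip stable)."""
    return yaml.safe_dump(tree, sort_keys=True, default_flow_style=False)
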