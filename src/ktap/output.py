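"""Result serialization.

All floats are written with 17 significant digits, so two runs with the
same config and seed produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import __version__
from .model import ModelSpec
from .riccati import check_preconditions
from .simulator import RunConfig, RunResult


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def write_final_state(result: RunResult, spec: ModelSpec, path) -> None:
    """Final n x M state as CSV with a one-line grid-metadata header."""
    g = spec.grid
    state = result.final_state
    vels = ";".join(_fmt(v) for v in spec.velocities.values)
    with open(path, "w", newline="") as fh:
        fh.write(
            f"# u_min={_fmt(g.u_min)} u_max={_fmt(g.u_max)} M={g.M} "
            f"t={_fmt(state.time)} velocities={vels}\n"
        )
        fh.write("u," + ",".join(f"f_{i + 1}" for i in range(spec.n)) + "\n")
        for k in range(g.M):
            row = [g.centers[k]] + [state.values[i, k] for i in range(spec.n)]
            fh.write(",".join(_fmt(x) for x in row) + "\n")


def summarize(result: RunResult, spec: ModelSpec, cfg: RunConfig, config_echo: dict | None = None) -> dict:
    """Self-describing run summary, including the moment-reduction checks."""
    rec0 = result.moments.records[0]
    rec1 = result.moments.records[-1]
    return {
        "status": result.status,
        "blowup_time_estimate": result.blowup_time_estimate,
        "min_f_observed": result.min_f_observed,
        "steps": result.steps,
        "t_final": result.final_state.time,
        "mass_initial": rec0.mu,
        "mass_final": rec1.mu,
        "E1_initial": rec0.E1,
        "E1_final": rec1.E1,
        "moment_reduction_checks": check_preconditions(spec),
        "seed": cfg.seed,
        "config": config_echo or {},
        "run_config": {
            "t_end": cfg.t_end,
            "dt_max": cfg.dt_max,
            "cfl": cfg.cfl,
            "record_every": cfg.record_every,
            "blowup_mass": cfg.blowup_mass,
            "safety": cfg.safety,
            "seed": cfg.seed,
        },
        "version": __version__,
    }


def write_results(
    result: RunResult,
    spec: ModelSpec,
    cfg: RunConfig,
    prefix,
    config_echo: dict | None = None,
) -> dict[str, Path]:
    """Write <prefix>_moments.csv, <prefix>_final.csv and <prefix>_summary.json."""
    prefix = Path(prefix)
    if prefix.parent != Path("."):
        prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "moments": prefix.with_name(prefix.name + "_moments.csv"),
        "final": prefix.with_name(prefix.name + "_final.csv"),
        "summary": prefix.with_name(prefix.name + "_summary.json"),
    }
    result.moments.to_csv(paths["moments"])
    write_final_state(result, spec, paths["final"])
    with open(paths["summary"], "w") as fh:
        json.dump(
            summarize(result, spec, cfg, config_echo),
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
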