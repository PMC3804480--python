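"""Moment functionals of the discrete hybrid distribution.

The (p, q)-order moment weights the densities by v_i^p u^q and integrates
over activity with the same midpoint rule used by the interaction
operators, so moment identities obtained by integration by parts hold
discretely up to the advection scheme's truncation error only.

Notation: E_pq = sum_i v_i^p * integral u^q f_i du;  mu_i is the mass of
population i, mu their sum, mu_bar = sum_i v_i mu_i, and
mu_tilde(p) = sum_i v_i^p mu_i.  E_1 := E_{1,1} is the controlled
"activation" moment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ParameterError
from .model import ModelSpec, StateDistribution

#: Moment pairs recorded by default: mass, activation, activation energy.
DEFAULT_PQ = ((0, 0), (1, 1), (2, 2))


def moment_pq(f: StateDistribution, spec: ModelSpec, p: int, q: int) -> float:
    """E_pq = sum_i v_i^p sum_k u_k^q f_i(u_k) du, with the convention 0^0 = 1."""
    if p < 0 or q < 0:
        raise ParameterError(f"moment orders must be nonnegative, got ({p}, {q})")
    spec.check_state(f)
    uq = spec.grid.centers ** q
    per_i = f.values @ uq * spec.grid.du
    vp = spec.velocities.values ** p
    return float(vp @ per_i)


def population_masses(f: StateDistribution, spec: ModelSpec) -> np.ndarray:
    """mu_i = integral of f_i over activity, one entry per population."""
    spec.check_state(f)
    return f.values.sum(axis=1) * spec.grid.du


@dataclass
class MomentRecord:
    """All moment functionals of one state at one time."""

    time: float
    E_pq: dict[tuple[int, int], float]
    mu_i: np.ndarray
    mu: float
    mu_bar: float
    mu_tilde: dict[int, float]

    @property
    def E1(self) -> float:
        return self.E_pq[(1, 1)]


def moment_record(
    f: StateDistribution,
    spec: ModelSpec,
    p_list: Sequence[int] = (0, 1, 2),
    pq_pairs: Iterable[tuple[int, int]] = DEFAULT_PQ,
) -> MomentRecord:
    """Populate a full :class:`MomentRecord` for the current state.

    ``p_list`` selects the velocity orders of mu_tilde; ``pq_pairs`` the
    (p, q) moments.  The pair (1, 1) is always included since the
    thermostat and the Riccati layer are driven by it.
    """
    mu_i = population_masses(f, spec)
    v = spec.velocities.values
    pairs = set(tuple(pq) for pq in pq_pairs) | {(1, 1), (0, 0)}
    E = {pq: moment_pq(f, spec, *pq) for pq in sorted(pairs)}
    mu_tilde = {int(p): float((v ** p) @ mu_i) for p in p_list}
    return MomentRecord(
        time=f.time,
        E_pq=E,
        mu_i=mu_i,
        mu=float(mu_i.sum()),
        mu_bar=float(v @ mu_i),
        mu_tilde=mu_tilde,
    )


@dataclass
class MomentSeries:
    """Time-indexed sequence of :class:`MomentRecord` with CSV export."""

    records: list[MomentRecord] = field(default_factory=list)

    def append(self, rec: MomentRecord) -> None:
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records])

    @property
    def mu(self) -> np.ndarray:
        return np.array([r.mu for r in self.records])

    @property
    def mu_bar(self) -> np.ndarray:
        return np.array([r.mu_bar for r in self.records])

    @property
    def E1(self) -> np.ndarray:
        return np.array([r.E1 for r in self.records])

    def column_names(self) -> list[str]:
        """Deterministic column ordering of the CSV/table form."""
        if not self.records:
            return ["time", "mu", "mu_bar", "E_1_1"]
        r0 = self.records[0]
        cols = ["time", "mu", "mu_bar", "E_1_1"]
        cols += [
            f"E_{p}_{q}" for (p, q) in sorted(r0.E_pq) if (p, q) != (1, 1)
        ]
        cols += [f"mu_tilde_{p}" for p in sorted(r0.mu_tilde)]
        cols += [f"mu_{i + 1}" for i in range(r0.mu_i.size)]
        return cols

    def rows(self) -> list[list[float]]:
        out = []
        for r in self.records:
            row = [r.time, r.mu, r.mu_bar, r.E1]
            row += [r.E_pq[pq] for pq in sorted(r.E_pq) if pq != (1, 1)]
            row += [r.mu_tilde[p] for p in sorted(r.mu_tilde)]
            row += list(r.mu_i)
            out.append(row)
        return out

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows(), columns=self.column_names())

    def to_csv(self, path) -> None:
        """Write with 17 significant digits so repeated runs are byte-identical."""
        with open(path, "w", newline="") as fh:
            fh.write(",".join(self.column_names()) + "\n")
            for row in self.rows():
                fh.write(",".join(f"{x:.17g}" for x in row) + "\n")
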