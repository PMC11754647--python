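"""Multi-objective shape annealing with a Pareto archive.

Competing objectives (two or three; more only with an explicit override,
since the approach has not been validated beyond three) are optimised
jointly: instead of a scalar energy the walk tracks a vector of energies,
and an archive keeps every feasible design not dominated by another.

Acceptance convention (Suppapitnarm-style): a candidate that is not
dominated by the current state and not dominated by any archive member is
accepted outright; otherwise it is accepted with probability
``prod_i exp(-max(0, dE_i) / T_i)`` under per-objective temperatures
cooled on a shared geometric schedule.  Every few stages the walk returns
to a uniformly drawn archive member to spread coverage along the front.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .anneal import AnnealingSchedule, calibrate_t0, next_temperature
from .constraints import ConstraintSet, is_feasible
from .errors import (
    ArityMismatchError,
    ExhaustedRetriesError,
    InfeasibleStartError,
    ObjectiveCountError,
)
from .grammar import RuleSet, apply_random_rule
from .mesh import DesignState, estimate_scaffold_nt
from .objectives import ObjectiveSpec


def dominates(u: Sequence[float], v: Sequence[float]) -> bool:
    """True iff ``u`` Pareto-dominates ``v`` under minimisation.

    Componentwise u <= v with strict improvement in at least one
    component; a vector never dominates itself.
    """
    if len(u) != len(v):
        raise ArityMismatchError(f"objective vectors of arity {len(u)} vs {len(v)}")
    le = all(a <= b for a, b in zip(u, v))
    lt = any(a < b for a, b in zip(u, v))
    return le and lt


@dataclass
class ArchiveEntry:
    state: DesignState
    vector: tuple[float, ...]


class ParetoArchive:
    """Mutually non-dominated set of feasible designs with objective vectors."""

    def __init__(self, capacity: int | None = None):
        self.members: list[ArchiveEntry] = []
        self.capacity = capacity

    def __len__(self) -> int:
        return len(self.members)

    def vectors(self) -> np.ndarray:
        return np.array([m.vector for m in self.members], dtype=float)

    def dominated_by_archive(self, vector: Sequence[float]) -> bool:
        return any(dominates(m.vector, vector) for m in self.members)

    def update(self, state: DesignState, vector: Sequence[float]) -> bool:
        """Insert a candidate; drop members it dominates.

        Returns True iff the candidate entered the archive.  Candidates
        dominated by (or equal to) an existing member are discarded, so
        the mutual non-domination invariant is restored after every call.
        """
        vec = tuple(float(x) for x in vector)
        for m in self.members:
            if dominates(m.vector, vec) or m.vector == vec:
                return False
        self.members = [m for m in self.members if not dominates(vec, m.vector)]
        self.members.append(ArchiveEntry(state, vec))
        if self.capacity is not None and len(self.members) > self.capacity:
            self._prune()
        return True

    def _prune(self) -> None:
        """Crowding-distance pruning in objective space down to capacity."""
        while len(self.members) > self.capacity:
            vecs = self.vectors()
            n, m = vecs.shape
            crowd = np.zeros(n)
            for j in range(m):
                order = np.argsort(vecs[:, j])
                span = vecs[order[-1], j] - vecs[order[0], j]
                crowd[order[0]] = crowd[order[-1]] = math.inf
                if span <= 0:
                    continue
                for r in range(1, n - 1):
                    crowd[order[r]] += (vecs[order[r + 1], j] - vecs[order[r - 1], j]) / span
            drop = int(np.argmin(crowd))
            del self.members[drop]

    def check_invariant(self) -> bool:
        for i, a in enumerate(self.members):
            for j, b in enumerate(self.members):
                if i != j and dominates(a.vector, b.vector):
                    return False
        return True


class MOSATrace:
    """Per-proposal record with the full objective vector."""

    def __init__(self, objective_names: Sequence[str]):
        self.objective_names = tuple(objective_names)
        self.rows: list[tuple] = []

    def record(self, iteration, temperatures, vector, accepted, rule, scaffold_nt,
               archive_size):
        self.rows.append(
            (iteration, *temperatures, *(vector if vector is not None else
                                         (math.nan,) * len(self.objective_names)),
             accepted, rule, scaffold_nt, archive_size)
        )

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        cols = (
            ["iteration"]
            + [f"T_{n}" for n in self.objective_names]
            + list(self.objective_names)
            + ["accepted", "rule", "scaffold_nt", "archive_size"]
        )
        return pd.DataFrame(self.rows, columns=cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class MOSAProblem:
    initial_state: DesignState
    ruleset: RuleSet
    constraints: ConstraintSet
    objectives: Sequence[ObjectiveSpec]
    schedule: AnnealingSchedule = field(default_factory=AnnealingSchedule)
    return_to_base_every: int | None = 5  # stages; None disables
    archive_capacity: int | None = None
    allow_many_objectives: bool = False


@dataclass
class MOSAResult:
    archive: ParetoArchive
    trace: MOSATrace
    t0: tuple[float, ...]
    final_state: DesignState


def run_mosa(problem: MOSAProblem, rng: np.random.Generator) -> MOSAResult:
    """Run multi-objective shape annealing; returns the Pareto archive.

    Seeded determinism mirrors the single-objective optimiser: the whole
    trajectory is a function of (problem, rng).
    """
    n_obj = len(problem.objectives)
    if n_obj < 2 or (n_obj > 3 and not problem.allow_many_objectives):
        raise ObjectiveCountError(
            f"{n_obj} objectives given; multi-objective shape annealing is "
            "validated with two or three (set allow_many_objectives to override)"
        )
    sched = problem.schedule
    state = problem.initial_state
    rep = is_feasible(state, problem.constraints)
    if not rep.feasible:
        raise InfeasibleStartError(f"initial state infeasible: {rep.violations}")

    def vector_of(s: DesignState) -> tuple[float, ...]:
        return tuple(obj.energy(s) for obj in problem.objectives)

    # per-objective initial temperatures from independent calibrations of
    # the same random-walk procedure used by the single-objective optimiser
    temps = tuple(
        calibrate_t0(
            state, problem.ruleset, problem.constraints, obj, rng,
            n_moves=sched.calibration_moves, target=sched.calibration_target,
        )
        for obj in problem.objectives
    )
    t0 = temps

    archive = ParetoArchive(capacity=problem.archive_capacity)
    current_vec = vector_of(state)
    archive.update(state, current_vec)
    trace = MOSATrace([obj.name for obj in problem.objectives])
    stage = 0

    for it in range(1, sched.total_iterations + 1):
        k_cap = sched.effective_k_max(it, problem.ruleset.k_max)
        try:
            app = apply_random_rule(
                state, problem.ruleset, problem.constraints, rng,
                max_retries=sched.max_retries, k_max=k_cap,
            )
        except ExhaustedRetriesError:
            trace.record(it, temps, None, False, "null",
                         estimate_scaffold_nt(state), len(archive))
        else:
            cand_vec = vector_of(app.state)
            if not dominates(current_vec, cand_vec) and not archive.dominated_by_archive(cand_vec):
                accepted = True
            else:
                p = 1.0
                for dE, T in zip(
                    (c - e for c, e in zip(cand_vec, current_vec)), temps
                ):
                    p *= math.exp(-max(0.0, dE) / T)
                accepted = rng.random() < p
            if accepted:
                state, current_vec = app.state, cand_vec
                archive.update(state, current_vec)
            trace.record(it, temps, cand_vec, accepted, app.rule,
                         estimate_scaffold_nt(app.state), len(archive))
        if it % sched.stage_length == 0:
            stage += 1
            temps = tuple(next_temperature(sched, T) for T in temps)
            if (
                problem.return_to_base_every is not None
                and stage % problem.return_to_base_every == 0
                and len(archive) > 0
            ):
                base = archive.members[rng.integers(len(archive.members))]
                state, current_vec = base.state, base.vector

    return MOSAResult(archive, trace, t0, state)
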