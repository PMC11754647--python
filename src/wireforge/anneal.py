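"""Single-objective shape annealing.

The optimiser walks the design space by drawing grammar rules at random,
keeping only feasible candidates, and accepting or rejecting each one by
the Metropolis criterion under a geometrically cooled temperature.  Early,
hot stages accept many objectively worse moves to escape local minima;
late stages, helped by a ramp that shrinks the vertex-extension step to a
single base pair, fine-tune the solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .constraints import ConstraintSet, is_feasible
from .errors import (
    ExhaustedRetriesError,
    InfeasibleStartError,
    NonFiniteEnergyError,
)
from .grammar import RuleSet, apply_random_rule
from .mesh import DesignState, estimate_scaffold_nt
from .objectives import ObjectiveSpec


@dataclass(frozen=True)
class AnnealingSchedule:
    """Geometric cooling schedule with a late extension ramp.

    ``t0 = None`` auto-calibrates the initial temperature so that roughly
    ``calibration_target`` of worsening moves would be accepted over a
    short random walk from the start state.  Temperature multiplies by
    ``alpha`` after every stage of ``stage_length`` proposals.  Over the
    final ``ramp_fraction`` of the run the maximum vertex-extension step
    decays linearly to one base pair.
    """

    t0: float | None = None
    alpha: float = 0.95
    stage_length: int = 50
    total_iterations: int = 20000
    ramp_fraction: float = 0.3
    stall_stages: int | None = 3
    calibration_target: float = 0.8
    calibration_moves: int = 100
    max_retries: int = 25

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.t0 is not None and self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if not 0 <= self.ramp_fraction < 1:
            raise ValueError("ramp_fraction must lie in [0, 1)")

    def effective_k_max(self, iteration: int, k_max: int) -> int:
        """Extension cap at a given iteration, after the ramp."""
        frac = iteration / max(self.total_iterations, 1)
        start = 1.0 - self.ramp_fraction
        if frac <= start or self.ramp_fraction == 0:
            return k_max
        t = (frac - start) / self.ramp_fraction
        return max(1, int(round(k_max + (1 - k_max) * min(t, 1.0))))


def metropolis_accept(
    E_new: float, E_old: float, T: float, rng: np.random.Generator
) -> bool:
    """Metropolis criterion (minimisation): always take improvements,
    otherwise accept with probability exp(-(E_new - E_old) / T) against a
    uniform draw in (0, 1)."""
    if not (math.isfinite(E_new) and math.isfinite(E_old)):
        raise NonFiniteEnergyError(f"non-finite energies: {E_new}, {E_old}")
    if T <= 0:
        raise ValueError("temperature must be positive")
    if E_new < E_old:
        return True
    p = math.exp(-(E_new - E_old) / T)
    return rng.random() < p


def next_temperature(schedule: AnnealingSchedule, T: float, step: int = 1) -> float:
    """Geometric cooling: one cooling multiplication per completed stage."""
    return T * schedule.alpha**step


def calibrate_t0(
    state: DesignState,
    ruleset: RuleSet,
    constraints: ConstraintSet,
    objective: ObjectiveSpec,
    rng: np.random.Generator,
    n_moves: int = 100,
    target: float = 0.8,
) -> float:
    """Pick T0 so the mean worsening move is accepted with ``target`` probability.

    Runs a short all-accepting random walk from the start, collects the
    positive energy increments, and solves exp(-mean / T0) = target.
    """
    current = state
    e_cur = objective.energy(current)
    worsening: list[float] = []
    for _ in range(n_moves):
        try:
            app = apply_random_rule(current, ruleset, constraints, rng, max_retries=10)
        except ExhaustedRetriesError:
            continue
        e_new = objective.energy(app.state)
        if e_new > e_cur:
            worsening.append(e_new - e_cur)
        current, e_cur = app.state, e_new
    if not worsening:
        # flat or monotone landscape: any small positive temperature works
        return max(abs(e_cur), 1.0) * 1e-3
    return float(np.mean(worsening)) / math.log(1.0 / target)


class OptimizationTrace:
    """Per-proposal record of the optimisation: one row per proposal."""

    COLUMNS = (
        "iteration",
        "temperature",
        "energy",
        "candidate_energy",
        "accepted",
        "rule",
        "scaffold_nt",
        "best_energy",
    )

    def __init__(self):
        self.rows: list[tuple] = []

    def record(self, iteration, temperature, energy, candidate_energy, accepted, rule,
               scaffold_nt, best_energy):
        self.rows.append(
            (iteration, temperature, energy, candidate_energy, accepted, rule,
             scaffold_nt, best_energy)
        )

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.COLUMNS)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class AnnealProblem:
    """Everything a single-objective run needs besides the random stream."""

    initial_state: DesignState
    ruleset: RuleSet
    constraints: ConstraintSet
    objective: ObjectiveSpec
    schedule: AnnealingSchedule = field(default_factory=AnnealingSchedule)


@dataclass
class AnnealResult:
    best_state: DesignState
    best_energy: float
    final_state: DesignState
    trace: OptimizationTrace
    t0: float


def anneal(
    problem: AnnealProblem,
    rng: np.random.Generator,
    callback: Callable[[int, DesignState, bool], None] | None = None,
) -> AnnealResult:
    """Run shape annealing and return the best feasible design found.

    The run is a pure function of (problem, rng): identical seeds and
    configuration reproduce every proposal, acceptance decision and hence
    the whole trace.  The best state seen is returned even if the walk
    later drifts to a worse one.
    """
    sched = problem.schedule
    state = problem.initial_state
    rep = is_feasible(state, problem.constraints)
    if not rep.feasible:
        raise InfeasibleStartError(f"initial state infeasible: {rep.violations}")

    t0 = sched.t0
    if t0 is None:
        t0 = calibrate_t0(
            state,
            problem.ruleset,
            problem.constraints,
            problem.objective,
            rng,
            n_moves=sched.calibration_moves,
            target=sched.calibration_target,
        )
    T = t0

    energy = problem.objective.energy(state)
    best_state, best_energy = state, energy
    trace = OptimizationTrace()
    stages_without_accept = 0
    accepted_in_stage = 0

    for it in range(1, sched.total_iterations + 1):
        k_cap = sched.effective_k_max(it, problem.ruleset.k_max)
        try:
            app = apply_random_rule(
                state,
                problem.ruleset,
                problem.constraints,
                rng,
                max_retries=sched.max_retries,
                k_max=k_cap,
            )
        except ExhaustedRetriesError:
            trace.record(it, T, energy, math.nan, False, "null",
                         estimate_scaffold_nt(state), best_energy)
        else:
            cand_energy = problem.objective.energy(app.state)
            accepted = metropolis_accept(cand_energy, energy, T, rng)
            e_before = energy
            if accepted:
                state, energy = app.state, cand_energy
                accepted_in_stage += 1
                if energy < best_energy:
                    best_state, best_energy = state, energy
                if callback is not None:
                    callback(it, state, True)
            # 'energy' column is the current solution's value when the
            # candidate was judged, so worse-move acceptances are visible
            trace.record(it, T, e_before, cand_energy, accepted, app.rule,
                         estimate_scaffold_nt(state), best_energy)
        if it % sched.stage_length == 0:
            if accepted_in_stage == 0:
                stages_without_accept += 1
            else:
                stages_without_accept = 0
            accepted_in_stage = 0
            if sched.stall_stages is not None and stages_without_accept >= sched.stall_stages:
                break
            T = next_temperature(sched, T)

    return AnnealResult(best_state, best_energy, state, trace, t0)
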