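"""Gaussian bare-bone and artificial-bee strategies, and the hybrid loop.

The hybrid optimizer (ABHGS) interleaves three phases each iteration:

1. the hunger-driven HGS move (:func:`abhgs.hgs.hgs_phase`);
2. a Gaussian bare-bone refinement: each agent samples a candidate either
   from N((pbest+Xb)/2, |pbest-Xb|) per dimension or from a scaled
   difference vector, keeping it only on strict improvement;
3. an artificial-bee exploration block over floor(N/2) food sources:
   employed-bee neighbourhood moves, probability-weighted onlooker
   reinforcement, and greedy random replacement of swarm members by good
   food sources.

Disabling phase 3 gives BHGS, phase 2 gives AHGS, both gives plain HGS; the
reduction to HGS is bit-exact under a shared seed.

Random-draw order (the determinism contract, continuing the list in
:mod:`abhgs.hgs`): bare-bone, per agent i: partner indices k1 then k2 by
rejection from ``integers(0, N)``, scale ``k`` = ``random()``, branch draws
``random(D)``, Gaussian draws ``standard_normal(D)`` (always drawn).
Employed/onlooker move, per food source i: partner by rejection from
``integers(0, M)``, then ``uniform(-1, 1, D)``.  Onlooker acceptance: one
``random()`` per visited source.  Replacement: one ``integers(0, N)`` per
food source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .core import (
    ObjectiveProblem,
    OptimizationResult,
    RunConfig,
    SwarmState,
    clamp_to_bounds,
    init_population,
)
from .diagnostics import DiversityTrace, record_trajectory
from .hgs import HGSParams, compute_shrink_a, hgs_phase

__all__ = [
    "BareboneParams",
    "ABCParams",
    "barebone_update",
    "employed_bee_phase",
    "onlooker_probabilities",
    "onlooker_bee_phase",
    "random_replacement_phase",
    "evals_per_iteration",
    "run_abhgs",
]


@dataclass(frozen=True)
class BareboneParams:
    """Bare-bone controls: branch probability CR (default 0.5) and whether
    the refinement is also applied to the food sources (off by default)."""

    cr: float = 0.5
    on_food: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.cr <= 1.0:
            raise ValueError("CR must lie in [0, 1]")


@dataclass(frozen=True)
class ABCParams:
    """Bee-strategy controls.  ``single_dim`` switches the neighbourhood move
    to the classic one-random-dimension variant instead of a full random
    vector."""

    single_dim: bool = False


def _distinct_index(n: int, rng: np.random.Generator, *exclude: int) -> int:
    """Rejection-sample an index in [0, n) avoiding ``exclude``."""
    while True:
        k = int(rng.integers(0, n))
        if k not in exclude:
            return k


def barebone_update(
    state: SwarmState,
    problem: ObjectiveProblem,
    params: BareboneParams,
    rng: np.random.Generator,
) -> None:
    """Gaussian bare-bone refinement of every agent, with greedy selection.

    Per agent i and dimension j: with probability CR the candidate component
    is drawn from N((pbest_ij + Xb_j)/2, |pbest_ij - Xb_j|); otherwise it is
    pbest_ij + k*(X_k1,j - X_k2,j) with one uniform scale k per agent and
    distinct partners k1, k2 != i.  The clamped candidate replaces X_i (and
    pbest_i) only if strictly better.  Charges N evaluations.
    """
    n, d = state.positions.shape
    if n < 3:
        raise ValueError("bare-bone refinement needs at least 3 agents")
    bounds = problem.bounds.expand(d)
    for i in range(n):
        k1 = _distinct_index(n, rng, i)
        k2 = _distinct_index(n, rng, i, k1)
        k = float(rng.random())
        u = rng.random(d)
        g = rng.standard_normal(d)
        mean = 0.5 * (state.pbest_pos[i] + state.best_pos)
        sd = np.abs(state.pbest_pos[i] - state.best_pos)
        gauss = mean + sd * g
        diff = state.pbest_pos[i] + k * (
            state.positions[k1] - state.positions[k2]
        )
        cand = clamp_to_bounds(np.where(u < params.cr, gauss, diff), bounds)
        f = problem(cand)
        state.budget.charge(1)
        if f < state.fitness[i]:
            state.positions[i] = cand
            state.fitness[i] = f
        if f < state.pbest_fit[i]:
            state.pbest_pos[i] = cand
            state.pbest_fit[i] = f


def _food_neighbour_move(
    state: SwarmState,
    problem: ObjectiveProblem,
    i: int,
    bounds,
    rng: np.random.Generator,
    single_dim: bool,
) -> None:
    """One employed/onlooker neighbourhood move on food source i (greedy)."""
    m, d = state.food_pos.shape
    k = _distinct_index(m, rng, i)
    if single_dim:
        j = int(rng.integers(0, d))
        r = float(rng.uniform(-1.0, 1.0))
        cand = state.food_pos[i].copy()
        cand[j] += r * (state.food_pos[i, j] - state.food_pos[k, j])
    else:
        r = rng.uniform(-1.0, 1.0, d)
        cand = state.food_pos[i] + r * (state.food_pos[i] - state.food_pos[k])
    cand = clamp_to_bounds(cand, bounds)
    f = problem(cand)
    state.budget.charge(1)
    if f < state.food_fit[i]:
        state.food_pos[i] = cand
        state.food_fit[i] = f


def employed_bee_phase(
    state: SwarmState,
    problem: ObjectiveProblem,
    rng: np.random.Generator,
    params: ABCParams = ABCParams(),
) -> None:
    """Each food source probes one random neighbour and keeps the better.

    food_i' = food_i + r (.) (food_i - food_k), r uniform in [-1, 1] and
    k != i a random food index.  Charges M = floor(N/2) evaluations.
    """
    m = state.food_pos.shape[0]
    if m < 2:
        raise ValueError("the bee strategy needs at least 2 food sources")
    bounds = problem.bounds.expand(state.dim)
    for i in range(m):
        _food_neighbour_move(state, problem, i, bounds, rng, params.single_dim)


def onlooker_probabilities(food_fit: np.ndarray) -> np.ndarray:
    """Selection probability prob(i) = 0.9 * min(F)/F(i) + 0.1 per source.

    The formula assumes positive fitness; non-positive values are first
    shifted by 1 - min(F) so that prob stays in (0, 1] with the best source
    at exactly 1.0.
    """
    f = np.asarray(food_fit, dtype=float)
    fmin = float(np.min(f))
    if fmin <= 0:
        f = f - fmin + 1.0
    return 0.9 * np.min(f) / f + 0.1


def onlooker_bee_phase(
    state: SwarmState,
    problem: ObjectiveProblem,
    prob: np.ndarray,
    rng: np.random.Generator,
    params: ABCParams = ABCParams(),
) -> None:
    """Probability-weighted reinforcement of promising food sources.

    Cycles over the sources (with wraparound); a source is probed with
    probability prob(i), and the phase ends after M accepted probes, so it
    charges exactly M evaluations.  Termination is guaranteed because
    prob >= 0.1 everywhere.
    """
    m = state.food_pos.shape[0]
    bounds = problem.bounds.expand(state.dim)
    i = 0
    accepted = 0
    while accepted < m:
        if float(rng.random()) < prob[i]:
            accepted += 1
            _food_neighbour_move(state, problem, i, bounds, rng, params.single_dim)
        i = (i + 1) % m


def random_replacement_phase(
    state: SwarmState,
    problem: ObjectiveProblem,
    rng: np.random.Generator,
) -> None:
    """Each food source challenges one random swarm member, greedily.

    For each source a random agent C is drawn; if the food source beats
    X_C, it becomes the new X_C (personal best updated on improvement).
    Uses stored fitness only — no evaluations charged.
    """
    n = state.n_agents
    m = state.food_pos.shape[0]
    for i in range(m):
        c = int(rng.integers(0, n))
        if state.food_fit[i] < state.fitness[c]:
            state.positions[c] = state.food_pos[i].copy()
            state.fitness[c] = float(state.food_fit[i])
            if state.fitness[c] < state.pbest_fit[c]:
                state.pbest_pos[c] = state.positions[c].copy()
                state.pbest_fit[c] = state.fitness[c]


def evals_per_iteration(config: RunConfig) -> int:
    """Objective evaluations charged per full iteration of the hybrid loop."""
    n, m = config.pop_size, config.n_food
    k = n
    if config.use_barebone:
        k += n
    if config.use_abc:
        k += 2 * m
    return k


def run_abhgs(
    problem: ObjectiveProblem,
    config: RunConfig,
    params: Optional[HGSParams] = None,
    bb_params: Optional[BareboneParams] = None,
    abc_params: Optional[ABCParams] = None,
    move_postprocess: Optional[Callable] = None,
    rng: Optional[np.random.Generator] = None,
    init_sampler: Optional[Callable] = None,
) -> OptimizationResult:
    """Run the hybrid optimizer; strategy flags in ``config`` select the
    variant (both on: ABHGS; abc only: AHGS; bare-bone only: BHGS; neither:
    plain HGS).

    Iterations run while the remaining evaluation budget covers a full
    iteration (and, if ``config.max_iters`` is set, until that many
    iterations).  The annealing horizon for the shrink factor is
    ceil(max_evals / evals-per-iteration) unless ``max_iters`` overrides it.
    ``move_postprocess`` is forwarded to the HGS move (binary wrapper hook).
    """
    params = params or HGSParams()
    bb_params = bb_params or BareboneParams()
    abc_params = abc_params or ABCParams()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    state = init_population(problem, config, rng, init_sampler=init_sampler)
    per_iter = evals_per_iteration(config)
    if config.max_iters is not None:
        max_iter = config.max_iters
    else:
        max_iter = max(1, math.ceil(config.max_evals / per_iter))

    convergence: list[float] = []
    trace = DiversityTrace() if config.record_diagnostics else None

    t = 0
    while (config.max_iters is None or t < config.max_iters) and state.budget.can_afford(per_iter):
        a = compute_shrink_a(t, max_iter)
        hgs_phase(state, problem, params, a, rng, move_postprocess=move_postprocess)
        if config.use_barebone:
            barebone_update(state, problem, bb_params, rng)
            if bb_params.on_food and state.budget.can_afford(config.n_food):
                _barebone_on_food(state, problem, bb_params, rng)
        if config.use_abc:
            employed_bee_phase(state, problem, rng, abc_params)
            prob = onlooker_probabilities(state.food_fit)
            onlooker_bee_phase(state, problem, prob, rng, abc_params)
            random_replacement_phase(state, problem, rng)
        state.update_pbest()
        state.update_extremes()
        convergence.append(state.best_fit)
        if trace is not None:
            trace.record(state.positions)
            record_trajectory(trace, state.positions, state.fitness, state.best_fit)
        state.iteration = t = t + 1

    return OptimizationResult(
        best_pos=state.best_pos.copy(),
        best_fit=state.best_fit,
        convergence=np.asarray(convergence),
        evals_used=state.evals_used,
        diversity_trace=trace,
        trajectory=np.asarray(trace.traj_dim1) if trace is not None else None,
        mean_fitness=np.asarray(trace.mean_fitness) if trace is not None else None,
    )


def _barebone_on_food(
    state: SwarmState,
    problem: ObjectiveProblem,
    params: BareboneParams,
    rng: np.random.Generator,
) -> None:
    """Optional bare-bone refinement of the food sources (greedy).

    Food sources have no personal best; each source stands in for its own
    pbest.  Charges M evaluations.
    """
    m, d = state.food_pos.shape
    bounds = problem.bounds.expand(d)
    for i in range(m):
        k1 = _distinct_index(m, rng, i)
        k2 = _distinct_index(m, rng, i, k1)
        k = float(rng.random())
        u = rng.random(d)
        g = rng.standard_normal(d)
        mean = 0.5 * (state.food_pos[i] + state.best_pos)
        sd = np.abs(state.food_pos[i] - state.best_pos)
        gauss = mean + sd * g
        diff = state.food_pos[i] + k * (state.food_pos[k1] - state.food_pos[k2])
        cand = clamp_to_bounds(np.where(u < params.cr, gauss, diff), bounds)
        f = problem(cand)
        state.budget.charge(1)
        if f < state.food_fit[i]:
            state.food_pos[i] = cand
            state.food_fit[i] = f
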