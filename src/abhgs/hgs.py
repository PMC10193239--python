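"""The base Hunger Games Search (HGS) optimizer.

HGS is a population metaheuristic in which each agent accumulates a "hunger"
level proportional to its fitness gap from the best agent; hunger modulates
two adaptive weights W1, W2 that drive the position update toward (or around)
the best-known position.  A shrinking envelope ``a`` anneals the perturbation
range over the run.

The composed hybrid loop lives in :mod:`abhgs.hybrid`; :func:`run_hgs` is the
plain HGS entry point (both strategy flags off).

Random-draw order per iteration (the determinism contract):

1. hunger update: ``r6`` (N), then ``r`` (N)
2. weights: ``r3`` (N), ``r4`` (N), ``r5`` (N)
3. move: ``u`` (N) for R, then ``r1`` (N), ``r2`` (N), ``randn`` (N)

All per-agent draws are scalars broadcast over the agent's dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    Bounds,
    ObjectiveProblem,
    OptimizationResult,
    RunConfig,
    SwarmState,
    clamp_to_bounds,
)

__all__ = [
    "HGSParams",
    "compute_shrink_a",
    "sample_R",
    "compute_E",
    "update_hunger",
    "compute_weights",
    "hgs_position_update",
    "hgs_phase",
    "run_hgs",
]


@dataclass(frozen=True)
class HGSParams:
    """HGS control parameters.

    ``l`` routes agents into the self-perturbation branch of the position
    update; ``lh`` (LH) is the lower bound on the per-iteration hunger
    increment.  Defaults follow the standard HGS setting l=0.08, LH=100.
    """

    l: float = 0.08
    lh: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.l <= 1.0:
            raise ValueError("l must lie in [0, 1]")
        if self.lh <= 0:
            raise ValueError("LH must be positive")


def compute_shrink_a(t: int, max_iter: int) -> float:
    """Shrink factor a = 2(1 - t/max_iter), linearly annealed from 2 to 0."""
    if max_iter <= 0:
        raise ValueError("max_iter must be positive")
    return max(0.0, 2.0 * (1.0 - t / max_iter))


def sample_R(a: float, rng: np.random.Generator) -> float:
    """One draw of R = 2*a*u - a, uniform in [-a, a]."""
    return 2.0 * a * float(rng.random()) - a


def compute_E(fit_i: float, best_fit: float) -> float:
    """Variation control E = sech(|F(i) - BF|), in (0, 1]; 1 for the best agent."""
    x = abs(fit_i - best_fit)
    # sech(x) = 2 / (e^x + e^-x); underflows cleanly to 0.0 for large gaps
    with np.errstate(over="ignore"):
        return float(2.0 / (np.exp(x) + np.exp(-x)))


def update_hunger(
    state: SwarmState,
    bounds: Bounds,
    params: HGSParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance per-agent hunger levels in place.

    Agents at the running best fitness reset to 0; every other agent gains
    H, where TH = (F(i)-BF)/(WF-BF) * r6 * 2 * (UB-LB) and H falls back to
    LH*(1+r) whenever TH < LH.  With vector bounds the scalar (UB-LB) is the
    mean per-dimension range.  When WF == BF the gap ratio is defined as 0,
    forcing the LH branch.
    """
    n = state.n_agents
    r6 = rng.random(n)
    r = rng.random(n)
    span = bounds.span
    denom = state.worst_fit - state.best_fit
    if denom > 0:
        th = (state.fitness - state.best_fit) / denom * r6 * 2.0 * span
    else:
        th = np.zeros(n)
    h = np.where(th < params.lh, params.lh * (1.0 + r), th)
    at_best = state.fitness == state.best_fit
    state.hungry[at_best] = 0.0
    state.hungry[~at_best] += h[~at_best]
    return state.hungry


def compute_weights(
    state: SwarmState, params: HGSParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Hunger weights W1, W2 for the position update.

    W1(i) = hungry(i)*N/SHungry * r4 when r3 < l, else 1 (and 1 throughout
    when total hunger is zero); W2(i) = (1 - exp(-|hungry(i) - SHungry|)) *
    r5 * 2, always in [0, 2).
    """
    n = state.n_agents
    r3 = rng.random(n)
    r4 = rng.random(n)
    r5 = rng.random(n)
    s_hungry = float(np.sum(state.hungry))
    if s_hungry > 0:
        hungry_w = state.hungry * n / s_hungry * r4
    else:
        hungry_w = np.ones(n)
    w1 = np.where(r3 < params.l, hungry_w, 1.0)
    w2 = (1.0 - np.exp(-np.abs(state.hungry - s_hungry))) * r5 * 2.0
    return w1, w2


def hgs_position_update(
    positions: np.ndarray,
    fitness: np.ndarray,
    best_pos: np.ndarray,
    best_fit: float,
    w1: np.ndarray,
    w2: np.ndarray,
    a: float,
    params: HGSParams,
    bounds: Bounds,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronous hunger-driven move of the whole population.

    Per agent with fresh uniform draws r1, r2: if r1 < l the agent perturbs
    itself by a single shared normal draw, X <- X*(1+randn); otherwise it
    moves around the best position, X <- W1*Xb +/- R*W2*|Xb - X|, with the
    sign chosen by comparing r2 with E = sech(|F(i)-BF|) (addition when
    r2 > E).  Equalities route to the strict-inequality complement.  The
    result is clamped onto the bounds.
    """
    n, d = positions.shape
    u = rng.random(n)
    r1 = rng.random(n)
    r2 = rng.random(n)
    randn = rng.standard_normal(n)
    big_r = 2.0 * a * u - a

    e = np.array([compute_E(f, best_fit) for f in fitness])
    gap = np.abs(best_pos[None, :] - positions)
    new = np.empty_like(positions)
    for i in range(n):
        if r1[i] < params.l:
            new[i] = positions[i] * (1.0 + randn[i])
        elif r2[i] > e[i]:
            new[i] = w1[i] * best_pos + big_r[i] * w2[i] * gap[i]
        else:
            new[i] = w1[i] * best_pos - big_r[i] * w2[i] * gap[i]
    return clamp_to_bounds(new, bounds)


def hgs_phase(
    state: SwarmState,
    problem: ObjectiveProblem,
    params: HGSParams,
    a: float,
    rng: np.random.Generator,
    move_postprocess=None,
) -> None:
    """One full HGS iteration on ``state`` (bookkeeping, hunger, move, eval).

    Bookkeeping (pbest, running BF/WF/Xb) uses the fitness of the current
    positions, so the move is synchronous against the previous snapshot.
    Charges N evaluations.  ``move_postprocess(positions, rng)`` optionally
    transforms the moved positions before evaluation (used by the binary
    feature-selection wrapper).
    """
    bounds = problem.bounds.expand(state.dim)
    state.update_pbest()
    state.update_extremes()
    update_hunger(state, bounds, params, rng)
    w1, w2 = compute_weights(state, params, rng)
    new_pos = hgs_position_update(
        state.positions,
        state.fitness,
        state.best_pos,
        state.best_fit,
        w1,
        w2,
        a,
        params,
        bounds,
        rng,
    )
    if move_postprocess is not None:
        new_pos = move_postprocess(new_pos, rng)
    state.positions = new_pos
    state.fitness = np.array([problem(x) for x in state.positions])
    state.budget.charge(state.n_agents)


def run_hgs(
    problem: ObjectiveProblem,
    config: RunConfig,
    params: HGSParams | None = None,
) -> OptimizationResult:
    """Run plain HGS: the hybrid loop with both strategies disabled."""
    from dataclasses import replace

    from .hybrid import run_abhgs

    config = replace(config, use_abc=False, use_barebone=False)
    return run_abhgs(problem, config, params)
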