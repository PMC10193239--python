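"""Shared data model for swarm optimization runs.

Problems, box bounds, run configuration, population state, evaluation-budget
accounting and bound repair.  Everything downstream (the HGS optimizer, the
hybrid strategies, the binary feature-selection wrapper) builds on these
types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "Bounds",
    "ObjectiveProblem",
    "RunConfig",
    "SwarmState",
    "OptimizationResult",
    "Budget",
    "BudgetExhausted",
    "clamp_to_bounds",
    "init_population",
]


@dataclass(frozen=True)
class Bounds:
    """Box constraints, broadcastable scalar or per-dimension vectors."""

    lb: np.ndarray
    ub: np.ndarray

    def __init__(self, lb, ub) -> None:
        lb = np.atleast_1d(np.asarray(lb, dtype=float))
        ub = np.atleast_1d(np.asarray(ub, dtype=float))
        lb, ub = np.broadcast_arrays(lb, ub)
        if not np.all(lb < ub):
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lb", lb.copy())
        object.__setattr__(self, "ub", ub.copy())

    def expand(self, dim: int) -> "Bounds":
        """Broadcast to a given dimensionality."""
        lb = np.broadcast_to(self.lb, (dim,)).copy()
        ub = np.broadcast_to(self.ub, (dim,)).copy()
        return Bounds(lb, ub)

    @property
    def span(self) -> float:
        """Scalar search-space range: mean per-dimension (ub - lb)."""
        return float(np.mean(self.ub - self.lb))

    def sample_uniform(self, n: int, dim: int, rng: np.random.Generator) -> np.ndarray:
        b = self.expand(dim)
        return rng.uniform(b.lb, b.ub, size=(n, dim))


@dataclass(frozen=True)
class ObjectiveProblem:
    """A minimization problem: deterministic objective over a box."""

    name: str
    dim: int
    bounds: Bounds
    objective: Callable[[np.ndarray], float]

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be positive")

    def __call__(self, x: np.ndarray) -> float:
        return float(self.objective(np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one optimizer run.

    ``pop_size`` must be at least 4: the bee strategy needs two food sources
    and the bare-bone move needs two distinct partner indices besides *i*.
    ``max_evals`` is an objective-evaluation budget; every fitness call in any
    phase is charged against it.  ``max_iters`` optionally caps outer
    iterations instead (used by the feature-selection wrapper).
    """

    pop_size: int = 30
    max_evals: int = 300_000
    seed: int = 0
    use_abc: bool = True
    use_barebone: bool = True
    record_diagnostics: bool = False
    max_iters: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        if self.max_evals < self.pop_size:
            raise ValueError("max_evals must cover at least one population evaluation")

    @property
    def n_food(self) -> int:
        return self.pop_size // 2


class BudgetExhausted(Exception):
    """Raised internally when an evaluation would exceed the budget."""


@dataclass
class Budget:
    """Objective-evaluation budget accounting."""

    max_evals: int
    used: int = 0

    @property
    def remaining(self) -> int:
        return self.max_evals - self.used

    def can_afford(self, k: int) -> bool:
        return self.used + k <= self.max_evals

    def charge(self, k: int) -> None:
        if k < 0:
            raise ValueError("cannot charge a negative evaluation count")
        if not self.can_afford(k):
            raise BudgetExhausted(
                f"charging {k} evaluations would exceed budget "
                f"({self.used}/{self.max_evals} used)"
            )
        self.used += k


@dataclass
class SwarmState:
    """Mutable bookkeeping for one optimizer run.

    ``best_fit``/``best_pos``/``worst_fit`` are running extremes over the
    whole history, so the best-so-far fitness never worsens.
    """

    positions: np.ndarray  # (N, D)
    fitness: np.ndarray  # (N,)
    hungry: np.ndarray  # (N,)
    pbest_pos: np.ndarray  # (N, D)
    pbest_fit: np.ndarray  # (N,)
    food_pos: np.ndarray  # (M, D)
    food_fit: np.ndarray  # (M,)
    best_pos: np.ndarray  # (D,)
    best_fit: float
    worst_fit: float
    iteration: int = 0
    budget: Budget = field(default_factory=lambda: Budget(0))

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    @property
    def evals_used(self) -> int:
        return self.budget.used

    def update_pbest(self) -> None:
        improved = self.fitness < self.pbest_fit
        self.pbest_pos[improved] = self.positions[improved]
        self.pbest_fit[improved] = self.fitness[improved]

    def update_extremes(self) -> None:
        """Fold current population fitness into the running BF/WF/Xb."""
        i = int(np.argmin(self.fitness))
        if self.fitness[i] < self.best_fit:
            self.best_fit = float(self.fitness[i])
            self.best_pos = self.positions[i].copy()
        wf = float(np.max(self.fitness))
        if wf > self.worst_fit:
            self.worst_fit = wf


@dataclass
class OptimizationResult:
    """Outcome of one run: best solution plus per-iteration traces."""

    best_pos: np.ndarray
    best_fit: float
    convergence: np.ndarray  # best-so-far fitness per iteration
    evals_used: int
    diversity_trace: Optional["object"] = None  # diagnostics.DiversityTrace
    trajectory: Optional[np.ndarray] = None  # agent-1 dim-1 per iteration
    mean_fitness: Optional[np.ndarray] = None


def clamp_to_bounds(pos: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Component-wise clamp onto the box; the repair rule for strays."""
    pos = np.asarray(pos, dtype=float)
    return np.clip(pos, bounds.lb, bounds.ub)


def init_population(
    problem: ObjectiveProblem,
    config: RunConfig,
    rng: np.random.Generator,
    init_sampler=None,
) -> SwarmState:
    """Uniform-random swarm plus floor(N/2) food sources, all evaluated.

    Charges N + floor(N/2) evaluations; raises if the budget cannot cover
    initialization.  ``init_sampler(n, dim, rng)`` optionally replaces the
    uniform draw (the binary wrapper seeds with 0/1 positions).
    """
    n, d, m = config.pop_size, problem.dim, config.n_food
    budget = Budget(config.max_evals)
    if not budget.can_afford(n + m):
        raise ValueError(
            f"max_evals={config.max_evals} cannot cover initialization "
            f"({n} agents + {m} food sources)"
        )
    bounds = problem.bounds.expand(d)
    if init_sampler is None:
        init_sampler = lambda k, dim, gen: bounds.sample_uniform(k, dim, gen)
    positions = np.asarray(init_sampler(n, d, rng), dtype=float)
    fitness = np.array([problem(x) for x in positions])
    budget.charge(n)
    food_pos = np.asarray(init_sampler(m, d, rng), dtype=float)
    food_fit = np.array([problem(x) for x in food_pos])
    budget.charge(m)

    best = int(np.argmin(fitness))
    state = SwarmState(
        positions=positions,
        fitness=fitness,
        hungry=np.zeros(n),
        pbest_pos=positions.copy(),
        pbest_fit=fitness.copy(),
        food_pos=food_pos,
        food_fit=food_fit,
        best_pos=positions[best].copy(),
        best_fit=float(fitness[best]),
        worst_fit=float(np.max(fitness)),
        budget=budget,
    )
    return state
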