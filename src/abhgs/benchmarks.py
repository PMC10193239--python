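"""Benchmark objectives, multi-run experiment harness, and rank statistics.

The harness runs a grid of (algorithm, problem) cells with paired seeds
(run r of every algorithm uses base_seed + r, so comparisons are paired),
aggregates mean/std of the final best fitness, and applies the standard
non-parametric comparison machinery: pairwise Wilcoxon signed-rank tests
against a reference algorithm with +/=/- tallies at the 0.05 level, and
Friedman average ranks (ARV, lower is better).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Bounds, ObjectiveProblem, OptimizationResult, RunConfig

__all__ = [
    "builtin_problems",
    "BUILTIN_PROBLEMS",
    "wilcoxon_signed_rank",
    "friedman_ranks",
    "AlgorithmSpec",
    "ExperimentGrid",
    "ComparisonReport",
    "run_experiment",
]


# ---------------------------------------------------------------------------
# classical test objectives (all with global minimum 0)

def _sphere(x):
    return float(np.sum(x * x))


def _rosenbrock(x):
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def _rastrigin(x):
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


def _ackley(x):
    d = x.size
    s1 = np.sum(x * x) / d
    s2 = np.sum(np.cos(2.0 * np.pi * x)) / d
    return float(-20.0 * np.exp(-0.2 * np.sqrt(s1)) - np.exp(s2) + 20.0 + np.e)


def _griewank(x):
    i = np.arange(1, x.size + 1)
    return float(np.sum(x * x) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0)


BUILTIN_PROBLEMS: dict[str, tuple[Callable, float, float]] = {
    "sphere": (_sphere, -100.0, 100.0),
    "rosenbrock": (_rosenbrock, -30.0, 30.0),
    "rastrigin": (_rastrigin, -5.12, 5.12),
    "ackley": (_ackley, -32.768, 32.768),
    "griewank": (_griewank, -600.0, 600.0),
}


def builtin_problems(names: Sequence[str], dim: int) -> list[ObjectiveProblem]:
    """Instantiate classical test problems by name at a given dimension."""
    problems = []
    for name in names:
        if name not in BUILTIN_PROBLEMS:
            raise KeyError(
                f"unknown problem {name!r}; available: {sorted(BUILTIN_PROBLEMS)}"
            )
        fn, lb, ub = BUILTIN_PROBLEMS[name]
        problems.append(
            ObjectiveProblem(name=name, dim=dim, bounds=Bounds(lb, ub), objective=fn)
        )
    return problems


# ---------------------------------------------------------------------------
# statistics

def wilcoxon_signed_rank(x, y) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped.  For n <= 12 retained pairs the p-value is
    computed by exact enumeration of all 2^n sign patterns on the observed
    (tie-averaged) ranks; beyond that the tie- and continuity-corrected
    normal approximation is used.  Returns (W+, p, degenerate) where
    ``degenerate`` flags the all-zero-differences case (p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, True
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    if n <= 12:
        # exact null distribution of W+ over all sign assignments of the
        # observed ranks (valid under ties as well)
        totals = np.array(
            [np.sum(ranks[list(signs)]) for signs in _sign_subsets(n)]
        )
        p_low = np.mean(totals <= w_plus + 1e-12)
        p_high = np.mean(totals >= w_plus - 1e-12)
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        _, p = stats.wilcoxon(
            x, y, zero_method="wilcox", correction=True, method="approx"
        )
        p = float(p)
    return w_plus, p, False


def _sign_subsets(n: int):
    """All subsets of {0..n-1} (indices receiving a positive sign)."""
    idx = range(n)
    for r in range(n + 1):
        yield from (list(c) for c in itertools.combinations(idx, r))


def friedman_ranks(scores: np.ndarray) -> np.ndarray:
    """Friedman average ranks over a problems x algorithms score matrix.

    Lower score = better; ties get average ranks.  Per problem the ranks of
    the k algorithms sum to k(k+1)/2, so the returned ARV vector always
    averages to (k+1)/2.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 1 or scores.shape[1] < 2:
        raise ValueError("need a problems x algorithms matrix with >= 2 algorithms")
    if np.isnan(scores).any():
        raise ValueError("missing cells in the score matrix")
    ranks = np.apply_along_axis(stats.rankdata, 1, scores)
    return ranks.mean(axis=0)


# ---------------------------------------------------------------------------
# experiment harness

@dataclass(frozen=True)
class AlgorithmSpec:
    """A named, configured optimizer: ``runner(problem, config)`` -> result."""

    name: str
    runner: Callable[[ObjectiveProblem, RunConfig], OptimizationResult]
    use_abc: bool = True
    use_barebone: bool = True


@dataclass
class ExperimentGrid:
    """A full comparison: algorithms x problems x paired seeded runs."""

    algorithms: list[AlgorithmSpec]
    problems: list[ObjectiveProblem]
    n_runs: int = 30
    pop_size: int = 30
    budget: int = 300_000
    base_seed: int = 0


@dataclass
class ComparisonReport:
    """Aggregated comparison: Avg/Std tables, Wilcoxon vs reference with
    +/=/- tallies, and Friedman average ranks."""

    finals: pd.DataFrame  # columns: problem, algorithm, run, seed, best_fit
    avg: pd.DataFrame  # problems x algorithms
    std: pd.DataFrame
    wilcoxon_p: pd.DataFrame  # problems x non-reference algorithms
    signs: pd.DataFrame  # '+', '=', '-' of reference vs each other algorithm
    sign_tally: pd.Series  # per algorithm: "w/t/l" counts summed over problems
    friedman_arv: pd.Series  # per algorithm
    reference: str

    def summary(self) -> str:
        lines = ["Avg (mean final best fitness):", self.avg.to_string(), ""]
        lines += ["Std:", self.std.to_string(), ""]
        lines += [f"Wilcoxon p-values ({self.reference} vs column):",
                  self.wilcoxon_p.to_string(), ""]
        lines += ["+/=/- (reference better / no difference / worse):",
                  self.sign_tally.to_string(), ""]
        lines += ["Friedman average rank (ARV, lower is better):",
                  self.friedman_arv.to_string()]
        return "\n".join(lines)


def run_experiment(grid: ExperimentGrid, alpha: float = 0.05) -> ComparisonReport:
    """Execute the grid and aggregate the comparison report.

    Run r of every algorithm on every problem uses seed base_seed + r, so
    the per-run final fitness values are paired across algorithms.  The
    first algorithm in the grid is the reference for Wilcoxon tests and the
    +/=/- tally: '+' means the reference is better (lower mean) with
    p < alpha, '-' the reverse, '=' no significant difference.
    """
    rows = []
    for problem in grid.problems:
        for algo in grid.algorithms:
            for r in range(grid.n_runs):
                seed = grid.base_seed + r
                config = RunConfig(
                    pop_size=grid.pop_size,
                    max_evals=grid.budget,
                    seed=seed,
                    use_abc=algo.use_abc,
                    use_barebone=algo.use_barebone,
                )
                result = algo.runner(problem, config)
                rows.append(
                    {
                        "problem": problem.name,
                        "algorithm": algo.name,
                        "run": r,
                        "seed": seed,
                        "best_fit": result.best_fit,
                    }
                )
    finals = pd.DataFrame(rows)

    algo_names = [a.name for a in grid.algorithms]
    prob_names = [p.name for p in grid.problems]
    pivot_mean = finals.pivot_table(
        index="problem", columns="algorithm", values="best_fit", aggfunc="mean"
    ).reindex(index=prob_names, columns=algo_names)
    pivot_std = finals.pivot_table(
        index="problem", columns="algorithm", values="best_fit", aggfunc="std"
    ).reindex(index=prob_names, columns=algo_names).fillna(0.0)

    reference = algo_names[0]
    others = algo_names[1:]
    pvals = pd.DataFrame(index=prob_names, columns=others, dtype=float)
    signs = pd.DataFrame(index=prob_names, columns=others, dtype=object)
    for prob in prob_names:
        sub = finals[finals["problem"] == prob]
        ref_vals = sub[sub["algorithm"] == reference].sort_values("run")["best_fit"].to_numpy()
        for other in others:
            other_vals = sub[sub["algorithm"] == other].sort_values("run")["best_fit"].to_numpy()
            _, p, degenerate = wilcoxon_signed_rank(ref_vals, other_vals)
            pvals.loc[prob, other] = p
            if degenerate or p >= alpha:
                signs.loc[prob, other] = "="
            elif ref_vals.mean() < other_vals.mean():
                signs.loc[prob, other] = "+"
            else:
                signs.loc[prob, other] = "-"
    tally = pd.Series(
        {
            other: "/".join(
                str(int((signs[other] == s).sum())) for s in ("+", "=", "-")
            )
            for other in others
        },
        name="+/=/-",
    )

    arv = pd.Series(
        friedman_ranks(pivot_mean.to_numpy()), index=algo_names, name="ARV"
    )
    return ComparisonReport(
        finals=finals,
        avg=pivot_mean,
        std=pivot_std,
        wilcoxon_p=pvals,
        signs=signs,
        sign_tally=tally,
        friedman_arv=arv,
        reference=reference,
    )
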