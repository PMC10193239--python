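"""Swarm diversity and exploration/exploitation balance diagnostics.

Dimension-wise diversity: DIVj is the mean absolute deviation of dimension j
from its population median, DIV the mean of DIVj over dimensions.  The
exploration percentage of an iteration is DIV relative to the running maximum
DIVmax; exploitation is its complement, so the two always sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DiversityTrace",
    "dimension_diversity",
    "track_divmax",
    "balance_percentages",
    "record_trajectory",
]


def dimension_diversity(positions: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-dimension diversity DIVj and its mean DIV over dimensions.

    DIVj = (1/N) sum_i |median(X_j) - X_ij|.  For even N the median is the
    mean of the two central order statistics.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[0] == 0:
        raise ValueError("positions must be a non-empty N x D matrix")
    med = np.median(positions, axis=0)
    div_j = np.mean(np.abs(med[None, :] - positions), axis=0)
    return div_j, float(np.mean(div_j))


def balance_percentages(div_t: float, div_max: float) -> tuple[float, float]:
    """Exploration% = DIV/DIVmax * 100 and its complement Exploitation%.

    A zero DIVmax (population identical in every recorded iteration) is
    treated as fully exploitative: (0, 100).
    """
    if div_max <= 0:
        return 0.0, 100.0
    explor = div_t / div_max * 100.0
    exploit = abs(div_max - div_t) / div_max * 100.0
    return explor, exploit


@dataclass
class DiversityTrace:
    """Per-iteration diversity, its running maximum, and the balance split."""

    div_per_iter: list[float] = field(default_factory=list)
    div_max: float = 0.0
    exploration_pct: list[float] = field(default_factory=list)
    exploitation_pct: list[float] = field(default_factory=list)
    per_dim: list[np.ndarray] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_fitness: list[float] = field(default_factory=list)
    traj_dim1: list[float] = field(default_factory=list)

    def record(self, positions: np.ndarray, keep_per_dim: bool = False) -> None:
        div_j, div = dimension_diversity(positions)
        track_divmax(self, div)
        explor, exploit = balance_percentages(div, self.div_max)
        self.div_per_iter.append(div)
        self.exploration_pct.append(explor)
        self.exploitation_pct.append(exploit)
        if keep_per_dim:
            self.per_dim.append(div_j)

    def renormalize(self) -> None:
        """Recompute the balance split against the final-run DIVmax."""
        self.exploration_pct = []
        self.exploitation_pct = []
        for div in self.div_per_iter:
            explor, exploit = balance_percentages(div, self.div_max)
            self.exploration_pct.append(explor)
            self.exploitation_pct.append(exploit)

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self.div_per_iter)
        running_max = np.maximum.accumulate(self.div_per_iter) if n else []
        frame = {
            "iter": np.arange(n),
            "div": self.div_per_iter,
            "div_max": running_max,
            "exploration_pct": self.exploration_pct,
            "exploitation_pct": self.exploitation_pct,
        }
        if len(self.mean_fitness) == n:
            frame["mean_fitness"] = self.mean_fitness
        if len(self.best_fitness) == n:
            frame["best_fitness"] = self.best_fitness
        if len(self.traj_dim1) == n:
            frame["traj_dim1"] = self.traj_dim1
        return pd.DataFrame(frame)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def track_divmax(trace: DiversityTrace, div_t: float) -> DiversityTrace:
    """Fold one iteration's DIV into the running maximum."""
    trace.div_max = max(trace.div_max, div_t)
    return trace


def record_trajectory(trace: DiversityTrace, positions, fitness, best_fit) -> None:
    """Append agent-1/dimension-1 position, mean fitness and best-so-far."""
    trace.traj_dim1.append(float(positions[0, 0]))
    trace.mean_fitness.append(float(np.mean(fitness)))
    trace.best_fitness.append(float(best_fit))
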