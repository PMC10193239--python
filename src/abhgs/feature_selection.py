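"""Binary wrapper feature selection (bABHGS and its ablations).

The continuous hybrid optimizer is turned into a subset-search by three
pieces: an arctan transfer function mapping a position component to a
sign-flip probability, a sign decode (feature j selected iff x_j > 0, with a
one-bit repair for empty masks), and a wrapper fitness

    fitness = alpha * (1 - Acc) + (1 - alpha) * DR / D

combining the cross-validated 1-nearest-neighbour error with the selected
fraction of features (both minimized).  alpha defaults to 0.05.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .core import Bounds, ObjectiveProblem, RunConfig
from .datasets import LabeledMatrix
from .hgs import HGSParams
from .hybrid import run_abhgs

__all__ = [
    "FeatureMask",
    "FSConfig",
    "FSEvaluation",
    "FSResult",
    "init_binary_population",
    "transfer_function",
    "apply_transfer_update",
    "decode_mask",
    "knn_predict",
    "cv_error",
    "fs_fitness",
    "run_babhgs_fs",
]


@dataclass
class FeatureMask:
    """A binary selected-feature vector; DR is the number of set bits."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)

    @property
    def dr(self) -> int:
        return int(np.count_nonzero(self.bits))

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


@dataclass(frozen=True)
class FSConfig:
    """Wrapper-search configuration.

    Defaults follow the standard gene-selection protocol: alpha=0.05, 1-NN,
    10-fold stratified CV, 20 search agents, 50 iterations.  ``loocv``
    switches to leave-one-out CV.  ``decode`` selects the mask rule:
    ``"sign"`` (x > 0, default) or ``"round"`` (x >= 0.5).
    """

    alpha: float = 0.05
    k_neighbors: int = 1
    folds: int = 10
    pop_size: int = 20
    max_iters: int = 50
    seed: int = 0
    loocv: bool = False
    use_abc: bool = True
    use_barebone: bool = True
    decode: str = "sign"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.folds < 2 and not self.loocv:
            raise ValueError("folds must be >= 2 (or use loocv)")
        if self.decode not in ("sign", "round"):
            raise ValueError("decode must be 'sign' or 'round'")


@dataclass(frozen=True)
class FSEvaluation:
    """Outcome of scoring one mask: accuracy, error, subset size, fitness."""

    acc: float
    error: float
    dr: int
    fitness: float


@dataclass
class FSResult:
    """Best subset found plus its score and the search trace."""

    best_mask: FeatureMask
    best_fitness: float
    error_rate: float
    accuracy: float
    n_selected: int
    selected_features: list[str]
    convergence: np.ndarray
    evals_used: int
    runtime: float
    seed: int


def init_binary_population(n_agents: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """Random 0/1 start: each bit is 1 when its uniform draw exceeds 0.5."""
    return (rng.random((n_agents, d)) > 0.5).astype(float)


def transfer_function(x):
    """Arctan transfer T(x) = |(2/pi) * arctan((pi/2) * x)|.

    Even in x, strictly increasing in |x|, T(0) = 0 and T -> 1 as |x| grows;
    used as a per-component sign-flip probability.
    """
    x = np.asarray(x, dtype=float)
    t = np.abs(2.0 / np.pi * np.arctan(np.pi / 2.0 * x))
    return t if t.ndim else float(t)


def apply_transfer_update(positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stochastically negate each component with probability T(x)."""
    positions = np.asarray(positions, dtype=float)
    u = rng.random(positions.shape)
    flip = u < transfer_function(positions)
    return np.where(flip, -positions, positions)


def decode_mask(position: np.ndarray, rng: np.random.Generator, rule: str = "sign") -> FeatureMask:
    """Map a continuous position to a feature mask.

    ``sign``: bit j = (x_j > 0); ``round``: bit j = (x_j >= 0.5).  An
    all-zero mask is repaired by setting one uniformly random bit, so every
    evaluated mask selects at least one feature.
    """
    position = np.asarray(position, dtype=float)
    if rule == "sign":
        bits = position > 0
    elif rule == "round":
        bits = position >= 0.5
    else:
        raise ValueError(f"unknown decode rule {rule!r}")
    if not bits.any():
        bits = bits.copy()
        bits[int(rng.integers(0, position.size))] = True
    return FeatureMask(bits)


def _majority_vote(labels: np.ndarray) -> object:
    """Majority label; ties go to the label seen earliest (nearest first)."""
    uniq, first, counts = np.unique(labels, return_index=True, return_counts=True)
    best = counts == counts.max()
    return uniq[best][np.argmin(first[best])]


def knn_predict(train_X: np.ndarray, train_y: np.ndarray, query: np.ndarray, k: int = 1):
    """k-nearest-neighbour prediction under Euclidean distance.

    Distance ties are broken toward the lowest training-row index; vote ties
    toward the nearer neighbour.  ``query`` may be one vector or a matrix of
    query rows.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    query_arr = np.atleast_2d(np.asarray(query, dtype=float))
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    if k > train_X.shape[0]:
        raise ValueError("k exceeds the number of training rows")
    train_y = np.asarray(train_y)
    dists = cdist(query_arr, train_X)
    order = np.argsort(dists, axis=1, kind="stable")[:, :k]
    preds = np.array([_majority_vote(train_y[row]) for row in order])
    single = np.asarray(query).ndim == 1
    return preds[0] if single else preds


def _cv_splits(y: np.ndarray, config: FSConfig):
    """Seed-deterministic stratified folds (reduced if a class is too small)."""
    y = np.asarray(y)
    if config.loocv:
        return list(LeaveOneOut().split(np.zeros_like(y), y))
    _, counts = np.unique(y, return_counts=True)
    n_splits = min(config.folds, int(counts.min()))
    if n_splits < 2:
        raise ValueError("every class needs at least 2 members for CV")
    skf = StratifiedKFold(
        n_splits=n_splits, shuffle=True, random_state=config.seed % (2**32)
    )
    return list(skf.split(np.zeros_like(y), y))


def fs_fitness(acc: float, dr: int, d: int, alpha: float) -> float:
    """Wrapper fitness alpha*(1-Acc) + (1-alpha)*DR/D, minimized in [0, 1]."""
    return alpha * (1.0 - acc) + (1.0 - alpha) * (dr / d)


def cv_error(
    data: LabeledMatrix,
    mask: FeatureMask,
    config: FSConfig,
    splits=None,
) -> FSEvaluation:
    """Cross-validated 1-NN score of one feature mask.

    Accuracy pools correct predictions over all held-out folds.  ``splits``
    lets a caller fix the fold assignment for a whole run; otherwise folds
    are derived deterministically from the config seed.
    """
    if mask.dr < 1:
        raise ValueError("mask selects no features")
    if data.n_samples < 2:
        raise ValueError("need at least 2 samples for cross-validation")
    if splits is None:
        splits = _cv_splits(data.y, config)
    Xm = data.X[:, mask.bits]
    correct = 0
    for train_idx, test_idx in splits:
        preds = knn_predict(
            Xm[train_idx], data.y[train_idx], Xm[test_idx], config.k_neighbors
        )
        correct += int(np.sum(preds == data.y[test_idx]))
    acc = correct / data.n_samples
    return FSEvaluation(
        acc=acc,
        error=1.0 - acc,
        dr=mask.dr,
        fitness=fs_fitness(acc, mask.dr, data.n_features, config.alpha),
    )


def run_babhgs_fs(
    data: LabeledMatrix,
    config: FSConfig,
    hgs_params: Optional[HGSParams] = None,
) -> FSResult:
    """Wrapper feature selection with the binary hybrid optimizer.

    Positions live in the unit box [0, 1] (so the hunger update's search
    range is 1); agents start as random 0/1 vectors, each continuous move is
    followed by the transfer-function sign update, and every evaluation
    decodes the position to a mask and scores it by cross-validated 1-NN
    fitness.  Strategy flags in ``config`` give bHGS / bAHGS / bBHGS /
    bABHGS.  The fold assignment is fixed once per run.
    """
    d = data.n_features
    splits = _cv_splits(data.y, config)
    decode_rng = np.random.default_rng((config.seed + 99991) % (2**31))

    best: dict = {"fitness": np.inf, "eval": None, "mask": None}

    def objective(x: np.ndarray) -> float:
        mask = decode_mask(x, decode_rng, config.decode)
        ev = cv_error(data, mask, config, splits=splits)
        if ev.fitness < best["fitness"]:
            best["fitness"] = ev.fitness
            best["eval"] = ev
            best["mask"] = mask
        return ev.fitness

    problem = ObjectiveProblem(
        name="feature-selection", dim=d, bounds=Bounds(0.0, 1.0), objective=objective
    )
    n, m = config.pop_size, config.pop_size // 2
    per_iter = n + (n if config.use_barebone else 0) + (2 * m if config.use_abc else 0)
    run_cfg = RunConfig(
        pop_size=n,
        max_evals=n + m + config.max_iters * per_iter,
        seed=config.seed,
        use_abc=config.use_abc,
        use_barebone=config.use_barebone,
        max_iters=config.max_iters,
    )

    t0 = time.perf_counter()
    result = run_abhgs(
        problem,
        run_cfg,
        params=hgs_params,
        move_postprocess=apply_transfer_update,
        init_sampler=lambda k, dim, gen: init_binary_population(k, dim, gen),
    )
    runtime = time.perf_counter() - t0

    ev: FSEvaluation = best["eval"]
    mask: FeatureMask = best["mask"]
    return FSResult(
        best_mask=mask,
        best_fitness=ev.fitness,
        error_rate=ev.error,
        accuracy=ev.acc,
        n_selected=ev.dr,
        selected_features=[data.feature_names[j] for j in mask.indices],
        convergence=result.convergence,
        evals_used=result.evals_used,
        runtime=runtime,
        seed=config.seed,
    )
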