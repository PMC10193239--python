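"""Synthetic gene-expression-like datasets and labeled-matrix IO.

Microarray gene-selection benchmarks are small-n / large-D matrices (tens of
samples, thousands of features, 2-10 classes).  The generator here produces
matrices of that shape with planted structure — a few informative features
whose class means are separated, redundant features that are noisy linear
combinations of the informative ones, and pure-noise features — so the whole
feature-selection pipeline can be exercised and its recovery measured against
a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SynthSpec",
    "LabeledMatrix",
    "make_synthetic_expression",
    "minmax_normalize",
    "read_labeled_csv",
    "write_labeled_csv",
]


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic expression matrix.

    ``effect_size`` (delta) is the separation between adjacent class means on
    informative features, in units of the within-class standard deviation
    (fixed at 1).  ``noise_sd`` scales the additive noise on redundant
    features.
    """

    n_samples: int = 60
    n_features: int = 2000
    n_informative: int = 10
    n_redundant: int = 0
    n_classes: int = 2
    effect_size: float = 3.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValueError("informative + redundant features exceed n_features")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_samples // self.n_classes < 2:
            raise ValueError("need at least 2 samples per class")
        if self.n_informative < 1:
            raise ValueError("need at least 1 informative feature")


@dataclass
class LabeledMatrix:
    """A sample-by-feature matrix with class labels.

    ``informative_idx`` carries the planted ground truth for synthetic
    fixtures; it is None for data read from disk.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    informative_idx: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on the number of samples")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length does not match X")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def minmax_normalize(X: np.ndarray) -> np.ndarray:
    """Per-feature rescale onto [-1, 1]: x' = 2(x - min)/(max - min) - 1.

    Constant features map to 0.
    """
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    out = np.zeros_like(X)
    ok = span > 0
    out[:, ok] = 2.0 * (X[:, ok] - lo[ok]) / span[ok] - 1.0
    return out


def make_synthetic_expression(spec: SynthSpec) -> LabeledMatrix:
    """Generate a labeled matrix with planted informative structure.

    Informative feature j in class c is N(mu_c, 1) with class means spaced
    ``effect_size`` apart.  Redundant features are random linear combinations
    (standard-normal coefficients) of the informative block plus
    N(0, noise_sd) noise.  The remaining features are N(0, 1) independent of
    the labels.  Labels are balanced; columns are shuffled and the matrix is
    min-max normalized to [-1, 1].  Ground-truth informative indices (after
    the shuffle) are recorded.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    g, r = spec.n_informative, spec.n_redundant

    # balanced labels: classes get floor(n/K) samples, remainder to the first
    counts = np.full(spec.n_classes, n // spec.n_classes)
    counts[: n % spec.n_classes] += 1
    y = np.repeat(np.arange(spec.n_classes), counts)

    centers = (np.arange(spec.n_classes) - (spec.n_classes - 1) / 2.0) * spec.effect_size
    X = rng.standard_normal((n, d))
    X[:, :g] += centers[y][:, None]
    if r > 0:
        w = rng.standard_normal((g, r)) / np.sqrt(g)
        X[:, g : g + r] = X[:, :g] @ w + spec.noise_sd * rng.standard_normal((n, r))

    perm = rng.permutation(d)
    X = X[:, perm]
    informative = np.flatnonzero(np.isin(perm, np.arange(g)))

    X = minmax_normalize(X)
    names = [f"gene_{j}" for j in range(d)]
    return LabeledMatrix(X=X, y=y, feature_names=names, informative_idx=informative)


def write_labeled_csv(data: LabeledMatrix, path, label_col: str = "label", sep: str = ",") -> None:
    """Write samples x features plus a label column as delimited text."""
    df = pd.DataFrame(data.X, columns=data.feature_names)
    df[label_col] = data.y
    df.to_csv(path, index=False, sep=sep)


def read_labeled_csv(path, label_col: str = "label", sep: str = ",") -> LabeledMatrix:
    """Read a delimited samples x features table with one label column.

    Raises a descriptive error for a missing label column, duplicate feature
    names, or non-numeric feature cells.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(sep)
    if len(set(header)) != len(header):  # pandas would silently mangle these
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"duplicate feature names in {path.name}: {dupes}")
    df = pd.read_csv(path, sep=sep)
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not found in {path.name} "
                         f"(columns: {list(df.columns)[:5]}...)")
    feature_cols = [c for c in df.columns if c != label_col]
    features = df[feature_cols]
    try:
        X = features.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric feature values in {path.name}: {exc}") from exc
    if np.isnan(X).any():
        raise ValueError(f"missing values in feature columns of {path.name}")
    return LabeledMatrix(X=X, y=df[label_col].to_numpy(), feature_names=feature_cols)
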