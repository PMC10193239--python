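"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from abhgs.core import Bounds, ObjectiveProblem


class ScriptedRNG:
    """A fake random generator replaying pre-scripted draws.

    Separate queues back the ``random``/``uniform``/``standard_normal``/
    ``integers`` methods, so a test can drive every stochastic branch of an
    operator deterministically and assert against a straight-line reference
    computation.
    """

    def __init__(self, uniform01=(), normal=(), ints=(), sym=()):
        self._uniform01 = list(uniform01)
        self._normal = list(normal)
        self._ints = list(ints)
        self._sym = list(sym)  # outputs of uniform(low, high, ...)

    def _take(self, queue: list, size):
        if size is None:
            return queue.pop(0)
        n = int(np.prod(size))
        vals = [queue.pop(0) for _ in range(n)]
        return np.asarray(vals, dtype=float).reshape(size)

    def random(self, size=None):
        return self._take(self._uniform01, size)

    def standard_normal(self, size=None):
        return self._take(self._normal, size)

    def uniform(self, low=0.0, high=1.0, size=None):
        return self._take(self._sym, size)

    def integers(self, low, high=None, size=None):
        assert size is None
        return self._ints.pop(0)

    def exhausted(self) -> bool:
        return not (self._uniform01 or self._normal or self._ints or self._sym)


@pytest.fixture
def scripted_rng_cls():
    return ScriptedRNG


def sphere_problem(dim: int, half_width: float = 100.0) -> ObjectiveProblem:
    return ObjectiveProblem(
        name="sphere",
        dim=dim,
        bounds=Bounds(-half_width, half_width),
        objective=lambda x: float(np.sum(x * x)),
    )


@pytest.fixture
def make_sphere():
    return sphere_problem
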