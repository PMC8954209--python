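"""Geometric aggregation operators for vague fuzzy numbers.

Three operators fuse a sequence of vague numbers into one:

* **IFWG** — weighted geometric mean applied positionally,
  ``(prod t_j^w_j, prod (1-f_j)^w_j)``.
* **IFOWG** — the values are first sorted by decreasing score (accuracy as
  tie-break), then IFWG is applied with position weights; input order is
  irrelevant.
* **IFHG** — hybrid: each value is first re-weighted by raising it to
  ``n * omega_j`` (importance weighting), the re-weighted values are sorted,
  and ordered position weights are applied.  With uniform importance weights
  it reduces exactly to IFOWG.

The ordered operators take their position weights from the
normal-distribution method: weights proportional to a Gaussian centred on
the middle rank, which softens the influence of extreme assessments.
"""

from __future__ import annotations

import functools
import math
from collections.abc import Iterable, Sequence

import numpy as np

from .vague import VagueNumber, _pow01, compare, vpow

__all__ = [
    "WeightVector",
    "WeightValidationError",
    "normal_owa_weights",
    "ifwg",
    "ifowg",
    "ifhg",
]

_SUM_TOL = 1e-9


class WeightValidationError(ValueError):
    """Raised when a weight vector is not a valid convex combination."""


class WeightVector(Sequence[float]):
    """Nonnegative weights summing to one.

    Validated on construction: every weight must be ``>= 0`` and the total
    must equal 1 within ``1e-9``.  Immutable sequence; supports ``len``,
    indexing and iteration.
    """

    __slots__ = ("_w",)

    def __init__(self, weights: Iterable[float]):
        w = tuple(float(x) for x in weights)
        if len(w) == 0:
            raise WeightValidationError("weight vector must be non-empty")
        for i, x in enumerate(w):
            if x < -_SUM_TOL or not math.isfinite(x):
                raise WeightValidationError(f"weight {i} is negative or non-finite: {x!r}")
        total = math.fsum(w)
        if abs(total - 1.0) > _SUM_TOL:
            raise WeightValidationError(f"weights sum to {total!r}, expected 1")
        self._w = tuple(max(x, 0.0) for x in w)

    @classmethod
    def uniform(cls, n: int) -> "WeightVector":
        if n < 1:
            raise WeightValidationError("n must be >= 1")
        return cls([1.0 / n] * n)

    def __len__(self) -> int:
        return len(self._w)

    def __getitem__(self, i):
        return self._w[i]

    def __iter__(self):
        return iter(self._w)

    def __eq__(self, other) -> bool:
        return isinstance(other, WeightVector) and self._w == other._w

    def __hash__(self) -> int:
        return hash(self._w)

    def __repr__(self) -> str:
        return f"WeightVector({list(self._w)!r})"

    def as_array(self) -> np.ndarray:
        return np.asarray(self._w)


def normal_owa_weights(n: int) -> WeightVector:
    """Ordered position weights from the normal-distribution method.

    With ``mu = (1+n)/2`` and population variance
    ``sigma^2 = (1/n) * sum_i (i - mu)^2`` over ranks ``i = 1..n``, position
    ``j`` receives weight proportional to ``exp(-(j-mu)^2 / (2 sigma^2))``,
    normalized to sum to 1.  The result is symmetric (``w_j = w_{n+1-j}``)
    and unimodal, de-emphasizing the extreme ranks.  ``n == 1`` gives
    ``[1.0]``.
    """
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if n == 1:
        return WeightVector([1.0])
    j = np.arange(1, n + 1, dtype=float)
    mu = (1.0 + n) / 2.0
    sigma2 = np.mean((j - mu) ** 2)
    g = np.exp(-((j - mu) ** 2) / (2.0 * sigma2))
    w = g / g.sum()
    # enforce exact symmetry against rounding drift
    w = (w + w[::-1]) / 2.0
    return WeightVector(w / w.sum())


def _check_lengths(values: Sequence[VagueNumber], *weight_vectors: WeightVector) -> int:
    n = len(values)
    if n == 0:
        raise ValueError("cannot aggregate an empty sequence of vague numbers")
    for wv in weight_vectors:
        if len(wv) != n:
            raise ValueError(f"length mismatch: {n} values but {len(wv)} weights")
    return n


def ifwg(values: Sequence[VagueNumber], weights: WeightVector) -> VagueNumber:
    """Weighted geometric aggregation, weights applied positionally.

    Returns ``(prod_j t_j^w_j, prod_j (1-f_j)^w_j)``.  No reordering takes
    place: weight ``w_j`` always multiplies the ``j``-th input.
    """
    weights = WeightVector(weights)
    _check_lengths(values, weights)
    t = math.prod(_pow01(v.t, w) for v, w in zip(values, weights))
    u = math.prod(_pow01(v.one_minus_f, w) for v, w in zip(values, weights))
    return VagueNumber(t, u)


def _sorted_desc(values: Sequence[VagueNumber]) -> list[VagueNumber]:
    # Descending by the tolerance-aware comparison (score, then accuracy);
    # the sort is stable so original position breaks remaining ties, and
    # each (t, 1-f) pair stays intact.
    return sorted(values, key=functools.cmp_to_key(compare), reverse=True)


def ifowg(values: Sequence[VagueNumber], ordered_weights: WeightVector) -> VagueNumber:
    """Ordered weighted geometric aggregation.

    Sorts the values by decreasing score (accuracy, then original index as
    tie-breaks) and applies :func:`ifwg` positionally with
    ``ordered_weights``; consequently the result does not depend on the
    order in which the values are supplied.
    """
    ordered_weights = WeightVector(ordered_weights)
    _check_lengths(values, ordered_weights)
    return ifwg(_sorted_desc(values), ordered_weights)


def ifhg(
    values: Sequence[VagueNumber],
    importance_weights: WeightVector,
    ordered_weights: WeightVector,
) -> VagueNumber:
    """Hybrid geometric aggregation.

    Each value is first raised componentwise to ``n * omega_j`` where
    ``omega`` are the importance weights (an importance above ``1/n``
    sharpens the assessment, below ``1/n`` flattens it toward ``(1, 1)``);
    the re-weighted values are then sorted by decreasing score and the
    ordered weights are applied to both components at each sorted position.

    With ``omega`` uniform every exponent is 1 and the operator coincides
    with :func:`ifowg`.
    """
    importance_weights = WeightVector(importance_weights)
    ordered_weights = WeightVector(ordered_weights)
    n = _check_lengths(values, importance_weights, ordered_weights)
    dotted = [vpow(v, n * w) for v, w in zip(values, importance_weights)]
    return ifwg(_sorted_desc(dotted), ordered_weights)
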