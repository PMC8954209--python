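"""Vague fuzzy number algebra.

A vague fuzzy number describes an assessment as an interval ``[t, 1-f]`` on
the unit line: ``t`` is the truth-membership (evidence in favour), ``f`` the
false-membership (evidence against), and the interval width ``1 - t - f`` is
the indeterminacy left by the assessor.  Consistency requires ``t + f <= 1``,
i.e. ``t <= 1 - f``.  This module provides the representation, the score and
accuracy defuzzification functions, a total preorder built from them, and the
componentwise power law that the geometric aggregation operators rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "VagueNumber",
    "VagueValidationError",
    "EPS",
    "score",
    "accuracy",
    "compare",
    "vpow",
]

#: Tolerance used by the constructor invariant checks.  Assessments are
#: typically elicited on a coarse one- or two-decimal grid and round-tripped
#: through text serialization, so exact floating comparisons would reject
#: legitimate inputs.
EPS = 1e-9


class VagueValidationError(ValueError):
    """Raised when a vague number violates its defining constraints."""


@dataclass(frozen=True, order=False)
class VagueNumber:
    """A vague fuzzy number stored as the interval ``(t, 1-f)``.

    Parameters
    ----------
    t
        Truth-membership, in ``[0, 1]``.
    one_minus_f
        Upper interval bound ``1 - f``, in ``[0, 1]``.  The false-membership
        is recovered as ``f = 1 - one_minus_f``.
    lenient
        When true, admit inconsistent numbers with ``t > 1 - f`` (flagged via
        :attr:`is_consistent`) instead of raising.  Off by default; intended
        only for representing inconsistent values found in external sources
        so they can be inspected and documented.
    """

    t: float
    one_minus_f: float
    lenient: bool = field(default=False, compare=False, repr=False)

    def __post_init__(self) -> None:
        t, u = float(self.t), float(self.one_minus_f)
        if not (-EPS <= t <= 1 + EPS):
            raise VagueValidationError(f"t={t!r} outside [0, 1]")
        if not (-EPS <= u <= 1 + EPS):
            raise VagueValidationError(f"one_minus_f={u!r} outside [0, 1]")
        if t > u + EPS and not self.lenient:
            raise VagueValidationError(
                f"inconsistent vague number: t={t!r} > 1-f={u!r} (t + f > 1)"
            )
        object.__setattr__(self, "t", min(max(t, 0.0), 1.0))
        object.__setattr__(self, "one_minus_f", min(max(u, 0.0), 1.0))

    @property
    def f(self) -> float:
        """False-membership ``1 - one_minus_f``."""
        return 1.0 - self.one_minus_f

    @property
    def is_consistent(self) -> bool:
        """Whether ``t + f <= 1`` holds (always true unless ``lenient``)."""
        return self.t <= self.one_minus_f + EPS

    def __iter__(self):
        yield self.t
        yield self.one_minus_f

    def __repr__(self) -> str:  # compact, table-like
        return f"({self.t:g}, {self.one_minus_f:g})"


def score(a: VagueNumber) -> float:
    """Score ``S(a) = t - f = t + (1-f) - 1``, in ``[-1, 1]``.

    The score is the defuzzified value used to order vague numbers and,
    after normalization, to turn aggregated assessments into weights.
    """
    return a.t - (1.0 - a.one_minus_f)


def accuracy(a: VagueNumber) -> float:
    """Accuracy ``t + f``, in ``[0, 1]``.

    Measures how much of the unit interval the assessment commits to either
    side; ``0`` is total indeterminacy.  Used as the secondary comparison key
    when scores tie.
    """
    return a.t + (1.0 - a.one_minus_f)


def compare(a: VagueNumber, b: VagueNumber, tol: float = 1e-12) -> int:
    """Three-way comparison: ``-1`` if ``a < b``, ``0`` if equal, ``1`` if greater.

    Primary key is the score; scores equal within ``tol`` fall back to the
    accuracy (higher accuracy ranks higher); both equal means equal.
    """
    sa, sb = score(a), score(b)
    if sa > sb + tol:
        return 1
    if sb > sa + tol:
        return -1
    ha, hb = accuracy(a), accuracy(b)
    if ha > hb + tol:
        return 1
    if hb > ha + tol:
        return -1
    return 0


def vpow(a: VagueNumber, lam: float) -> VagueNumber:
    """Componentwise power ``a^lam = (t^lam, (1-f)^lam)`` for ``lam >= 0``.

    Validity is preserved because ``x <= y`` implies ``x^lam <= y^lam`` on
    ``[0, 1]``.  The convention ``0**0 == 1`` applies, so a zero exponent
    makes any assessment vacuous ``(1, 1)`` rather than annihilating.
    """
    if lam < 0:
        raise ValueError(f"power exponent must be nonnegative, got {lam!r}")
    return VagueNumber(_pow01(a.t, lam), _pow01(a.one_minus_f, lam))


def _pow01(x: float, lam: float) -> float:
    if lam == 0.0:
        return 1.0  # includes 0**0
    return x**lam
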