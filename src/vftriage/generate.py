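"""Seeded generator of random valid triage problems.

Emulates the elicitation setting of the bundled case study: every
assessment is a vague number drawn on a coarse grid (default step 0.1,
matching one-decimal expert inputs).  For each cell the upper bound
``one_minus_f`` is drawn uniformly from the grid points of ``[0, 1]`` and
``t`` uniformly from the grid points of ``[0, one_minus_f]``, so validity
holds by construction.  All randomness flows through a single
``numpy.random.Generator`` seeded from the config; identical configs give
identical problems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import DecisionMatrix, PeerMatrix, TriageProblem
from .vague import VagueNumber

__all__ = ["GeneratorConfig", "generate_problem"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape, seed and value grid of a synthetic problem."""

    n_experts: int
    n_criteria: int
    n_patients: int
    seed: int
    grid: float = 0.1

    def __post_init__(self) -> None:
        if self.n_experts < 2:
            raise ValueError("need at least 2 experts (peer assessment is mutual)")
        if self.n_criteria < 1 or self.n_patients < 1:
            raise ValueError("need at least 1 criterion and 1 patient")
        steps = round(1.0 / self.grid)
        if not (0 < self.grid <= 1) or abs(steps * self.grid - 1.0) > 1e-9:
            raise ValueError(f"grid step {self.grid!r} must divide 1 exactly")


def _draw_cell(rng: np.random.Generator, steps: int) -> VagueNumber:
    upper = int(rng.integers(0, steps + 1))
    lower = int(rng.integers(0, upper + 1))
    return VagueNumber(lower / steps, upper / steps)


def generate_problem(config: GeneratorConfig) -> TriageProblem:
    """Generate a random valid :class:`TriageProblem` from a seeded config."""
    rng = np.random.default_rng(config.seed)
    steps = round(1.0 / config.grid)
    experts = tuple(f"E{i + 1}" for i in range(config.n_experts))
    criteria = tuple(f"C{i + 1}" for i in range(config.n_criteria))
    patients = tuple(f"P{i + 1}" for i in range(config.n_patients))

    peer = PeerMatrix(
        experts,
        tuple(
            tuple(None if i == j else _draw_cell(rng, steps) for j in range(len(experts)))
            for i in range(len(experts))
        ),
    )
    crit = DecisionMatrix(
        experts,
        criteria,
        tuple(
            tuple(_draw_cell(rng, steps) for _ in criteria) for _ in experts
        ),
    )
    pa = tuple(
        DecisionMatrix(
            criteria,
            patients,
            tuple(tuple(_draw_cell(rng, steps) for _ in patients) for _ in criteria),
        )
        for _ in experts
    )
    return TriageProblem(
        experts=experts,
        criteria=criteria,
        patients=patients,
        peer=peer,
        criteria_assessments=crit,
        patient_assessments=pa,
    )
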