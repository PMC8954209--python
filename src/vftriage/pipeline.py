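"""The triage hierarchization pipeline.

Four computational stages turn raw vague-fuzzy assessments into a priority
ranking of ICU-admission candidates:

1. **Expert weighting** — each expert's peers assess them; the assessments
   received are fused with IFOWG (normal-distribution ordered weights), the
   fused values are defuzzified by the score function, and the scores are
   normalized to a weight vector.
2. **Criteria weighting** — the experts assess every criterion; per
   criterion the assessments are fused with IFHG using the expert weights
   as importance weights, then defuzzified and normalized as above.
3. **Collective matrix** — per (criterion, patient) cell, the experts'
   patient assessments are fused with IFHG using the expert weights.
4. **Aggregation and ranking** — per patient, the collective column is
   fused across criteria with IFWG using the criteria weights; patients are
   ranked by decreasing score of the resulting aggregate.

The final admission decision is made by the clinical team; this pipeline
only produces the recommendation and every intermediate artifact needed to
audit it.
"""

from __future__ import annotations

import functools
from collections.abc import Sequence
from dataclasses import dataclass, field

from .operators import WeightVector, ifhg, ifwg, ifowg, normal_owa_weights
from .vague import VagueNumber, compare, score

__all__ = [
    "PeerMatrix",
    "DecisionMatrix",
    "TriageProblem",
    "WeightingBlock",
    "HierarchyResult",
    "DegenerateScoreError",
    "ShapeError",
    "StageError",
    "scores_to_weights",
    "expert_weights",
    "criteria_weights",
    "collective_matrix",
    "aggregate_patients",
    "rank_patients",
    "run_triage",
]


class ShapeError(ValueError):
    """Raised when matrix shapes or label sets are inconsistent."""


class DegenerateScoreError(ValueError):
    """Raised when a score to be normalized into a weight is not positive."""


class StageError(RuntimeError):
    """Wraps an error raised inside a pipeline stage with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _check_unique(labels: Sequence[str], what: str) -> tuple[str, ...]:
    labels = tuple(labels)
    if len(set(labels)) != len(labels):
        raise ShapeError(f"duplicate {what} labels: {list(labels)}")
    return labels


@dataclass(frozen=True)
class PeerMatrix:
    """Square experts-by-experts grid of peer assessments; diagonal absent.

    ``entries[i][j]`` is expert ``i``'s assessment of expert ``j`` and must
    be ``None`` exactly on the diagonal (an expert does not assess
    themselves).
    """

    expert_labels: tuple[str, ...]
    entries: tuple[tuple[VagueNumber | None, ...], ...]

    def __post_init__(self) -> None:
        labels = _check_unique(self.expert_labels, "expert")
        object.__setattr__(self, "expert_labels", labels)
        n = len(labels)
        if n < 2:
            raise ShapeError("peer matrix needs at least 2 experts")
        rows = tuple(tuple(r) for r in self.entries)
        if len(rows) != n or any(len(r) != n for r in rows):
            raise ShapeError(f"peer matrix must be {n}x{n}")
        for i in range(n):
            for j in range(n):
                cell = rows[i][j]
                if i == j:
                    if cell is not None:
                        raise ShapeError(f"diagonal cell ({labels[i]},{labels[j]}) must be absent")
                elif not isinstance(cell, VagueNumber):
                    raise ShapeError(f"cell ({labels[i]},{labels[j]}) missing or not a vague number")
        object.__setattr__(self, "entries", rows)

    @property
    def n_experts(self) -> int:
        return len(self.expert_labels)

    def received_by(self, j: int) -> list[VagueNumber]:
        """Assessments received by expert ``j`` (column ``j``, row order)."""
        return [self.entries[i][j] for i in range(self.n_experts) if i != j]


@dataclass(frozen=True)
class DecisionMatrix:
    """Labelled rectangular grid of vague numbers.

    Rows are criteria and columns patients for patient-status matrices;
    rows are experts and columns criteria for the criteria-assessment
    matrix.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    entries: tuple[tuple[VagueNumber, ...], ...]

    def __post_init__(self) -> None:
        rl = _check_unique(self.row_labels, "row")
        cl = _check_unique(self.col_labels, "column")
        object.__setattr__(self, "row_labels", rl)
        object.__setattr__(self, "col_labels", cl)
        rows = tuple(tuple(r) for r in self.entries)
        if len(rows) != len(rl) or any(len(r) != len(cl) for r in rows):
            raise ShapeError(
                f"matrix must be {len(rl)}x{len(cl)}, got "
                f"{len(rows)}x{len(rows[0]) if rows else 0}"
            )
        for i, r in enumerate(rows):
            for j, cell in enumerate(r):
                if not isinstance(cell, VagueNumber):
                    raise ShapeError(f"cell ({rl[i]},{cl[j]}) is not a vague number")
        object.__setattr__(self, "entries", rows)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_labels), len(self.col_labels))

    def column(self, j: int) -> list[VagueNumber]:
        return [row[j] for row in self.entries]

    def to_frame(self):
        """Render as a pandas DataFrame of (t, 1-f) tuples, for display."""
        import pandas as pd

        return pd.DataFrame(
            [[(c.t, c.one_minus_f) for c in row] for row in self.entries],
            index=list(self.row_labels),
            columns=list(self.col_labels),
        )


@dataclass(frozen=True)
class TriageProblem:
    """A complete group decision problem.

    Holds the peer assessments, the criteria assessments and one
    criteria-by-patients decision matrix per expert, with consistent label
    sets throughout.  Optional fixed weight vectors, when present, bypass
    the corresponding weighting stage.
    """

    experts: tuple[str, ...]
    criteria: tuple[str, ...]
    patients: tuple[str, ...]
    peer: PeerMatrix
    criteria_assessments: DecisionMatrix
    patient_assessments: tuple[DecisionMatrix, ...]
    fixed_expert_weights: WeightVector | None = None
    fixed_criteria_weights: WeightVector | None = None

    def __post_init__(self) -> None:
        experts = _check_unique(self.experts, "expert")
        criteria = _check_unique(self.criteria, "criteria")
        patients = _check_unique(self.patients, "patient")
        object.__setattr__(self, "experts", experts)
        object.__setattr__(self, "criteria", criteria)
        object.__setattr__(self, "patients", patients)
        object.__setattr__(self, "patient_assessments", tuple(self.patient_assessments))
        if self.peer.expert_labels != experts:
            raise ShapeError("peer matrix labels disagree with expert labels")
        ca = self.criteria_assessments
        if ca.row_labels != experts or ca.col_labels != criteria:
            raise ShapeError("criteria-assessment matrix must be experts x criteria")
        if len(self.patient_assessments) != len(experts):
            raise ShapeError(
                f"need one patient matrix per expert: "
                f"{len(self.patient_assessments)} matrices for {len(experts)} experts"
            )
        for label, m in zip(experts, self.patient_assessments):
            if m.row_labels != criteria or m.col_labels != patients:
                raise ShapeError(f"patient matrix of {label} must be criteria x patients")
        if self.fixed_expert_weights is not None and len(self.fixed_expert_weights) != len(experts):
            raise ShapeError("fixed expert weights length mismatch")
        if self.fixed_criteria_weights is not None and len(self.fixed_criteria_weights) != len(
            criteria
        ):
            raise ShapeError("fixed criteria weights length mismatch")


@dataclass(frozen=True)
class WeightingBlock:
    """Audit record of one weighting stage: aggregates, scores, weights."""

    labels: tuple[str, ...]
    aggregates: tuple[VagueNumber, ...]
    scores: tuple[float, ...]
    weights: WeightVector
    derivation: str  # "derived", "derived+shifted" or "fixed"


@dataclass(frozen=True)
class HierarchyResult:
    """Everything the pipeline produced, from weights to the final ranking.

    ``ranking`` lists patient labels by decreasing score; ``tie_groups``
    collects the groups (size >= 2) of patients whose aggregates compare
    equal and whose relative order is therefore label order only.
    """

    expert_block: WeightingBlock
    criteria_block: WeightingBlock
    collective: DecisionMatrix
    patients: tuple[str, ...]
    aggregates: tuple[VagueNumber, ...]
    scores: tuple[float, ...]
    ranking: tuple[str, ...]
    tie_groups: tuple[tuple[str, ...], ...] = field(default=())

    @property
    def expert_weights(self) -> WeightVector:
        return self.expert_block.weights

    @property
    def criteria_weights(self) -> WeightVector:
        return self.criteria_block.weights


def scores_to_weights(scores: Sequence[float], *, shift: bool = False) -> WeightVector:
    """Normalize positive scores into a weight vector ``s / sum(s)``.

    In strict mode (default) any score ``<= 0`` raises
    :class:`DegenerateScoreError`: scores live in ``[-1, 1]`` and silently
    normalizing negatives would flip priorities.  With ``shift=True`` the
    scores are first translated by ``x -> x - min(x) + delta`` with
    ``delta = (max - min) / 100`` (or 1 if all equal) so that all become
    positive; callers must record that the shift was applied.
    """
    s = [float(x) for x in scores]
    if len(s) == 0:
        raise DegenerateScoreError("no scores to normalize")
    if shift:
        lo, hi = min(s), max(s)
        delta = (hi - lo) / 100.0 if hi > lo else 1.0
        s = [x - lo + delta for x in s]
    else:
        for i, x in enumerate(s):
            if x <= 0:
                raise DegenerateScoreError(
                    f"score at position {i} is {x!r}; all scores must be positive "
                    "to normalize into weights (pass shift mode to translate)"
                )
    total = sum(s)
    return WeightVector([x / total for x in s])


def expert_weights(
    peer: PeerMatrix, *, shift: bool = False
) -> tuple[WeightVector, tuple[VagueNumber, ...], tuple[float, ...]]:
    """Derive expert weights from the peer-assessment matrix.

    For each expert the ``n - 1`` assessments *received* from colleagues are
    fused with IFOWG under normal-distribution ordered weights, defuzzified
    by the score function, and the scores normalized to weights.  Returns
    ``(weights, per-expert aggregates, per-expert scores)``.
    """
    n = peer.n_experts
    w = normal_owa_weights(n - 1)
    aggs = tuple(ifowg(peer.received_by(j), w) for j in range(n))
    scs = tuple(score(a) for a in aggs)
    return scores_to_weights(scs, shift=shift), aggs, scs


def criteria_weights(
    criteria_assessments: DecisionMatrix, omega: WeightVector, *, shift: bool = False
) -> tuple[WeightVector, tuple[VagueNumber, ...], tuple[float, ...]]:
    """Derive criteria weights from the experts' criteria assessments.

    Per criterion (column) the expert assessments are fused with IFHG using
    the expert weights ``omega`` as importance weights and
    normal-distribution ordered weights, then defuzzified and normalized.
    """
    n_experts, n_criteria = criteria_assessments.shape
    if len(omega) != n_experts:
        raise ShapeError(f"{len(omega)} expert weights for {n_experts} experts")
    w = normal_owa_weights(n_experts)
    aggs = tuple(
        ifhg(criteria_assessments.column(j), omega, w) for j in range(n_criteria)
    )
    scs = tuple(score(a) for a in aggs)
    return scores_to_weights(scs, shift=shift), aggs, scs


def collective_matrix(
    patient_assessments: Sequence[DecisionMatrix], omega: WeightVector
) -> DecisionMatrix:
    """Fuse the per-expert patient matrices into the collective matrix.

    Every (criterion, patient) cell of the result is the IFHG aggregate of
    that cell across experts, with the expert weights ``omega`` as
    importance weights and normal-distribution ordered weights.
    """
    mats = list(patient_assessments)
    if not mats:
        raise ShapeError("no patient-assessment matrices supplied")
    rl, cl = mats[0].row_labels, mats[0].col_labels
    for m in mats[1:]:
        if m.row_labels != rl or m.col_labels != cl:
            raise ShapeError("patient matrices disagree on row/column labels")
    if len(omega) != len(mats):
        raise ShapeError(f"{len(omega)} expert weights for {len(mats)} matrices")
    w = normal_owa_weights(len(mats))
    cells = tuple(
        tuple(
            ifhg([m.entries[i][j] for m in mats], omega, w) for j in range(len(cl))
        )
        for i in range(len(rl))
    )
    return DecisionMatrix(rl, cl, cells)


def aggregate_patients(
    collective: DecisionMatrix, criteria_w: WeightVector
) -> tuple[VagueNumber, ...]:
    """Fuse each patient's collective column across criteria with IFWG.

    The criteria weights are applied positionally — criterion ``i`` always
    carries weight ``criteria_w[i]`` — with no reordering.
    """
    n_criteria, n_patients = collective.shape
    if len(criteria_w) != n_criteria:
        raise ShapeError(f"{len(criteria_w)} criteria weights for {n_criteria} criteria")
    return tuple(ifwg(collective.column(j), criteria_w) for j in range(n_patients))


def rank_patients(
    patients: Sequence[str], aggregates: Sequence[VagueNumber]
) -> tuple[tuple[str, ...], tuple[tuple[str, ...], ...]]:
    """Order patients by decreasing score of their aggregate vague value.

    Ties on (score, accuracy) are broken by label order and reported as tie
    groups so downstream consumers know the order within a group carries no
    information.
    """
    if len(patients) != len(aggregates):
        raise ShapeError("patients/aggregates length mismatch")
    if len(patients) == 0:
        raise ShapeError("at least one patient required")

    def cmp(i: int, j: int) -> int:
        c = compare(aggregates[i], aggregates[j])
        if c != 0:
            return -c  # higher aggregate first
        return -1 if patients[i] < patients[j] else (1 if patients[i] > patients[j] else 0)

    idx = sorted(range(len(patients)), key=functools.cmp_to_key(cmp))
    ranking = tuple(patients[j] for j in idx)
    groups: list[tuple[str, ...]] = []
    current = [idx[0]]
    for prev, cur in zip(idx, idx[1:]):
        if compare(aggregates[prev], aggregates[cur]) == 0:
            current.append(cur)
        else:
            if len(current) > 1:
                groups.append(tuple(patients[j] for j in current))
            current = [cur]
    if len(current) > 1:
        groups.append(tuple(patients[j] for j in current))
    return ranking, tuple(groups)


def run_triage(
    problem: TriageProblem,
    *,
    use_fixed_weights: bool = False,
    shift_negative_scores: bool = False,
) -> HierarchyResult:
    """Run the full pipeline on a problem and return the audited result.

    ``use_fixed_weights`` substitutes the problem's fixed expert/criteria
    weight vectors (where present) for the derived ones; assessments are
    still aggregated so the audit record stays complete.
    ``shift_negative_scores`` opts in to the shift-normalization of
    :func:`scores_to_weights` instead of failing on non-positive scores.
    """

    def _stage(name, fn):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001 - re-raise with stage context
            raise StageError(name, e) from e

    def _expert_block() -> WeightingBlock:
        ew, aggs, scs = expert_weights(problem.peer, shift=shift_negative_scores)
        how = "derived+shifted" if shift_negative_scores else "derived"
        if use_fixed_weights and problem.fixed_expert_weights is not None:
            ew, how = problem.fixed_expert_weights, "fixed"
        return WeightingBlock(problem.experts, aggs, scs, ew, how)

    eb = _stage("expert_weights", _expert_block)

    def _criteria_block() -> WeightingBlock:
        cw, aggs, scs = criteria_weights(
            problem.criteria_assessments, eb.weights, shift=shift_negative_scores
        )
        how = "derived+shifted" if shift_negative_scores else "derived"
        if use_fixed_weights and problem.fixed_criteria_weights is not None:
            cw, how = problem.fixed_criteria_weights, "fixed"
        return WeightingBlock(problem.criteria, aggs, scs, cw, how)

    cb = _stage("criteria_weights", _criteria_block)
    coll = _stage(
        "collective_matrix", lambda: collective_matrix(problem.patient_assessments, eb.weights)
    )
    aggs = _stage("aggregate_patients", lambda: aggregate_patients(coll, cb.weights))
    scs = tuple(score(a) for a in aggs)
    ranking, ties = _stage("rank_patients", lambda: rank_patients(problem.patients, aggs))
    return HierarchyResult(
        expert_block=eb,
        criteria_block=cb,
        collective=coll,
        patients=problem.patients,
        aggregates=aggs,
        scores=scs,
        ranking=ranking,
        tie_groups=ties,
    )
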