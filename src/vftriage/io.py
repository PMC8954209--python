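"""Problem serialization: JSON documents, CSV bundles, bundled case study.

The canonical on-disk form is a versioned JSON document holding the label
lists, the peer-assessment matrix (``null`` diagonal), the
criteria-assessment matrix, one criteria-by-patients matrix per expert and
optional fixed weight vectors.  Every vague number is a two-element array
``[t, one_minus_f]``.

A CSV bundle (a directory) is also accepted for spreadsheet-origin data:
``peer.csv``, ``criteria.csv`` and ``patients_<expert>.csv``, each with a
header row and an index column, cells written as ``"t;one_minus_f"`` and
the peer diagonal as ``"-"``.  Orientation is fixed — peer rows/columns are
experts, criteria.csv rows are experts and columns criteria, patient files
have criteria rows and patient columns — and unlabelled matrices are
rejected rather than guessed at.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .operators import WeightVector
from .pipeline import DecisionMatrix, PeerMatrix, TriageProblem
from .vague import VagueNumber, VagueValidationError

__all__ = [
    "SCHEMA_VERSION",
    "ProblemFormatError",
    "load_problem",
    "save_problem",
    "problem_to_document",
    "problem_from_document",
    "load_case_study",
]

SCHEMA_VERSION = "1"

_CASE_STUDY_RESOURCE = "case_study.json"


class ProblemFormatError(ValueError):
    """Raised for malformed problem documents, with cell location where known."""


def _cell(value, where: str) -> VagueNumber:
    if (
        not isinstance(value, (list, tuple))
        or len(value) != 2
        or not all(isinstance(x, (int, float)) for x in value)
    ):
        raise ProblemFormatError(f"{where}: expected a [t, one_minus_f] pair, got {value!r}")
    try:
        return VagueNumber(float(value[0]), float(value[1]))
    except VagueValidationError as e:
        raise ProblemFormatError(f"{where}: {e}") from e


def _labels(doc: dict, key: str) -> tuple[str, ...]:
    v = doc.get(key)
    if not isinstance(v, list) or not v or not all(isinstance(x, str) for x in v):
        raise ProblemFormatError(f"'{key}' must be a non-empty list of strings")
    return tuple(v)


def problem_from_document(doc: dict) -> TriageProblem:
    """Validate a parsed JSON document and build a :class:`TriageProblem`."""
    if not isinstance(doc, dict):
        raise ProblemFormatError("document root must be an object")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ProblemFormatError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION!r})"
        )
    experts = _labels(doc, "experts")
    criteria = _labels(doc, "criteria")
    patients = _labels(doc, "patients")

    raw_peer = doc.get("peer_assessments")
    n = len(experts)
    if not isinstance(raw_peer, list) or len(raw_peer) != n:
        raise ProblemFormatError(f"'peer_assessments' must be a {n}x{n} array")
    peer_rows = []
    for i, row in enumerate(raw_peer):
        if not isinstance(row, list) or len(row) != n:
            raise ProblemFormatError(f"peer_assessments row {experts[i]}: expected {n} entries")
        cells = []
        for j, value in enumerate(row):
            where = f"peer_assessments ({experts[i]},{experts[j]})"
            if i == j:
                if value is not None:
                    raise ProblemFormatError(f"{where}: diagonal must be null")
                cells.append(None)
            else:
                cells.append(_cell(value, where))
        peer_rows.append(tuple(cells))
    peer = PeerMatrix(experts, tuple(peer_rows))

    def grid(raw, rows, cols, name) -> DecisionMatrix:
        if not isinstance(raw, list) or len(raw) != len(rows):
            raise ProblemFormatError(f"'{name}' must be a {len(rows)}x{len(cols)} array")
        out = []
        for i, r in enumerate(raw):
            if not isinstance(r, list) or len(r) != len(cols):
                raise ProblemFormatError(f"{name} row {rows[i]}: expected {len(cols)} entries")
            out.append(tuple(_cell(v, f"{name} ({rows[i]},{cols[j]})") for j, v in enumerate(r)))
        return DecisionMatrix(rows, cols, tuple(out))

    crit = grid(doc.get("criteria_assessments"), experts, criteria, "criteria_assessments")

    raw_pa = doc.get("patient_assessments")
    if not isinstance(raw_pa, dict) or set(raw_pa) != set(experts):
        raise ProblemFormatError("'patient_assessments' must map every expert label to a matrix")
    pa = tuple(
        grid(raw_pa[e], criteria, patients, f"patient_assessments[{e}]") for e in experts
    )

    def fixed(key, length) -> WeightVector | None:
        v = doc.get(key)
        if v is None:
            return None
        if not isinstance(v, list) or len(v) != length:
            raise ProblemFormatError(f"'{key}' must be a list of {length} numbers")
        return WeightVector(v)

    return TriageProblem(
        experts=experts,
        criteria=criteria,
        patients=patients,
        peer=peer,
        criteria_assessments=crit,
        patient_assessments=pa,
        fixed_expert_weights=fixed("fixed_expert_weights", len(experts)),
        fixed_criteria_weights=fixed("fixed_criteria_weights", len(criteria)),
    )


def problem_to_document(problem: TriageProblem) -> dict:
    """Serialize a problem back to its canonical JSON document form."""
    pair = lambda c: [c.t, c.one_minus_f]  # noqa: E731
    doc: dict = {
        "schema_version": SCHEMA_VERSION,
        "experts": list(problem.experts),
        "criteria": list(problem.criteria),
        "patients": list(problem.patients),
        "peer_assessments": [
            [None if c is None else pair(c) for c in row] for row in problem.peer.entries
        ],
        "criteria_assessments": [
            [pair(c) for c in row] for row in problem.criteria_assessments.entries
        ],
        "patient_assessments": {
            e: [[pair(c) for c in row] for row in m.entries]
            for e, m in zip(problem.experts, problem.patient_assessments)
        },
    }
    if problem.fixed_expert_weights is not None:
        doc["fixed_expert_weights"] = list(problem.fixed_expert_weights)
    if problem.fixed_criteria_weights is not None:
        doc["fixed_criteria_weights"] = list(problem.fixed_criteria_weights)
    return doc


def load_problem(path: str | Path) -> TriageProblem:
    """Load a problem from a JSON file or a CSV bundle directory."""
    p = Path(path)
    if p.is_dir():
        return _load_csv_bundle(p)
    try:
        with open(p, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise ProblemFormatError(f"{p}: not valid JSON ({e})") from e
    try:
        return problem_from_document(doc)
    except ProblemFormatError as e:
        raise ProblemFormatError(f"{p}: {e}") from e


def save_problem(problem: TriageProblem, path: str | Path) -> None:
    """Write a problem as a canonical JSON document (UTF-8, 1-space indent)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(problem_to_document(problem), fh, indent=1)
        fh.write("\n")


def _parse_csv_cell(text, where: str):
    s = str(text).strip()
    if s == "-":
        return None
    parts = s.split(";")
    if len(parts) != 2:
        raise ProblemFormatError(f"{where}: expected 't;one_minus_f', got {text!r}")
    try:
        return [float(parts[0]), float(parts[1])]
    except ValueError as e:
        raise ProblemFormatError(f"{where}: non-numeric component in {text!r}") from e


def _read_csv_matrix(path: Path) -> tuple[list[str], list[str], list[list]]:
    df = pd.read_csv(path, index_col=0, dtype=str)
    if df.index.isnull().any() or any(str(c).startswith("Unnamed") for c in df.columns):
        raise ProblemFormatError(f"{path.name}: matrices must carry row and column labels")
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    cells = [
        [_parse_csv_cell(df.iat[i, j], f"{path.name} ({rows[i]},{cols[j]})") for j in range(len(cols))]
        for i in range(len(rows))
    ]
    return rows, cols, cells


def _load_csv_bundle(directory: Path) -> TriageProblem:
    peer_path = directory / "peer.csv"
    crit_path = directory / "criteria.csv"
    if not peer_path.exists() or not crit_path.exists():
        raise ProblemFormatError(f"{directory}: CSV bundle needs peer.csv and criteria.csv")
    experts, peer_cols, peer_cells = _read_csv_matrix(peer_path)
    if experts != peer_cols:
        raise ProblemFormatError("peer.csv row and column labels must match")
    crit_rows, criteria, crit_cells = _read_csv_matrix(crit_path)
    if crit_rows != experts:
        raise ProblemFormatError("criteria.csv rows must be the experts of peer.csv")
    pa: dict[str, list] = {}
    patients: list[str] | None = None
    for e in experts:
        f = directory / f"patients_{e}.csv"
        if not f.exists():
            raise ProblemFormatError(f"{directory}: missing {f.name}")
        rows, cols, cells = _read_csv_matrix(f)
        if rows != criteria:
            raise ProblemFormatError(f"{f.name}: rows must be the criteria of criteria.csv")
        if patients is None:
            patients = cols
        elif cols != patients:
            raise ProblemFormatError(f"{f.name}: patient columns disagree across experts")
        pa[e] = cells
    doc = {
        "schema_version": SCHEMA_VERSION,
        "experts": experts,
        "criteria": criteria,
        "patients": patients,
        "peer_assessments": peer_cells,
        "criteria_assessments": crit_cells,
        "patient_assessments": pa,
    }
    return problem_from_document(doc)


def load_case_study() -> TriageProblem:
    """Load the bundled five-expert, five-criterion, five-patient case study.

    The fixture ships with the published expert and criteria weight vectors
    as ``fixed_*_weights`` so the documented collective matrix, aggregates
    and ranking can be reproduced exactly via ``use_fixed_weights=True``.
    """
    text = resources.files("vftriage.data").joinpath(_CASE_STUDY_RESOURCE).read_text("utf-8")
    return problem_from_document(json.loads(text))
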