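"""Human- and machine-readable audit reports for hierarchy results.

The text report mirrors the conventions of the published tables: weight
vectors and weighting-block aggregates at 2 decimals, the collective
matrix, aggregates and scores at 3 decimals.  The JSON report is
schema-stable and carries full double precision so that reloading it
recovers the scores exactly.
"""

from __future__ import annotations

import json

from .pipeline import HierarchyResult, WeightingBlock

__all__ = ["render_report", "report_to_dict"]


def report_to_dict(result: HierarchyResult) -> dict:
    """Full-precision, schema-stable dictionary form of a result."""

    def block(b: WeightingBlock) -> dict:
        return {
            "labels": list(b.labels),
            "aggregates": [[a.t, a.one_minus_f] for a in b.aggregates],
            "scores": list(b.scores),
            "weights": list(b.weights),
            "derivation": b.derivation,
        }

    return {
        "report_version": "1",
        "expert_weighting": block(result.expert_block),
        "criteria_weighting": block(result.criteria_block),
        "collective_matrix": {
            "criteria": list(result.collective.row_labels),
            "patients": list(result.collective.col_labels),
            "cells": [[[c.t, c.one_minus_f] for c in row] for row in result.collective.entries],
        },
        "patients": list(result.patients),
        "aggregates": [[a.t, a.one_minus_f] for a in result.aggregates],
        "scores": list(result.scores),
        "ranking": list(result.ranking),
        "tie_groups": [list(g) for g in result.tie_groups],
    }


def _fmt_pairs(labels, pairs, nd: int) -> str:
    return "  ".join(
        f"{lab}=({p[0]:.{nd}f}, {p[1]:.{nd}f})" for lab, p in zip(labels, pairs)
    )


def _fmt_vec(labels, values, nd: int) -> str:
    return "  ".join(f"{lab}={v:.{nd}f}" for lab, v in zip(labels, values))


def render_report(result: HierarchyResult, format: str = "text") -> str:
    """Render a result as ``text`` (rounded tables) or ``json`` (exact)."""
    if format == "json":
        return json.dumps(report_to_dict(result), indent=1, sort_keys=True)
    if format != "text":
        raise ValueError(f"unknown report format {format!r}")

    r = result
    lines: list[str] = []
    lines.append("=== Expert weighting ===")
    lines.append(
        "aggregates: " + _fmt_pairs(r.expert_block.labels, [tuple(a) for a in r.expert_block.aggregates], 2)
    )
    lines.append("scores:     " + _fmt_vec(r.expert_block.labels, r.expert_block.scores, 2))
    lines.append(
        f"weights ({r.expert_block.derivation}): "
        + _fmt_vec(r.expert_block.labels, r.expert_block.weights, 2)
    )
    lines.append("=== Criteria weighting ===")
    lines.append(
        "aggregates: " + _fmt_pairs(r.criteria_block.labels, [tuple(a) for a in r.criteria_block.aggregates], 2)
    )
    lines.append("scores:     " + _fmt_vec(r.criteria_block.labels, r.criteria_block.scores, 2))
    lines.append(
        f"weights ({r.criteria_block.derivation}): "
        + _fmt_vec(r.criteria_block.labels, r.criteria_block.weights, 2)
    )
    lines.append("=== Collective matrix (criteria x patients) ===")
    header = "      " + "  ".join(f"{p:>14s}" for p in r.collective.col_labels)
    lines.append(header)
    for crit, row in zip(r.collective.row_labels, r.collective.entries):
        cells = "  ".join(f"({c.t:.3f}, {c.one_minus_f:.3f})" for c in row)
        lines.append(f"{crit:<6s}{cells}")
    lines.append("=== Patient aggregates and scores ===")
    lines.append("aggregates: " + _fmt_pairs(r.patients, [tuple(a) for a in r.aggregates], 3))
    lines.append("scores:     " + _fmt_vec(r.patients, r.scores, 3))
    lines.append("=== Ranking (highest priority first) ===")
    lines.append(" > ".join(r.ranking))
    if r.tie_groups:
        for g in r.tie_groups:
            lines.append("tied (order not informative): " + ", ".join(g))
    return "\n".join(lines)
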