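"""File formats: condition-graph and demand TSV, solution JSON, SIF export.

The primary interchange format is tab-separated text: a graph file with
columns ``source  target  weight  conditions`` (conditions comma-separated,
1-based) and a demand file with columns ``source  target  condition``.
Confidence scores from interaction databases are converted to weights by
the negative logarithm, so a minimum-weight subgraph is a maximum-likelihood
one under edge independence.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .model import (
    ConditionGraph,
    ConditionGraphError,
    CSNInstance,
    Demand,
    Solution,
)


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line number."""


GRAPH_COLUMNS = ["source", "target", "weight", "conditions"]
DEMAND_COLUMNS = ["source", "target", "condition"]


def _parse_conditions(text, line: int) -> frozenset:
    try:
        conds = frozenset(int(tok) for tok in str(text).split(",") if tok != "")
    except ValueError:
        raise ParseError(f"line {line}: malformed condition list {text!r}") from None
    if not conds:
        raise ParseError(f"line {line}: empty condition list")
    return conds


def read_condition_graph(path, directed: bool = False,
                         num_conditions: Optional[int] = None) -> ConditionGraph:
    """Read a condition graph from TSV.

    Duplicate rows for one edge are merged by condition-set union provided
    their weights agree; conflicting weights are an error naming both lines.
    ``num_conditions`` defaults to the largest condition index seen.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GRAPH_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s) {missing} in {path}")

    rows = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            w = float(row["weight"])
        except ValueError:
            raise ParseError(
                f"line {line}: malformed weight {row['weight']!r}") from None
        if w < 0:
            raise ParseError(f"line {line}: negative weight {w}")
        conds = _parse_conditions(row["conditions"], line)
        rows.append((str(row["source"]), str(row["target"]), w, conds, line))

    C = num_conditions or max((max(r[3]) for r in rows), default=1)
    g = ConditionGraph(num_conditions=C, directed=directed)
    seen: Dict[Tuple, Tuple[float, frozenset, int]] = {}
    for (u, v, w, conds, line) in rows:
        key = g.canonical(u, v)
        if key in seen:
            w0, conds0, line0 = seen[key]
            if abs(w0 - w) > 1e-12:
                raise ParseError(
                    f"line {line}: weight {w} conflicts with weight {w0} "
                    f"for the same edge on line {line0}")
            seen[key] = (w0, conds0 | conds, line0)
        else:
            seen[key] = (w, conds, line)
    for (u, v), (w, conds, _) in seen.items():
        g.add_edge(u, v, w, conds)
    return g


def write_condition_graph(graph: ConditionGraph, path) -> None:
    rows = [(u, v, graph.weight(u, v),
             ",".join(map(str, sorted(graph.exists_at(u, v)))))
            for (u, v) in sorted(graph.edges, key=repr)]
    pd.DataFrame(rows, columns=GRAPH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_demands(path, graph: Optional[ConditionGraph] = None) -> List[Demand]:
    """Read demands from TSV, validating against a graph when given."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in DEMAND_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s) {missing} in {path}")
    demands = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            c = int(row["condition"])
        except ValueError:
            raise ParseError(
                f"line {line}: malformed condition {row['condition']!r}") from None
        d = Demand(str(row["source"]), str(row["target"]), c)
        if graph is not None:
            if d.source not in graph.vertices or d.target not in graph.vertices:
                raise ParseError(f"line {line}: unknown vertex in demand {d}")
            if not 1 <= c <= graph.num_conditions:
                raise ParseError(f"line {line}: condition {c} out of range")
        demands.append(d)
    return demands


def write_demands(demands: Sequence[Demand], path) -> None:
    rows = [(d.source, d.target, d.condition) for d in demands]
    pd.DataFrame(rows, columns=DEMAND_COLUMNS).to_csv(path, sep="\t", index=False)


def solution_to_dict(sol: Solution, status: str = "optimal") -> dict:
    return {
        "status": status,
        "objective": sol.cost,
        "chosen_edges": sorted([list(map(str, e)) for e in sol.chosen_edges]),
        "witnesses": [
            {"source": str(d.source), "target": str(d.target),
             "condition": d.condition, "path": list(map(str, p))}
            for d, p in sorted(sol.witnesses.items(),
                               key=lambda kv: repr(kv[0]))
        ],
    }


def write_solution(sol: Solution, path, status: str = "optimal") -> None:
    Path(path).write_text(json.dumps(solution_to_dict(sol, status), indent=1))


def read_solution(path, graph: ConditionGraph) -> Solution:
    data = json.loads(Path(path).read_text())
    chosen = frozenset(graph.canonical(u, v) for (u, v) in data["chosen_edges"])
    sol = Solution(chosen_edges=chosen,
                   cost=sum(graph.weight(e) for e in chosen))
    return sol


def write_sif(graph: ConditionGraph, path) -> None:
    """Simple-interaction-format export for network viewers."""
    rel = "pd" if graph.directed else "pp"
    lines = [f"{u}\t{rel}\t{v}" for (u, v) in sorted(graph.edges, key=repr)]
    Path(path).write_text("\n".join(lines) + "\n")


def confidence_to_weight(confidence: Optional[float],
                         policy: str = "min-nonzero",
                         known_confidences: Iterable[float] = ()) -> float:
    """Negative-log weighting of an interaction confidence score.

    ``confidence`` must lie in (0, 1]; a score of 1 gives weight 0.  A
    missing score (``None``) is substituted according to ``policy``:
    ``"min-nonzero"`` uses the smallest nonzero confidence among
    ``known_confidences`` (for sparsely scored databases), ``"max"`` uses
    the maximal confidence (for small, highly curated sources).
    """
    if confidence is None:
        known = [c for c in known_confidences if c > 0]
        if not known:
            raise ValueError("no known confidences to substitute from")
        confidence = min(known) if policy == "min-nonzero" else max(known)
    if not 0 < confidence <= 1:
        raise ValueError(f"confidence {confidence} outside (0, 1]")
    return -math.log(confidence)
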