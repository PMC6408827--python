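"""Flow-based integer linear programming for condition Steiner networks.

The core model targets single-source instances: one binary selection
variable ``d_uv`` per underlying edge and one continuous flow variable
``d_uvc`` per arc/condition pair with the arc alive at ``c``.  ``k_c`` units
of flow leave the source at condition ``c`` (one per demand), conservation
holds at every vertex, and the linking constraint ``d_uvc <= k_c * d_uv``
forces any flow-carrying edge into the paid solution.  Flows may stay
fractional: a feasible fractional flow in the selected subgraph certifies
the demanded paths exist, so only the selection variables need integrality —
this keeps the branch-and-bound tree small.

Undirected edges are bidirected internally, with a single binary gating both
anti-parallel arcs so two-way use is paid for once.  General multi-source
instances are routed through the reduction to the common-source/common-sink
form first (:func:`csnet.reductions.csn_to_csp`).

The MILP backend is HiGHS via :func:`scipy.optimize.milp`, which is
deterministic and single-threaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .model import (
    ConditionGraph,
    ConditionGraphError,
    CSNInstance,
    Demand,
    Solution,
    frame,
    satisfies,
)
from .oracle import InfeasibleInstanceError
from .reductions import csn_to_csp
from .variants import to_edge_variant

import networkx as nx

FLOW_TOL = 1e-6


@dataclass
class ILPModel:
    """Assembled variables, constraints, and objective of the flow program.

    ``binary_vars`` maps each underlying edge to its column; ``flow_vars``
    maps ``(arc, condition)`` pairs to columns.  ``demand_rhs`` holds the
    flow-balance right-hand side ``δ_vc`` (positive for targets, ``-k_c`` at
    the source) and ``flow_amount`` the per-condition demand count ``k_c``.
    """
    instance: CSNInstance
    binary_vars: Dict[Tuple, int]
    flow_vars: Dict[Tuple, int]
    objective: np.ndarray
    constraints: List[LinearConstraint]
    integrality: np.ndarray
    bounds: Bounds
    demand_rhs: Dict[Tuple, float]
    flow_amount: Dict[int, int]

    @property
    def num_variables(self) -> int:
        return self.objective.size


def build_flow_program(instance: CSNInstance) -> ILPModel:
    """Assemble the single-source flow program for an edge-variant instance.

    Demands sharing a target and condition aggregate into ``δ_vc >= 2``
    rather than erroring.  Conditions without demands contribute no flow
    variables (their flow is identically zero).
    """
    if instance.variant != "edge":
        raise ConditionGraphError("build_flow_program expects the edge variant")
    if not instance.is_single_source():
        raise ConditionGraphError(
            "multiple sources; use solve_csn, which reduces to a "
            "common-source instance first")
    g = instance.graph
    source = instance.root

    k_c: Dict[int, int] = {}
    delta: Dict[Tuple, float] = {}
    for d in instance.demands:
        k_c[d.condition] = k_c.get(d.condition, 0) + 1
        delta[(d.target, d.condition)] = delta.get((d.target, d.condition), 0.0) + 1.0
    for c, k in k_c.items():
        delta[(source, c)] = -float(k)

    edge_list = sorted(g.edges, key=repr)
    binary_vars = {e: i for i, e in enumerate(edge_list)}
    ncols = len(edge_list)

    # Arcs: the edge itself if directed, both orientations otherwise.
    arcs_of_edge: Dict[Tuple, List[Tuple]] = {}
    for e in edge_list:
        u, v = e
        arcs_of_edge[e] = [(u, v)] if g.directed else [(u, v), (v, u)]

    flow_vars: Dict[Tuple, int] = {}
    for e in edge_list:
        for c in sorted(g.exists_at(e)):
            if c not in k_c:
                continue
            for arc in arcs_of_edge[e]:
                flow_vars[(arc, c)] = ncols
                ncols += 1

    objective = np.zeros(ncols)
    for e, col in binary_vars.items():
        objective[col] = g.weight(e)

    lb = np.zeros(ncols)
    ub = np.empty(ncols)
    integrality = np.zeros(ncols)
    for e, col in binary_vars.items():
        ub[col] = 1.0
        integrality[col] = 1
    for (arc, c), col in flow_vars.items():
        ub[col] = float(k_c[c])

    rows: List[int] = []
    cols: List[int] = []
    vals: List[float] = []
    con_lb: List[float] = []
    con_ub: List[float] = []
    nrow = 0

    # Linking: d_uvc - k_c * d_uv <= 0 for each flow variable.
    for e in edge_list:
        ecol = binary_vars[e]
        for c in sorted(g.exists_at(e)):
            if c not in k_c:
                continue
            for arc in arcs_of_edge[e]:
                fcol = flow_vars[(arc, c)]
                rows += [nrow, nrow]
                cols += [fcol, ecol]
                vals += [1.0, -float(k_c[c])]
                con_lb.append(-np.inf)
                con_ub.append(0.0)
                nrow += 1

    # Conservation: inflow - outflow = delta at every vertex and condition.
    vert_list = sorted(g.vertices, key=repr)
    row_of: Dict[Tuple, int] = {}
    for c in sorted(k_c):
        for v in vert_list:
            row_of[(v, c)] = nrow
            rhs = delta.get((v, c), 0.0)
            con_lb.append(rhs)
            con_ub.append(rhs)
            nrow += 1
    for ((u, v), c), fcol in flow_vars.items():
        rows.append(row_of[(v, c)])
        cols.append(fcol)
        vals.append(1.0)
        rows.append(row_of[(u, c)])
        cols.append(fcol)
        vals.append(-1.0)

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(nrow, ncols))
    constraint = LinearConstraint(A, np.array(con_lb), np.array(con_ub))

    return ILPModel(
        instance=instance,
        binary_vars=binary_vars,
        flow_vars=flow_vars,
        objective=objective,
        constraints=[constraint],
        integrality=integrality,
        bounds=Bounds(lb, ub),
        demand_rhs=delta,
        flow_amount=k_c,
    )


_STATUS = {0: "optimal", 1: "timeout", 2: "infeasible", 3: "unbounded"}


def solve_model(model: ILPModel, backend: str = "highs",
                time_limit: float = 600.0) -> Tuple[Optional[Solution], str]:
    """Solve an assembled flow program; returns ``(solution, status)``.

    Status is one of ``optimal``, ``feasible`` (incumbent found at the time
    limit), ``timeout``, or ``infeasible``.  Chosen edges carrying zero flow
    at every condition are pruned before costing.
    """
    if backend != "highs":
        raise ConditionGraphError(
            f"unknown MILP backend {backend!r}; available: 'highs'")
    res = milp(
        c=model.objective,
        constraints=model.constraints,
        integrality=model.integrality,
        bounds=model.bounds,
        options={"time_limit": float(time_limit)},
    )
    status = _STATUS.get(res.status, "error")
    if status == "timeout" and res.x is not None:
        status = "feasible"
    if res.x is None:
        return None, status

    g = model.instance.graph
    x = res.x
    flow_through: Dict[Tuple, float] = {e: 0.0 for e in model.binary_vars}
    for ((u, v), c), col in model.flow_vars.items():
        e = g.canonical(u, v)
        flow_through[e] += abs(x[col])
    kept = frozenset(
        e for e, col in model.binary_vars.items()
        if x[col] > 0.5 and flow_through[e] > FLOW_TOL)
    sol = Solution(chosen_edges=kept, cost=sum(g.weight(e) for e in kept))
    for d in model.instance.demands:
        satisfies(sol, d, g)
    return sol, status


def solve_csn(instance: CSNInstance, backend: str = "highs",
              time_limit: float = 600.0) -> Solution:
    """Solve any condition Steiner instance to proven optimality.

    Pipeline: normalize to the edge variant, check each demand is
    individually satisfiable (naming the first that is not), reduce to a
    common-source instance when demands have several sources, build and
    solve the flow program, then lift the optimum back through every
    transformation.  The returned solution carries witness paths for all
    original demands.
    """
    handle = to_edge_variant(instance)
    inst = handle.instance
    g = inst.graph

    for d in inst.demands:
        fg = frame(g, d.condition)
        ok = (nx.has_path(fg, d.source, d.target)
              if d.source in fg and d.target in fg else False)
        if not ok:
            raise InfeasibleInstanceError(
                f"demand {d} cannot be satisfied by any subgraph", demand=d)

    if inst.is_single_source():
        chain = [handle.lift]
        work = inst
    else:
        red = csn_to_csp(inst)
        chain = [handle.lift, red.lift]
        work = red.instance

    model = build_flow_program(work)
    sol, status = solve_model(model, backend=backend, time_limit=time_limit)
    if status == "infeasible" or sol is None:
        raise InfeasibleInstanceError(
            f"MILP reported status {status!r} despite per-demand reachability")
    for lift in reversed(chain):
        sol = lift(sol)
    sol.status = status
    return sol
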