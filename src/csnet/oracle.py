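"""Exact ground-truth solvers for small instances.

These enumerate candidate edge sets in nondecreasing total weight (a lazy
best-first expansion of the subset lattice), so the first feasible set popped
is provably optimal.  They are deliberately refused on large inputs — the
point is an independent oracle for validating the ILP, the approximation
algorithms, and the cost preservation of every reduction, never a production
solver.
"""

from __future__ import annotations

import heapq
import itertools
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .model import (
    INF,
    ConditionGraph,
    ConditionGraphError,
    CSNInstance,
    CSTInstance,
    CPCSTInstance,
    Demand,
    PrioritySteinerInstance,
    PrioritySolution,
    Solution,
    Vertex,
)
from .variants import to_edge_variant


class OracleSizeError(ValueError):
    """The instance exceeds the enumeration budget; refusal, not approximation."""


class InfeasibleInstanceError(ValueError):
    """No subgraph satisfies the demands; carries the first failing demand."""

    def __init__(self, message: str, demand: Optional[Demand] = None):
        super().__init__(message)
        self.demand = demand


def _adjacency(edges: Sequence[Tuple[Vertex, Vertex]],
               directed: bool) -> Dict[Vertex, List[Tuple[Vertex, int]]]:
    adj: Dict[Vertex, List[Tuple[Vertex, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        if not directed:
            adj.setdefault(v, []).append((u, idx))
    return adj


def _reaches(adj, allowed: Set[int], a: Vertex, b: Vertex) -> bool:
    if a == b:
        return True
    seen = {a}
    stack = [a]
    while stack:
        x = stack.pop()
        for (y, idx) in adj.get(x, ()):
            if idx in allowed and y not in seen:
                if y == b:
                    return True
                seen.add(y)
                stack.append(y)
    return False


def _reachable_set(adj, allowed: Set[int], a: Vertex) -> Set[Vertex]:
    seen = {a}
    stack = [a]
    while stack:
        x = stack.pop()
        for (y, idx) in adj.get(x, ()):
            if idx in allowed and y not in seen:
                seen.add(y)
                stack.append(y)
    return seen


def _cheapest_subsets(weights: Sequence[float]):
    """Yield index subsets of ``weights`` in nondecreasing total weight.

    Weights must be sorted ascending.  Classic lazy enumeration: each subset
    is generated once, children of ``(.., j)`` are append-``j+1`` and
    replace-last-by-``j+1``.
    """
    n = len(weights)
    heap: List[Tuple[float, Tuple[int, ...]]] = [(0.0, ())]
    while heap:
        w, subset = heapq.heappop(heap)
        yield w, subset
        if not subset:
            if n:
                heapq.heappush(heap, (weights[0], (0,)))
            continue
        j = subset[-1]
        if j + 1 < n:
            heapq.heappush(heap, (w + weights[j + 1], subset + (j + 1,)))
            heapq.heappush(heap,
                           (w - weights[j] + weights[j + 1],
                            subset[:-1] + (j + 1,)))


def _relevant_edges(graph: ConditionGraph,
                    demands: Sequence[Demand]) -> List[Tuple[Vertex, Vertex]]:
    """Edges that can lie on a witness path of at least one demand."""
    all_edges = sorted(graph.edges, key=lambda e: (graph.weight(e), repr(e)))
    keep = set()
    for d in demands:
        cond_edges = [e for e in all_edges if d.condition in graph.exists_at(e)]
        adj = _adjacency(cond_edges, graph.directed)
        allowed = set(range(len(cond_edges)))
        fwd = _reachable_set(adj, allowed, d.source)
        if graph.directed:
            radj = _adjacency([(v, u) for (u, v) in cond_edges], True)
            bwd = _reachable_set(radj, allowed, d.target)
            for (u, v) in cond_edges:
                if u in fwd and v in bwd:
                    keep.add((u, v))
        else:
            if d.target in fwd:
                for (u, v) in cond_edges:
                    if u in fwd and v in fwd:
                        keep.add((u, v))
    return [e for e in all_edges if e in keep]


def brute_force_opt(instance: CSNInstance, edge_budget: int = 20) -> Solution:
    """Provably optimal solution of a small condition Steiner instance.

    Any variant and orientation is accepted (non-edge variants are converted
    and the optimum lifted back, preserving cost exactly).  Enumeration is
    restricted to edges on at least one demand-relevant path, which does not
    affect exactness.  Raises :class:`OracleSizeError` beyond ``edge_budget``
    relevant edges and :class:`InfeasibleInstanceError` when some demand is
    unsatisfiable.
    """
    handle = to_edge_variant(instance)
    inst = handle.instance
    g = inst.graph

    edges = _relevant_edges(g, inst.demands)
    # Zero-weight edges never hurt, so they ride along for free; only the
    # positively weighted edges are enumerated.
    zero = [i for i, e in enumerate(edges) if g.weight(e) <= 0.0]
    pos = [i for i, e in enumerate(edges) if g.weight(e) > 0.0]
    if len(pos) > edge_budget:
        raise OracleSizeError(
            f"{len(pos)} weighted relevant edges exceed the budget of "
            f"{edge_budget}")

    # Per-demand adjacency over the relevant edge list.
    per_demand = []
    for d in inst.demands:
        idxs = {i for i, e in enumerate(edges) if d.condition in g.exists_at(e)}
        per_demand.append((d, idxs))
    adj = _adjacency(edges, g.directed)

    full = set(range(len(edges)))
    for d, idxs in per_demand:
        if not _reaches(adj, full & idxs, d.source, d.target):
            raise InfeasibleInstanceError(
                f"demand {d} cannot be satisfied by any subgraph", demand=d)

    from .model import satisfies
    weights = [g.weight(edges[i]) for i in pos]
    base = set(zero)
    for w, subset in _cheapest_subsets(weights):
        chosen = base | {pos[i] for i in subset}
        if all(_reaches(adj, chosen & idxs, d.source, d.target)
               for d, idxs in per_demand):
            sol = Solution(
                chosen_edges=frozenset(g.canonical(*edges[i]) for i in chosen),
                cost=w + 0.0)
            # Tidy up: keep only the edges the witness paths actually use.
            used = set()
            for d in inst.demands:
                assert satisfies(sol, d, g)
                path = sol.witnesses[d]
                used.update(g.canonical(a, b) for a, b in zip(path, path[1:]))
            tidy = Solution(chosen_edges=frozenset(used),
                            cost=sum(g.weight(e) for e in used),
                            witnesses=dict(sol.witnesses))
            assert abs(tidy.cost - w) <= 1e-9
            return handle.lift(tidy)
    raise InfeasibleInstanceError("exhausted subsets without a feasible one")


# ---------------------------------------------------------------------------
# Tree-shaped objectives
# ---------------------------------------------------------------------------

def _mutually_reachable(adj, allowed: Set[int], X: FrozenSet[Vertex]) -> bool:
    it = iter(X)
    a = next(it)
    reach = _reachable_set(adj, allowed, a)
    return all(x in reach for x in it)


def brute_force_tree_opt(instance) -> Solution:
    """Exact minimizer for condition Steiner tree / prize-collecting tree.

    For CST the search runs over arbitrary edge subsets in nondecreasing
    weight — the optimum need not be a tree, since per-condition paths
    between the same terminals can close cycles.  For CPCST the objective
    itself is over subtrees, so candidate edge sets are restricted to trees
    (including single-vertex and empty ones) and scored as edge weight plus
    the penalties of omitted vertex/condition pairs.
    """
    if isinstance(instance, CSTInstance):
        return _cst_opt(instance)
    if isinstance(instance, CPCSTInstance):
        return _cpcst_opt(instance)
    raise TypeError(f"unsupported instance type {type(instance).__name__}")


def _cst_opt(instance: CSTInstance) -> Solution:
    g = instance.graph
    edges = sorted(g.edges, key=lambda e: (g.weight(e), repr(e)))
    zero = [i for i, e in enumerate(edges) if g.weight(e) <= 0.0]
    pos = [i for i, e in enumerate(edges) if g.weight(e) > 0.0]
    if len(pos) > 20:
        raise OracleSizeError("instance too large for exhaustive search")
    adj = _adjacency(edges, directed=False)
    full = set(range(len(edges)))
    per_cond = []
    for c, X in enumerate(instance.terminal_sets, start=1):
        idxs = {i for i, e in enumerate(edges) if c in g.exists_at(e)}
        if not _mutually_reachable(adj, full & idxs, X):
            raise InfeasibleInstanceError(
                f"terminal set {sorted(map(repr, X))} disconnected at condition {c}")
        per_cond.append((X, idxs))
    weights = [g.weight(edges[i]) for i in pos]
    base = set(zero)
    for w, subset in _cheapest_subsets(weights):
        chosen = base | {pos[i] for i in subset}
        if all(_mutually_reachable(adj, chosen & idxs, X)
               for X, idxs in per_cond):
            return Solution(
                chosen_edges=frozenset(g.canonical(*edges[i]) for i in chosen),
                cost=w)
    raise InfeasibleInstanceError("exhausted subsets without a feasible one")


def _is_tree(edges: Sequence[Tuple[Vertex, Vertex]]) -> bool:
    """Connected and acyclic (empty edge sets count as trees)."""
    if not edges:
        return True
    parent: Dict[Vertex, Vertex] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    verts = set()
    for (u, v) in edges:
        verts.update((u, v))
    for v in verts:
        parent[v] = v
    comps = len(verts)
    for (u, v) in edges:
        ru, rv = find(u), find(v)
        if ru == rv:
            return False
        parent[ru] = rv
        comps -= 1
    return comps == 1


def _cpcst_opt(instance: CPCSTInstance) -> Solution:
    g = instance.graph
    if len(g.vertices) > 8 or len(g.edges) > 16:
        raise OracleSizeError("instance too large for exhaustive search")
    edges = sorted(g.edges, key=lambda e: (g.weight(e), repr(e)))
    C = g.num_conditions

    def omitted_penalty(tree_vertices: Set[Vertex]) -> float:
        total = 0.0
        for (v, c), p in instance.penalty.items():
            if v not in tree_vertices:
                if p == INF:
                    return INF
                total += p
        return total

    best: Optional[Tuple[float, Tuple[int, ...], FrozenSet[Vertex]]] = None

    # Vertexless and single-vertex trees.
    for tv in [frozenset()] + [frozenset({v}) for v in sorted(g.vertices, key=repr)]:
        score = omitted_penalty(set(tv))
        if score < INF and (best is None or score < best[0]):
            best = (score, (), tv)

    n = len(edges)
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            sub = [edges[i] for i in subset]
            if not _is_tree(sub):
                continue
            tv = set()
            for (u, v) in sub:
                tv.update((u, v))
            score = sum(g.weight(e) for e in sub) + omitted_penalty(tv)
            if score < INF and (best is None or score < best[0]):
                best = (score, subset, frozenset(tv))

    if best is None:
        raise InfeasibleInstanceError(
            "every subtree omits an infinitely penalized vertex")
    score, subset, _ = best
    return Solution(
        chosen_edges=frozenset(g.canonical(*edges[i]) for i in subset),
        cost=score)


# ---------------------------------------------------------------------------
# Priority Steiner Tree
# ---------------------------------------------------------------------------

def brute_force_priority_opt(instance: PrioritySteinerInstance,
                             edge_budget: int = 20) -> PrioritySolution:
    """Exact priority-Steiner optimum by cheapest-first subset enumeration."""
    edges = list(instance.edges)
    order = sorted(range(len(edges)), key=lambda j: (edges[j][2], j))
    pairs = [(edges[j][0], edges[j][1]) for j in order]
    prios = [edges[j][3] for j in order]
    adj = _adjacency(pairs, directed=False)
    zero = [i for i in range(len(order)) if edges[order[i]][2] <= 0.0]
    pos = [i for i in range(len(order)) if edges[order[i]][2] > 0.0]
    if len(pos) > edge_budget:
        raise OracleSizeError(
            f"{len(pos)} weighted multiedges exceed the budget of {edge_budget}")

    per_demand = []
    full = set(range(len(order)))
    for (a, b, p) in instance.demands:
        idxs = {i for i in range(len(order)) if prios[i] <= p}
        if not _reaches(adj, full & idxs, a, b):
            raise InfeasibleInstanceError(
                f"demand ({a!r}, {b!r}) unroutable at priority {p}")
        per_demand.append(((a, b), idxs))

    weights = [edges[order[i]][2] for i in pos]
    base = set(zero)
    for w, subset in _cheapest_subsets(weights):
        chosen = base | {pos[i] for i in subset}
        if all(_reaches(adj, chosen & idxs, a, b)
               for (a, b), idxs in per_demand):
            return PrioritySolution(
                chosen_edges=frozenset(order[i] for i in chosen), cost=w)
    raise InfeasibleInstanceError("exhausted subsets without a feasible one")
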