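"""Approximation algorithms for condition Steiner networks.

Two algorithms live here.  The *union of shortest paths* routes every demand
independently and takes the union — a k-approximation, and the best ratio
achievable in terms of k alone for the general problem.  For monotonic
single-source directed instances, a *recursive greedy* over the per-condition
metric closure (the classic density-driven directed-Steiner-tree recursion,
run on vertex/condition pairs instead of plain vertices) achieves an
``i²(i−1)·k^(1/i)`` guarantee at recursion depth ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import networkx as nx

from .model import (
    ConditionGraph,
    ConditionGraphError,
    CSNInstance,
    Demand,
    Solution,
    Vertex,
    frame,
    is_monotonic,
    satisfies,
)
from .oracle import InfeasibleInstanceError


def _vkey(v):
    """Deterministic sort key valid across the vertex types we produce."""
    if isinstance(v, bool):
        return (2, repr(v))
    if isinstance(v, int):
        return (0, v)
    if isinstance(v, tuple):
        return (1, tuple(_vkey(x) for x in v))
    return (2, repr(v))


# ---------------------------------------------------------------------------
# Metric closure
# ---------------------------------------------------------------------------

class MetricClosure:
    """Per-condition all-pairs shortest distances ``w̃(u, v, c)``.

    Unreachable pairs have infinite distance.  ``recover_path`` rebuilds one
    concrete shortest path per triple, deterministically (ties broken toward
    the lexicographically smallest predecessor).
    """

    def __init__(self, graph: ConditionGraph):
        self.graph = graph
        self._dist: Dict[int, Dict[Vertex, Dict[Vertex, float]]] = {}
        self._frames = {}
        self._parents: Dict[Tuple[Vertex, int], Dict[Vertex, Vertex]] = {}
        for c in range(1, graph.num_conditions + 1):
            fg = frame(graph, c)
            self._frames[c] = fg
            self._dist[c] = {
                u: nx.single_source_dijkstra_path_length(fg, u, weight="weight")
                for u in fg.nodes
            }

    def distance(self, u: Vertex, v: Vertex, c: int) -> float:
        if not 1 <= c <= self.graph.num_conditions:
            raise ConditionGraphError(f"condition {c} out of range")
        return self._dist[c].get(u, {}).get(v, float("inf"))

    def _parent_tree(self, u: Vertex, c: int) -> Dict[Vertex, Vertex]:
        """Deterministic shortest-path tree rooted at ``u`` in frame ``c``.

        Dijkstra with a (distance, vertex-key) heap; each vertex's parent is
        picked, at finalization time, as the smallest already-finalized
        neighbor that attains its distance.  Finalization order makes the
        parent pointers acyclic even across zero-weight ties.
        """
        key = (u, c)
        if key in self._parents:
            return self._parents[key]
        import heapq
        fg = self._frames[c]
        pred = fg.pred if fg.is_directed() else fg.adj
        dist: Dict[Vertex, float] = {u: 0.0}
        parent: Dict[Vertex, Vertex] = {}
        done: set = set()
        heap = [(0.0, _vkey(u), u)]
        while heap:
            d, _, x = heapq.heappop(heap)
            if x in done or d > dist.get(x, float("inf")) + 1e-15:
                continue
            if x != u:
                cands = [w for w in pred[x]
                         if w in done
                         and abs(dist[w] + fg[w][x]["weight"] - d) <= 1e-12]
                parent[x] = min(cands, key=_vkey)
            done.add(x)
            for y in fg.succ[x] if fg.is_directed() else fg.adj[x]:
                nd = d + fg[x][y]["weight"]
                if nd < dist.get(y, float("inf")) - 1e-15:
                    dist[y] = nd
                    heapq.heappush(heap, (nd, _vkey(y), y))
        self._parents[key] = parent
        return parent

    def recover_path(self, u: Vertex, v: Vertex, c: int) -> Tuple[Vertex, ...]:
        """One shortest u→v path in G_c; raises if unreachable."""
        if self.distance(u, v, c) == float("inf"):
            raise ConditionGraphError(
                f"{v!r} unreachable from {u!r} at condition {c}")
        parent = self._parent_tree(u, c)
        path = [v]
        while path[-1] != u:
            path.append(parent[path[-1]])
        path.reverse()
        return tuple(path)


def metric_closure(graph: ConditionGraph) -> MetricClosure:
    """All-pairs, per-condition shortest-path table with path recovery."""
    return MetricClosure(graph)


# ---------------------------------------------------------------------------
# Union of shortest paths
# ---------------------------------------------------------------------------

def shortest_path_union(instance: CSNInstance) -> Solution:
    """One shortest path per demand, deduplicated into a single subgraph.

    Feasible whenever every demand is individually satisfiable; the cost is
    at most ``k`` times the optimum (and can approach that bound).
    """
    if instance.variant != "edge":
        raise ConditionGraphError("expects an edge-variant instance")
    g = instance.graph
    closure = metric_closure(g)
    chosen = set()
    witnesses = {}
    for d in instance.demands:
        if closure.distance(d.source, d.target, d.condition) == float("inf"):
            raise InfeasibleInstanceError(
                f"demand {d} cannot be satisfied by any subgraph", demand=d)
        path = closure.recover_path(d.source, d.target, d.condition)
        witnesses[d] = path
        for a, b in zip(path, path[1:]):
            chosen.add(g.canonical(a, b))
    return Solution(chosen_edges=frozenset(chosen),
                    cost=sum(g.weight(e) for e in chosen),
                    witnesses=witnesses)


# ---------------------------------------------------------------------------
# Recursive greedy on the closure (modified Charikar recursion)
# ---------------------------------------------------------------------------

@dataclass
class ClosureTree:
    """An out-tree in closure space.

    Nodes are ``(vertex, condition)`` states; conditions never decrease along
    root-to-leaf paths, and each arc is priced at the closure distance at the
    head's condition.  ``covered`` is the set of ``(target, condition)``
    demands the tree satisfies; ``density`` is cost per covered demand.
    """
    root: Tuple[Vertex, int]
    arcs: Tuple[Tuple[Tuple[Vertex, int], Tuple[Vertex, int], float], ...]
    cost: float
    covered: FrozenSet[Tuple[Vertex, int]]

    @property
    def density(self) -> float:
        return self.cost / len(self.covered) if self.covered else float("inf")


def _closure_tree_candidates(graph: ConditionGraph):
    states = []
    for v in sorted(graph.vertices, key=_vkey):
        for c in range(1, graph.num_conditions + 1):
            states.append((v, c))
    return states


def charikar_closure_tree(instance: CSNInstance, level: int = 2,
                          closure: Optional[MetricClosure] = None) -> ClosureTree:
    """Run the density-greedy recursion; return the tree in closure space.

    ``level`` is the recursion depth ``i``: depth 1 connects the root
    directly to the nearest uncovered targets; depth ``i`` repeatedly picks,
    over all intermediate states ``(x, c_x)`` and subtree sizes ``k'``, the
    depth-``(i-1)`` subtree (plus entry arc) of minimum density.  For
    ``i >= 2`` the tree cost is within ``i²(i−1)·k^(1/i)`` of the optimum.
    """
    if level < 1:
        raise ConditionGraphError("recursion level must be >= 1")
    g = instance.graph
    if not g.directed:
        raise ConditionGraphError("expects a directed instance")
    if instance.variant != "edge":
        raise ConditionGraphError("expects an edge-variant instance")
    if not instance.is_single_source():
        raise ConditionGraphError("expects a single-source instance")
    if not is_monotonic(g):
        raise ConditionGraphError("instance is not monotonic")

    root_vertex = instance.root
    demands = sorted({(d.target, d.condition) for d in instance.demands},
                     key=lambda t: (_vkey(t[0]), t[1]))
    wt = closure if closure is not None else metric_closure(g)
    for (b, c) in demands:
        if wt.distance(root_vertex, b, c) == float("inf"):
            raise InfeasibleInstanceError(
                f"demand {(root_vertex, b, c)} cannot be satisfied",
                demand=Demand(root_vertex, b, c))

    states = _closure_tree_candidates(g)
    memo: Dict = {}

    def best_subtree(i: int, root: Tuple[Vertex, int], k: int,
                     uncovered: FrozenSet[Tuple[Vertex, int]]) -> Optional[ClosureTree]:
        """Cheapest-density depth-i tree at ``root`` covering >= k demands."""
        key = (i, root, k, uncovered)
        if key in memo:
            return memo[key]
        v, c = root
        result: Optional[ClosureTree] = None
        if i == 1:
            cands = []
            for (b, cb) in uncovered:
                if cb >= c:
                    dist = wt.distance(v, b, cb)
                    if dist < float("inf"):
                        cands.append((dist, _vkey(b), cb, (b, cb)))
            if len(cands) >= k:
                cands.sort()
                take = cands[:k]
                arcs = tuple((root, t, dist) for (dist, _, _, t) in take)
                result = ClosureTree(
                    root=root, arcs=arcs,
                    cost=sum(dist for (dist, _, _, _) in take),
                    covered=frozenset(t for (_, _, _, t) in take))
        else:
            arcs: List = []
            cost = 0.0
            covered: set = set()
            rem = k
            left = set(uncovered)
            feasible = True
            while rem > 0:
                best = None  # (density, cost, xkey, cx, entry, subtree)
                for (x, cx) in states:
                    if cx < c:
                        continue
                    entry = wt.distance(v, x, cx)
                    if entry == float("inf"):
                        continue
                    for kp in range(1, rem + 1):
                        sub = best_subtree(i - 1, (x, cx), kp, frozenset(left))
                        if sub is None:
                            break
                        total = entry + sub.cost
                        dens = total / len(sub.covered)
                        cand = (dens, total, _vkey(x), cx, entry, sub)
                        if best is None or cand[:4] < best[:4]:
                            best = cand
                if best is None:
                    feasible = False
                    break
                _, total, _, _, entry, sub = best
                if sub.root != root:
                    arcs.append((root, sub.root, entry))
                arcs.extend(sub.arcs)
                cost += total
                covered |= sub.covered
                left -= sub.covered
                rem = k - len(covered)
            if feasible:
                result = ClosureTree(root=root, arcs=tuple(arcs), cost=cost,
                                     covered=frozenset(covered))
        memo[key] = result
        return result

    top = best_subtree(level, (root_vertex, 1), len(demands),
                       frozenset(demands))
    if top is None:  # pragma: no cover - prechecked above
        raise InfeasibleInstanceError("recursion failed to cover all demands")
    return top


def expand_closure_tree(tree: ClosureTree, closure: MetricClosure,
                        graph: ConditionGraph) -> Solution:
    """Replace every closure arc by a recovered shortest path and take the union.

    Each underlying edge is counted once, so the expanded cost never exceeds
    the closure-tree cost.
    """
    chosen = set()
    for ((u, cu), (v, cv), price) in tree.arcs:
        if price == float("inf"):
            raise ConditionGraphError("closure tree contains an infinite arc")
        if u == v:
            continue
        path = closure.recover_path(u, v, cv)
        for a, b in zip(path, path[1:]):
            chosen.add(graph.canonical(a, b))
    return Solution(chosen_edges=frozenset(chosen),
                    cost=sum(graph.weight(e) for e in chosen))


def charikar_tree(instance: CSNInstance, level: int = 2) -> Solution:
    """Recursive-greedy solution for monotonic single-source directed instances.

    Builds the closure tree at the requested recursion depth, expands its
    arcs into concrete shortest paths, and records witness paths for every
    demand.  The solution cost is bounded by the closure-tree cost, hence by
    ``i²(i−1)·k^(1/i)`` times the optimum for ``level = i >= 2``.
    """
    closure = metric_closure(instance.graph)
    tree = charikar_closure_tree(instance, level=level, closure=closure)
    sol = expand_closure_tree(tree, closure, instance.graph)
    for d in instance.demands:
        if not satisfies(sol, d, instance.graph):  # pragma: no cover
            raise ConditionGraphError(f"expanded tree misses demand {d}")
    return sol
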