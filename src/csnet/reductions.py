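"""Inter-problem reductions with solution lifting.

Every reduction here is *strict*: the optimal objective value of the produced
instance equals that of the source instance (up to zero-weight bookkeeping
edges), and each returned :class:`ReductionResult` carries a ``lift``
procedure mapping any feasible solution of the produced instance back to a
feasible solution of the source instance of equal (or smaller) cost.

The chain CSN → CSP → CST → CPCST lets a single-source flow solver handle
arbitrary demand sets; the monotonic reductions connect the condition
problems to priority Steiner tree and directed Steiner tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Tuple

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
    is_monotonic,
    satisfies,
    solution_cost,
)


@dataclass
class ReductionResult:
    """A produced instance together with a solution-lifting procedure."""
    instance: object
    lift: Callable[[object], object]


def _fresh_name(base: str, taken) -> str:
    name = base
    while name in taken:
        name = name + "_"
    return name


def _with_witnesses(sol: Solution, instance: CSNInstance) -> Solution:
    for d in instance.demands:
        satisfies(sol, d, instance.graph)
    return sol


# ---------------------------------------------------------------------------
# CSN -> CSP  (one condition per demand, a global source/sink pair)
# ---------------------------------------------------------------------------

def csn_to_csp(instance: CSNInstance) -> ReductionResult:
    """Collapse k arbitrary demands into k single-pair demands.

    The produced instance has one condition per source demand ``i``; original
    edges keep their membership (``e`` exists at new condition ``i`` iff it
    existed at the demand's condition ``c_i``), and four zero-weight gadget
    edges thread the global source/sink through the demand's endpoints at
    condition ``i`` only.  Works for directed and undirected inputs alike.
    """
    if instance.variant != "edge":
        raise ConditionGraphError("csn_to_csp expects an edge-variant instance")
    g = instance.graph
    k = instance.num_demands
    if k == 0:
        raise ConditionGraphError("instance has no demands")

    taken = set(map(repr, g.vertices))
    src = _fresh_name("SRC", taken)
    snk = _fresh_name("SNK", taken)

    new = ConditionGraph(num_conditions=k, directed=g.directed)
    for v in g.vertices:
        new.add_vertex(v)
    original_edges = set()
    for e in g.edges:
        conds = {i for i, d in enumerate(instance.demands, start=1)
                 if d.condition in g.exists_at(e)}
        if conds:
            new.add_edge(e[0], e[1], g.weight(e), conds)
            original_edges.add(new.canonical(*e))
    for i, d in enumerate(instance.demands, start=1):
        xi = _fresh_name(f"x{i}", taken)
        yi = _fresh_name(f"y{i}", taken)
        new.add_edge(src, xi, 0.0, {i})
        new.add_edge(xi, d.source, 0.0, {i})
        new.add_edge(d.target, yi, 0.0, {i})
        new.add_edge(yi, snk, 0.0, {i})

    produced = CSNInstance(
        graph=new,
        demands=[Demand(src, snk, i) for i in range(1, k + 1)],
        variant="edge",
    )

    def lift(sol: Solution) -> Solution:
        kept = frozenset(e for e in sol.chosen_edges if e in original_edges)
        out = Solution(chosen_edges=kept,
                       cost=sum(g.weight(e) for e in kept))
        return _with_witnesses(out, instance)

    return ReductionResult(instance=produced, lift=lift)


# ---------------------------------------------------------------------------
# CSP -> CST  (terminal pair per condition)
# ---------------------------------------------------------------------------

def csp_to_cst(instance: CSNInstance) -> ReductionResult:
    """Re-read a common-endpoint instance as condition Steiner tree.

    Every demand must share one source ``a`` and one target ``b``; the
    terminal set at each demanded condition becomes ``{a, b}`` (conditions
    without a demand get the trivially satisfied singleton ``{a}``).
    """
    if instance.graph.directed:
        raise ConditionGraphError("condition Steiner tree is undirected")
    pairs = {(d.source, d.target) for d in instance.demands}
    if len(pairs) != 1:
        raise ConditionGraphError("csp_to_cst needs a common source/target pair")
    (a, b) = next(iter(pairs))
    demanded = {d.condition for d in instance.demands}
    terminal_sets = [frozenset({a, b}) if c in demanded else frozenset({a})
                     for c in range(1, instance.graph.num_conditions + 1)]
    produced = CSTInstance(graph=instance.graph, terminal_sets=terminal_sets)

    def lift(sol: Solution) -> Solution:
        out = Solution(chosen_edges=sol.chosen_edges,
                       cost=solution_cost(sol, instance.graph))
        return _with_witnesses(out, instance)

    return ReductionResult(instance=produced, lift=lift)


# ---------------------------------------------------------------------------
# CST -> CPCST  (infinite penalties pin the terminals)
# ---------------------------------------------------------------------------

def cst_to_cpcst(instance: CSTInstance) -> ReductionResult:
    """Encode terminal sets as infinite prize-collecting penalties.

    ``p(v, c) = INF`` for terminals ``v ∈ X_c`` and 0 elsewhere, so any
    finite-cost tree must contain every terminal.
    """
    penalty = {}
    for c, X in enumerate(instance.terminal_sets, start=1):
        for v in X:
            penalty[(v, c)] = INF
    produced = CPCSTInstance(graph=instance.graph, penalty=penalty)

    def lift(sol: Solution) -> Solution:
        return Solution(chosen_edges=sol.chosen_edges,
                        cost=solution_cost(sol, instance.graph))

    return ReductionResult(instance=produced, lift=lift)


# ---------------------------------------------------------------------------
# Monotonic CSN <-> Priority Steiner Tree
# ---------------------------------------------------------------------------

def monotonic_csn_to_priority(instance: CSNInstance) -> ReductionResult:
    """Earliest existence condition becomes the edge's priority level."""
    g = instance.graph
    if g.directed:
        raise ConditionGraphError("priority Steiner tree is undirected")
    if instance.variant != "edge":
        raise ConditionGraphError("expects an edge-variant instance")
    if not is_monotonic(g):
        raise ConditionGraphError("instance is not monotonic")
    edge_order = sorted(g.edges, key=repr)
    edges = [(u, v, g.weight(u, v), min(g.exists_at(u, v)))
             for (u, v) in edge_order]
    demands = [(d.source, d.target, d.condition) for d in instance.demands]
    produced = PrioritySteinerInstance(
        vertices=g.vertices, edges=edges, demands=demands)

    def lift(sol: PrioritySolution) -> Solution:
        kept = frozenset(g.canonical(edges[j][0], edges[j][1])
                         for j in sol.chosen_edges)
        out = Solution(chosen_edges=kept,
                       cost=sum(g.weight(e) for e in kept))
        return _with_witnesses(out, instance)

    return ReductionResult(instance=produced, lift=lift)


def priority_to_monotonic_csn(instance: PrioritySteinerInstance) -> ReductionResult:
    """Priorities become conditions; parallel multiedges are split in half.

    An edge of priority ``p`` exists at every condition ``>= p``.  Each
    member of a parallel bundle is replaced by two half-weight edges joined
    at a fresh midpoint node (both halves keep the original priority), so
    the produced condition graph is simple; lifting contracts the splits.
    """
    C = instance.max_priority
    g = ConditionGraph(num_conditions=C, directed=False)
    for v in instance.vertices:
        g.add_vertex(v)

    by_pair = {}
    for j, (u, v, w, p) in enumerate(instance.edges):
        key = tuple(sorted((u, v), key=repr))
        by_pair.setdefault(key, []).append(j)

    split_halves = {}  # multiedge index -> (half1, half2) canonical keys
    plain = {}         # multiedge index -> canonical key
    for key, idxs in by_pair.items():
        if len(idxs) == 1:
            j = idxs[0]
            u, v, w, p = instance.edges[j]
            plain[j] = g.add_edge(u, v, w, range(p, C + 1))
        else:
            for j in idxs:
                u, v, w, p = instance.edges[j]
                mid = ("split", key[0], key[1], j)
                h1 = g.add_edge(u, mid, w / 2.0, range(p, C + 1))
                h2 = g.add_edge(mid, v, w / 2.0, range(p, C + 1))
                split_halves[j] = (h1, h2)

    produced = CSNInstance(
        graph=g,
        demands=[Demand(a, b, p) for (a, b, p) in instance.demands],
        variant="edge",
    )

    def lift(sol: Solution) -> PrioritySolution:
        chosen = set()
        cost = 0.0
        for j, e in plain.items():
            if e in sol.chosen_edges:
                chosen.add(j)
                cost += instance.edges[j][2]
        for j, (h1, h2) in split_halves.items():
            if h1 in sol.chosen_edges and h2 in sol.chosen_edges:
                chosen.add(j)
                cost += instance.edges[j][2]
        return PrioritySolution(chosen_edges=frozenset(chosen), cost=cost)

    return ReductionResult(instance=produced, lift=lift)


# ---------------------------------------------------------------------------
# Monotonic CST -> Monotonic CSN
# ---------------------------------------------------------------------------

def monotonic_cst_to_csn(instance: CSTInstance) -> ReductionResult:
    """Anchor one terminal per condition and demand paths to the rest.

    The anchor is the lexicographically smallest terminal of each set, giving
    ``|X_c| - 1`` demands per condition; a terminal set of size one yields no
    demands at its condition.
    """
    if not is_monotonic(instance.graph):
        raise ConditionGraphError("instance is not monotonic")
    demands = []
    for c, X in enumerate(instance.terminal_sets, start=1):
        anchor = min(X, key=repr)
        for b in sorted(X - {anchor}, key=repr):
            demands.append(Demand(anchor, b, c))
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # singleton terminal sets leave gaps
        produced = CSNInstance(graph=instance.graph, demands=demands,
                               variant="edge")

    def lift(sol: Solution) -> Solution:
        return Solution(chosen_edges=sol.chosen_edges,
                        cost=solution_cost(sol, instance.graph))

    return ReductionResult(instance=produced, lift=lift)


# ---------------------------------------------------------------------------
# Monotonic single-source DCSN -> Directed Steiner Tree (layered graph)
# ---------------------------------------------------------------------------

def monotonic_ssdcsn_to_dst(instance: CSNInstance) -> ReductionResult:
    """Layered time-expansion onto a one-condition directed instance.

    Layer ``i`` copies every vertex; a within-layer arc ``(u^i, v^i)`` of the
    original weight exists for each edge alive at condition ``i``, and free
    vertical arcs ``(v^i, v^{i+1})`` let paths wait for later conditions.
    Each demand ``(a, b, c)`` becomes the tree demand ``(a^1, b^c)``.  The
    produced instance is directed Steiner tree in condition-graph clothing
    (a single condition, single source).
    """
    g = instance.graph
    if not g.directed:
        raise ConditionGraphError("expects a directed instance")
    if instance.variant != "edge":
        raise ConditionGraphError("expects an edge-variant instance")
    if not instance.is_single_source():
        raise ConditionGraphError("expects a single-source instance")
    if not is_monotonic(g):
        raise ConditionGraphError("instance is not monotonic")
    a = instance.root
    ck = max(d.condition for d in instance.demands)

    layered = ConditionGraph(num_conditions=1, directed=True)
    for v in g.vertices:
        for i in range(1, ck + 1):
            layered.add_vertex((v, i))
    for (u, v) in g.edges:
        for i in g.exists_at(u, v):
            if i <= ck:
                layered.add_edge((u, i), (v, i), g.weight(u, v), {1})
    for v in g.vertices:
        for i in range(1, ck):
            layered.add_edge((v, i), (v, i + 1), 0.0, {1})

    produced = CSNInstance(
        graph=layered,
        demands=[Demand((a, 1), (d.target, d.condition), 1)
                 for d in instance.demands],
        variant="edge",
    )

    return ReductionResult(instance=produced,
                           lift=lambda sol: lift_dst_solution(sol, instance))


def lift_dst_solution(tree: Solution, original: CSNInstance) -> Solution:
    """Project a layered-graph tree back to the condition graph.

    Each within-layer arc ``(u^i, v^i)`` contributes the original edge
    ``(u, v)``; vertical waiting arcs vanish.  An underlying edge used in
    several layers is counted once, so the projected cost never exceeds the
    tree cost.  Raises if the projection fails to satisfy the original
    demands (i.e. the input tree was infeasible for the layered instance).
    """
    g = original.graph
    kept = set()
    for ((u, i), (v, j)) in tree.chosen_edges:
        if u != v:
            assert i == j
            kept.add(g.canonical(u, v))
    sol = Solution(chosen_edges=frozenset(kept),
                   cost=sum(g.weight(e) for e in kept))
    for d in original.demands:
        if not satisfies(sol, d, g):
            raise ConditionGraphError(
                f"layered tree does not satisfy demand {d}")
    return sol
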