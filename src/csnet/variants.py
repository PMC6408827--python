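"""Strict equivalences between the edge, node, and node-and-edge formulations.

All solvers in this package operate on the canonical edge formulation; these
transforms convert the other two formulations to it while preserving the
optimal objective exactly, and lift solutions back so callers never see
gadget nodes.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Sequence, Tuple

from .model import (
    ConditionGraph,
    ConditionGraphError,
    CSNInstance,
    Demand,
    Solution,
    Vertex,
    satisfies,
)
from .reductions import ReductionResult


def make_node_instance(node_exists_at: Mapping[Vertex, Iterable[int]],
                       edges: Sequence[Tuple[Vertex, Vertex, float]],
                       demands: Sequence[Demand],
                       num_conditions: int,
                       directed: bool = False) -> CSNInstance:
    """Build a node-variant instance from per-vertex condition sets.

    An edge exists at the intersection of its endpoints' condition sets;
    edges whose intersection is empty are dropped (they can never carry a
    path).
    """
    tau = {v: frozenset(cs) for v, cs in node_exists_at.items()}
    g = ConditionGraph(num_conditions=num_conditions, directed=directed)
    for v in tau:
        g.add_vertex(v)
    for (u, v, w) in edges:
        conds = tau.get(u, frozenset()) & tau.get(v, frozenset())
        if conds:
            g.add_edge(u, v, w, conds)
    return CSNInstance(graph=g, demands=demands, variant="node",
                       node_exists_at=tau)


def node_and_edge_to_node(instance: CSNInstance) -> ReductionResult:
    """Replace each edge by a midpoint node carrying its condition set.

    The edge ``(u, v)`` with condition set ``τ(u,v)`` becomes a node
    ``x_(u,v)`` existing at ``τ(u,v)``, an edge ``(u, x)`` of the original
    weight and an edge ``(x, v)`` of zero weight; the optimum is preserved
    exactly.
    """
    if instance.variant != "node-and-edge":
        raise ConditionGraphError("expects a node-and-edge instance")
    g = instance.graph
    tau = {v: frozenset(cs) for v, cs in instance.node_exists_at.items()}
    for e in g.edges:
        u, v = e
        if not g.exists_at(e) <= (tau.get(u, frozenset()) & tau.get(v, frozenset())):
            raise ConditionGraphError(
                f"edge {e!r} exists at conditions its endpoints do not")

    node_tau: Dict[Vertex, frozenset] = dict(tau)
    new_edges = []
    weighted_half: Dict[Tuple[Vertex, Vertex], Tuple[Vertex, Vertex]] = {}
    for e in sorted(g.edges, key=repr):
        u, v = e
        x = ("x", u, v)
        node_tau[x] = g.exists_at(e)
        new_edges.append((u, x, g.weight(e)))
        new_edges.append((x, v, 0.0))
        weighted_half[(u, x)] = e

    produced = make_node_instance(node_tau, new_edges, instance.demands,
                                  g.num_conditions, directed=g.directed)

    def lift(sol: Solution) -> Solution:
        pg = produced.graph
        kept = set()
        for (u, x), e in weighted_half.items():
            if pg.canonical(u, x) in sol.chosen_edges:
                kept.add(e)
        out = Solution(chosen_edges=frozenset(kept),
                       cost=sum(g.weight(e) for e in kept))
        for d in instance.demands:
            satisfies(out, d, g)
        return out

    return ReductionResult(instance=produced, lift=lift)


def node_to_edge(instance: CSNInstance) -> ReductionResult:
    """Drop the per-vertex condition sets; edges keep the induced ones.

    In a node-variant instance every edge already exists at exactly the
    intersection of its endpoints' condition sets, so the edge-variant
    instance has the same graph with all nodes present at all conditions.
    """
    if instance.variant != "node":
        raise ConditionGraphError("expects a node-variant instance")
    produced = CSNInstance(graph=instance.graph, demands=instance.demands,
                           variant="edge")

    def lift(sol: Solution) -> Solution:
        out = Solution(chosen_edges=sol.chosen_edges, cost=sol.cost)
        for d in instance.demands:
            satisfies(out, d, instance.graph)
        return out

    return ReductionResult(instance=produced, lift=lift)


def to_edge_variant(instance: CSNInstance) -> ReductionResult:
    """Normalize any variant to the edge formulation, composing lifts."""
    if instance.variant == "edge":
        return ReductionResult(instance=instance, lift=lambda sol: sol)
    if instance.variant == "node-and-edge":
        step1 = node_and_edge_to_node(instance)
        step2 = node_to_edge(step1.instance)
        return ReductionResult(instance=step2.instance,
                               lift=lambda sol: step1.lift(step2.lift(sol)))
    return node_to_edge(instance)
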