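"""Core data model for condition Steiner problems.

A *condition graph* is a sequence of graphs ``G_1 .. G_C`` over one shared
vertex set: every underlying edge carries a nonnegative weight and the set of
conditions (1-based indices) at which it is present.  A *demand* ``(a, b, c)``
asks for an ``a``–``b`` path whose edges all exist at condition ``c``; a
solution is a subgraph of the underlying graph, and its cost counts each
underlying edge once no matter how many conditions use it.

Conditions model discrete biological contexts — time points, treatments, cell
states — in which different subsets of a reference interaction network (for
instance a protein–protein interaction database) are believed to be active.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Hashable, Iterable, Mapping, Optional, Sequence, Tuple

import networkx as nx

Vertex = Hashable
Edge = Tuple[Vertex, Vertex]

#: Sentinel for infinite prize-collecting penalties.  Kept as a distinct
#: object (not a large float) so cost arithmetic stays exact.
INF = math.inf


class ConditionGraphError(ValueError):
    """Raised for structurally invalid condition graphs or queries."""


class ConditionGraph:
    """Weighted graph whose edges exist at subsets of conditions ``1..C``.

    Undirected edges are stored canonically (sorted endpoint pair) so that
    weight and condition lookups are order-independent.  Parallel edges are
    disallowed; the priority-Steiner multigraph type is separate.
    """

    def __init__(self, num_conditions: int, directed: bool = False):
        if num_conditions < 1:
            raise ConditionGraphError("need at least one condition")
        self.num_conditions = int(num_conditions)
        self.directed = bool(directed)
        self._vertices: set = set()
        self._weight: Dict[Edge, float] = {}
        self._exists_at: Dict[Edge, FrozenSet[int]] = {}

    # -- construction -----------------------------------------------------

    def add_vertex(self, v: Vertex) -> None:
        self._vertices.add(v)

    def canonical(self, u: Vertex, v: Vertex) -> Edge:
        """Canonical key for the edge ``(u, v)``."""
        if self.directed:
            return (u, v)
        return (u, v) if repr(u) <= repr(v) else (v, u)

    def add_edge(self, u: Vertex, v: Vertex, weight: float,
                 conditions: Iterable[int]) -> Edge:
        if u == v:
            raise ConditionGraphError(f"self-loop at {u!r}")
        if weight < 0:
            raise ConditionGraphError(f"negative weight on ({u!r}, {v!r})")
        conds = frozenset(int(c) for c in conditions)
        if not conds:
            raise ConditionGraphError(f"empty condition set on ({u!r}, {v!r})")
        if not conds <= set(range(1, self.num_conditions + 1)):
            raise ConditionGraphError(
                f"conditions {sorted(conds)} out of range 1..{self.num_conditions}")
        e = self.canonical(u, v)
        if e in self._weight:
            raise ConditionGraphError(f"duplicate edge {e!r}")
        self._vertices.add(u)
        self._vertices.add(v)
        self._weight[e] = float(weight)
        self._exists_at[e] = conds
        return e

    # -- queries -----------------------------------------------------------

    @property
    def vertices(self) -> FrozenSet[Vertex]:
        return frozenset(self._vertices)

    @property
    def edges(self) -> FrozenSet[Edge]:
        return frozenset(self._weight)

    def has_edge(self, u: Vertex, v: Vertex) -> bool:
        return self.canonical(u, v) in self._weight

    def weight(self, u: Vertex, v: Vertex = None) -> float:
        e = u if v is None else self.canonical(u, v)
        try:
            return self._weight[e]
        except KeyError:
            raise ConditionGraphError(f"unknown edge {e!r}") from None

    def exists_at(self, u: Vertex, v: Vertex = None) -> FrozenSet[int]:
        e = u if v is None else self.canonical(u, v)
        try:
            return self._exists_at[e]
        except KeyError:
            raise ConditionGraphError(f"unknown edge {e!r}") from None

    def copy(self) -> "ConditionGraph":
        g = ConditionGraph(self.num_conditions, self.directed)
        g._vertices = set(self._vertices)
        g._weight = dict(self._weight)
        g._exists_at = dict(self._exists_at)
        return g

    def __contains__(self, e: Edge) -> bool:
        return e in self._weight

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "directed" if self.directed else "undirected"
        return (f"<ConditionGraph {kind} |V|={len(self._vertices)} "
                f"|E|={len(self._weight)} C={self.num_conditions}>")


def frame(graph: ConditionGraph, c: int):
    """The plain weighted graph ``G_c = (V, E_c)`` at a single condition.

    Returns a :class:`networkx.DiGraph` or :class:`networkx.Graph` with the
    underlying weights restricted to edges existing at ``c``.
    """
    if not 1 <= c <= graph.num_conditions:
        raise ConditionGraphError(
            f"condition {c} out of range 1..{graph.num_conditions}")
    g = nx.DiGraph() if graph.directed else nx.Graph()
    g.add_nodes_from(graph.vertices)
    for (u, v) in graph.edges:
        if c in graph.exists_at(u, v):
            g.add_edge(u, v, weight=graph.weight(u, v))
    return g


def is_monotonic(graph: ConditionGraph) -> bool:
    """True iff every edge persists once born: ``e in G_c ⇒ e in G_{c'}``, c' ≥ c."""
    C = graph.num_conditions
    for e in graph.edges:
        conds = graph.exists_at(e)
        if conds != frozenset(range(min(conds), C + 1)):
            return False
    return True


@dataclass(frozen=True, order=True)
class Demand:
    """Connectivity demand ``(a, b, c)``: an a–b path alive at condition c."""
    source: Vertex
    target: Vertex
    condition: int

    def __post_init__(self):
        if self.source == self.target:
            raise ValueError(f"demand endpoints coincide: {self.source!r}")


def _check_demands(graph: ConditionGraph, demands: Sequence[Demand]) -> None:
    covered = set()
    for d in demands:
        if not 1 <= d.condition <= graph.num_conditions:
            raise ConditionGraphError(
                f"demand condition {d.condition} out of range "
                f"1..{graph.num_conditions}")
        if d.source not in graph.vertices or d.target not in graph.vertices:
            raise ConditionGraphError(f"demand {d} references unknown vertices")
        covered.add(d.condition)
    missing = set(range(1, graph.num_conditions + 1)) - covered
    if missing:
        warnings.warn(
            f"no demand at condition(s) {sorted(missing)}; instance accepted",
            stacklevel=3)


@dataclass
class CSNInstance:
    """A condition Steiner network instance in one of three formulations.

    ``variant`` selects which parts of the input vary across conditions:

    - ``"edge"``: per-edge condition sets (the canonical form all solvers use);
    - ``"node"``: per-vertex condition sets; an edge exists at ``c`` exactly
      when both endpoints do;
    - ``"node-and-edge"``: per-edge condition sets constrained to the nodes'.
    """
    graph: ConditionGraph
    demands: Sequence[Demand]
    variant: str = "edge"
    node_exists_at: Optional[Mapping[Vertex, FrozenSet[int]]] = None

    def __post_init__(self):
        if self.variant not in ("edge", "node", "node-and-edge"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant != "edge" and self.node_exists_at is None:
            raise ValueError(f"variant {self.variant!r} needs node_exists_at")
        self.demands = tuple(self.demands)
        _check_demands(self.graph, self.demands)
        if self.variant == "node":
            for e in self.graph.edges:
                u, v = e
                expect = (frozenset(self.node_exists_at.get(u, frozenset())) &
                          frozenset(self.node_exists_at.get(v, frozenset())))
                if self.graph.exists_at(e) != expect:
                    raise ConditionGraphError(
                        f"node-variant edge {e!r} not induced by its endpoints")

    @property
    def num_demands(self) -> int:
        return len(self.demands)

    def is_single_source(self) -> bool:
        return len({d.source for d in self.demands}) == 1

    @property
    def root(self) -> Vertex:
        sources = {d.source for d in self.demands}
        if len(sources) != 1:
            raise ConditionGraphError("instance is not single-source")
        return next(iter(sources))


@dataclass
class CSTInstance:
    """Condition Steiner tree: per-condition terminal sets to interconnect."""
    graph: ConditionGraph
    terminal_sets: Sequence[FrozenSet[Vertex]]

    def __post_init__(self):
        if self.graph.directed:
            raise ConditionGraphError("condition Steiner tree is undirected")
        if len(self.terminal_sets) != self.graph.num_conditions:
            raise ConditionGraphError("need one terminal set per condition")
        self.terminal_sets = tuple(frozenset(x) for x in self.terminal_sets)
        for c, X in enumerate(self.terminal_sets, start=1):
            if not X:
                raise ConditionGraphError(f"empty terminal set at condition {c}")
            if not X <= self.graph.vertices:
                raise ConditionGraphError(
                    f"terminals {X - self.graph.vertices} unknown at condition {c}")


@dataclass
class CPCSTInstance:
    """Condition prize-collecting Steiner tree.

    The sought object is a subtree ``T``; the objective adds, to the weight
    of the tree's edges, the penalty ``p(v, c)`` for every vertex/condition
    pair with ``v`` outside the tree.  ``penalty`` maps ``(v, c)`` to a
    nonnegative real or :data:`INF`; missing pairs default to 0.
    """
    graph: ConditionGraph
    penalty: Mapping[Tuple[Vertex, int], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.graph.directed:
            raise ConditionGraphError("prize-collecting Steiner tree is undirected")
        for (v, c), p in self.penalty.items():
            if p < 0:
                raise ConditionGraphError(f"negative penalty at ({v!r}, {c})")

    def get_penalty(self, v: Vertex, c: int) -> float:
        return self.penalty.get((v, c), 0.0)


@dataclass
class PrioritySteinerInstance:
    """Priority Steiner tree on an undirected multigraph.

    ``edges`` is a sequence of ``(u, v, weight, priority)``; parallel edges
    are allowed (each sequence position is its own multiedge).  A demand
    ``(a, b)`` with priority ``p`` must be routed along edges of priority
    ``<= p``.
    """
    vertices: FrozenSet[Vertex]
    edges: Sequence[Tuple[Vertex, Vertex, float, int]]
    demands: Sequence[Tuple[Vertex, Vertex, int]]

    def __post_init__(self):
        self.vertices = frozenset(self.vertices)
        self.edges = tuple(self.edges)
        self.demands = tuple(self.demands)
        for (u, v, w, p) in self.edges:
            if w < 0 or p < 1:
                raise ConditionGraphError(f"bad multiedge ({u!r},{v!r},{w},{p})")

    @property
    def max_priority(self) -> int:
        levels = [p for (_, _, _, p) in self.edges]
        levels += [p for (_, _, p) in self.demands]
        return max(levels) if levels else 1


@dataclass
class Solution:
    """A chosen edge set plus its cost and per-demand witness paths."""
    chosen_edges: FrozenSet[Edge]
    cost: float
    witnesses: Dict[Demand, Tuple[Vertex, ...]] = field(default_factory=dict)

    def __post_init__(self):
        self.chosen_edges = frozenset(self.chosen_edges)


@dataclass
class PrioritySolution:
    """Solution of a priority Steiner instance: chosen multiedge indices."""
    chosen_edges: FrozenSet[int]
    cost: float

    def __post_init__(self):
        self.chosen_edges = frozenset(self.chosen_edges)


def solution_cost(solution: Solution, graph: ConditionGraph) -> float:
    """Sum of weights of the chosen edges, each counted exactly once."""
    return sum(graph.weight(e) for e in solution.chosen_edges)


def _restricted_frame(graph: ConditionGraph, c: int, edges: FrozenSet[Edge]):
    g = nx.DiGraph() if graph.directed else nx.Graph()
    g.add_nodes_from(graph.vertices)
    for e in edges:
        if c in graph.exists_at(e):
            g.add_edge(*e)
            if not graph.directed:
                g.add_edge(e[1], e[0])
    return g


def satisfies(solution: Solution, demand: Demand,
              graph: ConditionGraph) -> bool:
    """Whether ``solution`` routes ``demand`` at its condition.

    On success the witness path is recorded on the solution.
    """
    if not 1 <= demand.condition <= graph.num_conditions:
        raise ConditionGraphError(f"demand condition {demand.condition} invalid")
    g = _restricted_frame(graph, demand.condition, solution.chosen_edges)
    if demand.source not in g or demand.target not in g:
        return False
    try:
        path = nx.shortest_path(g, demand.source, demand.target)
    except nx.NetworkXNoPath:
        return False
    solution.witnesses[demand] = tuple(path)
    return True


def is_feasible(solution: Solution, instance: CSNInstance) -> bool:
    """Exhaustively check every demand of the instance."""
    return all(satisfies(solution, d, instance.graph) for d in instance.demands)
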