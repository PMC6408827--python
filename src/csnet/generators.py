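"""Instance generators: hardness gadgets, worst-case fixtures, random instances.

Three families live here:

- *Label-cover gadgets*: the bundle/strand constructions that translate
  (hypergraph) label-cover instances into condition Steiner instances whose
  optimum reveals whether a consistent labeling exists.  Contact edges have
  weight 1, all other edges weight 0, and agreeing label tuples share one
  merged contact edge across conditions.
- *Worst-case fixtures*: the hub-and-spokes instance on which routing every
  demand independently is a factor ``k`` worse than the optimum.
- *Random instances*: monotonic instances for the recursive-greedy
  algorithm, small mixed instances for oracle cross-checks, and a
  PPI-style single-source sampler (scale-free-ish topology, negative-log
  confidence weights, per-condition node activity).

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model import (
    ConditionGraph,
    ConditionGraphError,
    CSNInstance,
    CSTInstance,
    Demand,
    Vertex,
)
from .variants import make_node_instance


# ---------------------------------------------------------------------------
# Label cover
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelCoverInstance:
    """Bipartite constraint instance with per-edge projection functions.

    ``projections[(edge, endpoint)]`` maps each label to a color; an edge is
    satisfied by a labeling when both endpoint projections agree.
    """
    left: Tuple[Vertex, ...]
    right: Tuple[Vertex, ...]
    edges: Tuple[Tuple[Vertex, Vertex], ...]
    labels: Tuple[int, ...]
    colors: Tuple[int, ...]
    projections: Mapping[Tuple[Tuple[Vertex, Vertex], Vertex], Mapping[int, int]]

    def __post_init__(self):
        for e in self.edges:
            for side in e:
                proj = self.projections.get((e, side))
                if proj is None or set(proj) != set(self.labels):
                    raise ValueError(
                        f"projection for edge {e} endpoint {side!r} not total")

    def agreeing_pairs(self, e) -> List[Tuple[int, int]]:
        """Label pairs (l, r) whose projections agree on edge e."""
        pu = self.projections[(e, e[0])]
        pv = self.projections[(e, e[1])]
        return [(l, r) for l in self.labels for r in self.labels
                if pu[l] == pv[r]]


@dataclass(frozen=True)
class KPHLCInstance:
    """k-partite hypergraph label cover: one vertex per part per hyperedge."""
    parts: Tuple[Tuple[Vertex, ...], ...]
    hyperedges: Tuple[Tuple[Vertex, ...], ...]
    labels: Tuple[int, ...]
    projections: Mapping[Tuple[Tuple[Vertex, ...], Vertex], Mapping[int, int]]

    def __post_init__(self):
        k = len(self.parts)
        if k < 2:
            raise ValueError("need at least two parts")
        for e in self.hyperedges:
            if len(e) != k:
                raise ValueError(f"hyperedge {e} does not touch every part")
            for c, v in enumerate(e):
                if v not in self.parts[c]:
                    raise ValueError(f"vertex {v!r} not in part {c + 1}")
        degree = {v: 0 for part in self.parts for v in part}
        for e in self.hyperedges:
            for v in e:
                degree[v] += 1
        if len(set(degree.values())) > 1:
            warnings.warn("hypergraph is not regular", stacklevel=2)

    @property
    def k(self) -> int:
        return len(self.parts)

    def agreeing_tuples(self, e) -> List[Tuple[int, ...]]:
        """Label k-tuples whose projections all map to one color."""
        out = []
        projs = [self.projections[(e, v)] for v in e]
        import itertools
        for combo in itertools.product(self.labels, repeat=len(e)):
            colors = {projs[i][l] for i, l in enumerate(combo)}
            if len(colors) == 1:
                out.append(combo)
        return out


class _GadgetBuilder:
    """Accumulates gadget vertices/edges; merges contact edges by strand key."""

    def __init__(self, num_conditions: int):
        self.num_conditions = num_conditions
        self.zero_edges: List[Tuple[str, str, int]] = []  # (u, v, condition)
        self.contacts: Dict[str, set] = {}  # contact key -> conditions

    def contact_nodes(self, key: str) -> Tuple[str, str]:
        return f"{key}&in", f"{key}&out"

    def simple_strand(self, b1: str, b2: str, key: str, condition: int) -> None:
        """b1 -> c1 -> c2 -> b2 with the (c1, c2) contact edge merged by key."""
        c1, c2 = self.contact_nodes(key)
        self.zero_edges.append((b1, c1, condition))
        self.zero_edges.append((c2, b2, condition))
        self.contacts.setdefault(key, set()).add(condition)

    def build(self, demands: Sequence[Demand]) -> CSNInstance:
        g = ConditionGraph(num_conditions=self.num_conditions, directed=True)
        for (u, v, c) in self.zero_edges:
            if not g.has_edge(u, v):
                g.add_edge(u, v, 0.0, {c})
            else:
                # same zero edge reused at another condition: rebuild union
                conds = g.exists_at(u, v) | {c}
                w = g.weight(u, v)
                g._weight[(u, v)] = w
                g._exists_at[(u, v)] = frozenset(conds)
        for key, conds in self.contacts.items():
            c1, c2 = self.contact_nodes(key)
            g.add_edge(c1, c2, 1.0, conds)
        return CSNInstance(graph=g, demands=demands, variant="edge")


def label_cover_to_2dcsn(lc: LabelCoverInstance) -> CSNInstance:
    """Gadget translation of label cover to a 2-condition directed instance.

    The left side becomes a chain of bundles alive at condition 1, the right
    side a chain alive at condition 2; each agreeing label pair contributes a
    shared (merged) unit-weight contact edge.  The optimum equals ``|E|``
    exactly when a total labeling exists, and exceeds it otherwise; the
    underlying digraph is acyclic.
    """
    b = _GadgetBuilder(num_conditions=2)

    def side_chain(side_nodes, condition, incident, strand_labels, key_of,
                   prefix):
        chain = [f"{prefix}{i + 1}_S" for i in range(len(side_nodes) + 1)]
        for i, node in enumerate(side_nodes):
            b1, b2 = chain[i], chain[i + 1]
            if not incident(node):
                # unconstrained node: its labeling is free, bridge the chain
                b.zero_edges.append((b1, b2, condition))
                continue
            for lab in strand_labels:
                edges_here = incident(node)
                # waypoints of the chain of per-edge bundles inside the strand
                way = [b1] + [f"{prefix}|{node}.{lab}|{t + 1}"
                              for t in range(len(edges_here) - 1)] + [b2]
                for t, e in enumerate(edges_here):
                    keys = key_of(node, lab, e)
                    if not keys:
                        keys = [f"lone|{prefix}|{node}.{lab}|{e}"]
                    for key in keys:
                        b.simple_strand(way[t], way[t + 1], key, condition)
        return chain[0], chain[-1]

    # Traverse each strand's bundles in the partner's chain order, so both
    # chains visit a merged contact at a consistent global position.
    def u_incident(u):
        return sorted((e for e in lc.edges if e[0] == u),
                      key=lambda e: lc.right.index(e[1]))

    def v_incident(v):
        return sorted((e for e in lc.edges if e[1] == v),
                      key=lambda e: lc.left.index(e[0]))

    def u_keys(u, l, e):
        pu = lc.projections[(e, e[0])]
        pv = lc.projections[(e, e[1])]
        return [f"path|{e}|{l}.{r}" for r in lc.labels if pu[l] == pv[r]]

    def v_keys(v, r, e):
        pu = lc.projections[(e, e[0])]
        pv = lc.projections[(e, e[1])]
        return [f"path|{e}|{l}.{r}" for l in lc.labels if pu[l] == pv[r]]

    u_start, u_end = side_chain(lc.left, 1, u_incident, lc.labels, u_keys, "u")
    v_start, v_end = side_chain(lc.right, 2, v_incident, lc.labels, v_keys, "v")
    return b.build([Demand(u_start, u_end, 1), Demand(v_start, v_end, 2)])


def kphlc_to_dcsn(instance: KPHLCInstance) -> CSNInstance:
    """Gadget translation of k-partite hypergraph label cover to k conditions.

    Part ``c``'s bundle chain is alive at condition ``c`` only; agreeing
    label k-tuples are merged into one contact edge shared by all k
    conditions.  For strongly satisfiable inputs the optimum is the
    hyperedge count ``|E|``; with no agreeing tuple anywhere it is
    ``k · |E|``.
    """
    k = instance.k
    if k < 2:
        raise ConditionGraphError("need k >= 2")
    b = _GadgetBuilder(num_conditions=k)
    demands = []
    for c, part in enumerate(instance.parts, start=1):
        chain = [f"p{c}_{i + 1}_S" for i in range(len(part) + 1)]
        for i, node in enumerate(part):
            b1, b2 = chain[i], chain[i + 1]
            incident = [e for e in instance.hyperedges if e[c - 1] == node]
            if not incident:
                b.zero_edges.append((b1, b2, c))
                continue
            for lab in instance.labels:
                way = [b1] + [f"p{c}|{node}.{lab}|{t + 1}"
                              for t in range(len(incident) - 1)] + [b2]
                for t, e in enumerate(incident):
                    combos = [cmb for cmb in instance.agreeing_tuples(e)
                              if cmb[c - 1] == lab]
                    keys = [f"path|{e}|{cmb}" for cmb in combos]
                    if not keys:
                        keys = [f"lone|p{c}|{node}.{lab}|{e}"]
                    for key in keys:
                        b.simple_strand(way[t], way[t + 1], key, c)
        demands.append(Demand(chain[0], chain[-1], c))
    return b.build(demands)


def example1() -> CSNInstance:
    """The worked two-condition toy produced by the label-cover gadget.

    One constraint edge (u, v), labels {1, 2}, two colors; the projections
    are the unique assignment (up to renaming) in which v's label 2 agrees
    with both labels of u while v's label 1 agrees with neither:
    ``π_u = {1: 1, 2: 1}``, ``π_v = {1: 2, 2: 1}``.  Condition 1 holds the
    u-side strands, condition 2 one lone strand for v-label 1 plus a bundle
    of two merged strands for v-label 2.  The optimal subgraph routes both
    demands through one shared contact edge, so the optimum is exactly 1.
    """
    e = ("u", "v")
    lc = LabelCoverInstance(
        left=("u",), right=("v",),
        edges=(e,),
        labels=(1, 2), colors=(1, 2),
        projections={(e, "u"): {1: 1, 2: 1},
                     (e, "v"): {1: 2, 2: 1}},
    )
    return label_cover_to_2dcsn(lc)


def random_label_cover(num_left: int = 2, num_right: int = 2,
                       num_edges: int = 3, num_labels: int = 2,
                       num_colors: int = 2, seed: int = 0,
                       satisfiable: bool = True,
                       unsatisfiable_edge: bool = False,
                       allow_crossing: bool = False) -> LabelCoverInstance:
    """Random bipartite label-cover instance.

    With ``satisfiable`` a total labeling is planted (every edge agrees under
    it).  With ``unsatisfiable_edge`` one edge's projections have disjoint
    color ranges, so no labeling satisfies it.  By default the constraint
    edges form a non-crossing "staircase" (no pair (u_i, v_j), (u_{i'},
    v_{j'}) with i < i' and j > j'): this is the regime in which the gadget
    translation yields an acyclic digraph — a crossing pair whose contact
    edges both merge would force a directed cycle through the two chains.
    """
    rng = np.random.default_rng(seed)
    if num_colors < 2 and unsatisfiable_edge:
        raise ValueError("need two colors to make an edge unsatisfiable")
    left = tuple(f"u{i}" for i in range(num_left))
    right = tuple(f"v{j}" for j in range(num_right))
    labels = tuple(range(1, num_labels + 1))
    colors = tuple(range(1, num_colors + 1))
    if allow_crossing:
        pairs = []
        for i in range(max(num_left, num_right, num_edges)):
            pairs.append((left[i % num_left], right[i % num_right]))
            if len(pairs) >= num_edges:
                break
        pairs = list(dict.fromkeys(pairs))
        while len(pairs) < num_edges:
            cand = (left[rng.integers(num_left)], right[rng.integers(num_right)])
            if cand not in pairs:
                pairs.append(cand)
    else:
        if num_edges > num_left + num_right - 1:
            raise ValueError(
                "a non-crossing staircase admits at most |U| + |V| - 1 edges")
        # staircase walk: advance one side's index at a time, never retreat
        pairs = [(0, 0)]
        while len(pairs) < num_edges:
            i, j = pairs[-1]
            moves = [(i + 1, j)] if i + 1 < num_left else []
            if j + 1 < num_right:
                moves.append((i, j + 1))
            pairs.append(moves[int(rng.integers(len(moves)))])
        pairs = [(left[i], right[j]) for (i, j) in pairs]
    edges = tuple(pairs)

    planted = {v: int(rng.integers(1, num_labels + 1)) for v in left + right}
    projections = {}
    for e in edges:
        u, v = e
        pu = {l: int(rng.integers(1, num_colors + 1)) for l in labels}
        pv = {l: int(rng.integers(1, num_colors + 1)) for l in labels}
        if satisfiable:
            agree = int(rng.integers(1, num_colors + 1))
            pu[planted[u]] = agree
            pv[planted[v]] = agree
        projections[(e, u)] = pu
        projections[(e, v)] = pv
    if unsatisfiable_edge:
        e = edges[0]
        projections[(e, e[0])] = {l: 1 for l in labels}
        projections[(e, e[1])] = {l: 2 for l in labels}
    return LabelCoverInstance(left=left, right=right, edges=edges,
                              labels=labels, colors=colors,
                              projections=projections)


def random_kphlc(k: int = 3, num_hyperedges: int = 2, num_labels: int = 2,
                 num_colors: int = 2, seed: int = 0,
                 strongly_satisfiable: bool = True,
                 no_agreement: bool = False) -> KPHLCInstance:
    """Random k-partite hypergraph label-cover instance.

    ``strongly_satisfiable`` plants a labeling under which every hyperedge's
    projections all agree; ``no_agreement`` gives every vertex of every
    hyperedge a projection range disjoint from the others', so no label
    tuple agrees anywhere.
    """
    rng = np.random.default_rng(seed)
    if no_agreement and num_colors < k:
        num_colors = k
    labels = tuple(range(1, num_labels + 1))
    parts = tuple(
        tuple(f"p{c + 1}n{i}" for i in range(num_hyperedges))
        for c in range(k))
    # one hyperedge per "row" keeps the hypergraph 1-regular
    hyperedges = tuple(tuple(parts[c][i] for c in range(k))
                       for i in range(num_hyperedges))
    planted = {v: int(rng.integers(1, num_labels + 1))
               for part in parts for v in part}
    projections = {}
    for e in hyperedges:
        if no_agreement:
            for c, v in enumerate(e):
                projections[(e, v)] = {l: c + 1 for l in labels}
            continue
        agree = int(rng.integers(1, num_colors + 1))
        for v in e:
            pv = {l: int(rng.integers(1, num_colors + 1)) for l in labels}
            if strongly_satisfiable:
                pv[planted[v]] = agree
            projections[(e, v)] = pv
    return KPHLCInstance(parts=parts, hyperedges=hyperedges, labels=labels,
                         projections=projections)


# ---------------------------------------------------------------------------
# Worst case for the union of shortest paths
# ---------------------------------------------------------------------------

def star_worst_case(k: int, M: float, eps: float) -> CSNInstance:
    """Hub-and-spokes instance where per-demand routing is k times optimal.

    The root has a direct arc of weight ``M - eps`` to each of ``k`` targets
    and an arc of weight ``M`` to a hub with free arcs to every target.  The
    optimum (through the hub) costs ``M``; the union of per-demand shortest
    paths takes every direct arc, costing ``k (M - eps)``.
    """
    if not 0 < eps < M:
        raise ValueError("need 0 < eps < M")
    g = ConditionGraph(num_conditions=1, directed=True)
    demands = []
    for j in range(1, k + 1):
        g.add_edge("root", f"t{j}", M - eps, {1})
        g.add_edge("hub", f"t{j}", 0.0, {1})
        demands.append(Demand("root", f"t{j}", 1))
    g.add_edge("root", "hub", M, {1})
    return CSNInstance(graph=g, demands=demands, variant="edge")


# ---------------------------------------------------------------------------
# Random graphs
# ---------------------------------------------------------------------------

def _skewed_digraph(n: int, m: int, rng) -> Tuple[List[str], List[Tuple[str, str, float]]]:
    """Degree-skewed weighted digraph, every vertex reachable from v0.

    Preferential-attachment flavour: a random out-tree from the root
    guarantees reachability, then extra arcs attach to endpoints sampled
    proportionally to their current degree.  Weights are negative logs of
    pseudo-confidences drawn uniformly from (0.5, 0.99).
    """
    if m < n - 1:
        raise ValueError(f"need at least {n - 1} arcs for {n} vertices")
    names = [f"v{i}" for i in range(n)]
    pool: List[int] = [0]
    arcs = set()
    for i in range(1, n):
        parent = pool[rng.integers(len(pool))]
        arcs.add((parent, i))
        pool += [parent, i]
    tries = 0
    while len(arcs) < m and tries < 50 * m:
        tries += 1
        u = pool[rng.integers(len(pool))]
        v = int(rng.integers(n))
        if u != v and (u, v) not in arcs:
            arcs.add((u, v))
            pool += [u, v]
    weighted = []
    for (u, v) in sorted(arcs):
        conf = rng.uniform(0.5, 0.99)
        weighted.append((names[u], names[v], float(-math.log(conf))))
    return names, weighted


def _deterministic_shortest_path(adj, dist, target):
    """Backwards reconstruction choosing the smallest predecessor at ties."""
    path = [target]
    cur = target
    while dist[cur] > 0:
        cands = [u for (u, w) in adj.get(cur, ())
                 if u in dist and abs(dist[u] + w - dist[cur]) <= 1e-12]
        cur = min(cands)
        path.append(cur)
    path.reverse()
    return path


def random_single_source_instance(n: int, m: int, beta: int, C: int, p: float,
                                  seed: int = 0,
                                  replace: bool = False) -> CSNInstance:
    """PPI-style random node-variant single-source instance.

    Emulates sampling a biological process over a reference interaction
    network: pick a root ``a``; for each of ``C`` conditions sample ``beta``
    reachable target proteins (without replacement within a condition unless
    ``replace``); a node is active at condition ``c`` if it lies on the
    (deterministic, lexicographic tie-broken) shortest path from ``a`` to one
    of that condition's targets, or otherwise with probability ``p``.
    Demands connect the root to every sampled target at its condition.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be a probability")
    rng = np.random.default_rng(seed)
    names, weighted = _skewed_digraph(n, m, rng)
    a = names[0]

    fwd: Dict[str, List[Tuple[str, float]]] = {}
    back: Dict[str, List[Tuple[str, float]]] = {}
    for (u, v, w) in weighted:
        fwd.setdefault(u, []).append((v, w))
        back.setdefault(v, []).append((u, w))

    import heapq
    dist = {a: 0.0}
    heap = [(0.0, a)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist.get(u, float("inf")):
            continue
        for (v, w) in fwd.get(u, ()):
            nd = d + w
            if nd < dist.get(v, float("inf")) - 1e-15:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    reachable = sorted(set(dist) - {a})
    if len(reachable) < beta:
        raise ConditionGraphError(
            f"only {len(reachable)} vertices reachable from the root; "
            f"need beta={beta}")

    node_tau: Dict[str, set] = {v: set() for v in names}
    demands = []
    for c in range(1, C + 1):
        targets = rng.choice(reachable, size=beta, replace=replace)
        for b in sorted(set(map(str, targets))):
            for v in _deterministic_shortest_path(back, dist, b):
                node_tau[v].add(c)
        for b in map(str, targets):
            demands.append(Demand(a, b, c))
        for v in names:
            if c not in node_tau[v] and rng.random() < p:
                node_tau[v].add(c)
    node_tau[a].update(range(1, C + 1))

    edges = [(u, v, w) for (u, v, w) in weighted]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_node_instance(node_tau, edges, demands, C, directed=True)


def random_monotonic_instance(n: int, m: int, C: int, k: int, seed: int = 0,
                              directed: bool = True,
                              single_source: bool = True) -> CSNInstance:
    """Random monotonic instance with feasible demands.

    Every edge is assigned a uniform birth condition and persists thereafter,
    so the instance is monotonic by construction.  Demands are sampled among
    pairs reachable at their condition (rooted at ``v0`` when
    ``single_source``).
    """
    rng = np.random.default_rng(seed)
    names, weighted = _skewed_digraph(n, m, rng)
    g = ConditionGraph(num_conditions=C, directed=directed)
    for (u, v, w) in weighted:
        if not directed and g.has_edge(u, v):
            continue
        birth = int(rng.integers(1, C + 1))
        g.add_edge(u, v, w, range(birth, C + 1))

    import networkx as nx
    from .model import frame
    demands: List[Demand] = []
    seen = set()
    conditions = list(range(1, C + 1)) * ((k // C) + 1)
    for c in conditions:
        if len(demands) >= k:
            break
        fg = frame(g, c)
        if single_source:
            a = names[0]
            reach = sorted(nx.descendants(fg, a)) if a in fg else []
        else:
            a = names[int(rng.integers(n))]
            reach = sorted(nx.descendants(fg, a)) if a in fg else []
        if not reach:
            continue
        b = reach[int(rng.integers(len(reach)))]
        if (a, b, c) not in seen:
            seen.add((a, b, c))
            demands.append(Demand(a, b, c))
    if not demands:
        raise ConditionGraphError("failed to sample any feasible demand")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CSNInstance(graph=g, demands=demands, variant="edge")


def random_small_instance(seed: int = 0,
                          directed: Optional[bool] = None,
                          variant: Optional[str] = None,
                          max_vertices: int = 8, max_edges: int = 14,
                          max_conditions: int = 3,
                          max_demands: int = 3) -> CSNInstance:
    """Small random instance for oracle cross-checks (mixed shapes).

    Orientation and variant are drawn from the seed unless pinned.  All
    demands are feasible by construction.
    """
    rng = np.random.default_rng(seed)
    if directed is None:
        directed = bool(rng.integers(2))
    if variant is None:
        variant = ["edge", "node", "node-and-edge"][int(rng.integers(3))]
    n = int(rng.integers(4, max_vertices + 1))
    C = int(rng.integers(1, max_conditions + 1))
    names = [f"n{i}" for i in range(n)]

    pairs = set()
    for i in range(1, n):
        j = int(rng.integers(i))
        pairs.add((names[j], names[i]))
    target_edges = int(rng.integers(n - 1, max_edges + 1))
    tries = 0
    while len(pairs) < target_edges and tries < 200:
        tries += 1
        u, v = rng.choice(n, size=2, replace=False)
        u, v = int(u), int(v)
        key = (names[u], names[v])
        if not directed and (names[v], names[u]) in pairs:
            continue
        pairs.add(key)
    weights = {e: float(np.round(rng.uniform(0.0, 3.0), 3)) for e in sorted(pairs)}

    if variant == "edge":
        g = ConditionGraph(num_conditions=C, directed=directed)
        for (u, v), w in weights.items():
            conds = [c for c in range(1, C + 1) if rng.random() < 0.7]
            if not conds:
                conds = [int(rng.integers(1, C + 1))]
            g.add_edge(u, v, w, conds)
        inst_graph = g
        node_tau = None
    else:
        node_tau = {}
        for v in names:
            conds = {c for c in range(1, C + 1) if rng.random() < 0.8}
            if not conds:
                conds = {int(rng.integers(1, C + 1))}
            node_tau[v] = frozenset(conds)
        if variant == "node":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                base = make_node_instance(
                    node_tau, [(u, v, w) for (u, v), w in weights.items()],
                    [], C, directed=directed)
            inst_graph = base.graph
        else:
            g = ConditionGraph(num_conditions=C, directed=directed)
            for (u, v), w in weights.items():
                induced = node_tau[u] & node_tau[v]
                conds = {c for c in induced if rng.random() < 0.8}
                if induced and not conds:
                    conds = {sorted(induced)[int(rng.integers(len(induced)))]}
                if conds:
                    g.add_edge(u, v, w, conds)
            inst_graph = g

    import networkx as nx
    from .model import frame
    demands = []
    k = int(rng.integers(1, max_demands + 1))
    attempts = 0
    while len(demands) < k and attempts < 60:
        attempts += 1
        c = int(rng.integers(1, C + 1))
        fg = frame(inst_graph, c)
        a = names[int(rng.integers(n))]
        reach = sorted(nx.descendants(fg, a)) if a in fg else []
        if not reach:
            continue
        b = reach[int(rng.integers(len(reach)))]
        d = Demand(a, b, c)
        if d not in demands:
            demands.append(d)
    if not demands:
        # fall back to any edge as a one-hop demand
        e = sorted(inst_graph.edges, key=repr)[0]
        demands = [Demand(e[0], e[1], min(inst_graph.exists_at(e)))]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CSNInstance(graph=inst_graph, demands=demands, variant=variant,
                           node_exists_at=node_tau)


def random_cst_instance(seed: int = 0, monotonic: bool = False,
                        shared_root: bool = False,
                        uniform_conditions: bool = False) -> CSTInstance:
    """Small random condition Steiner tree instance.

    ``uniform_conditions`` makes every edge alive at every condition;
    combined with ``shared_root`` (all terminal sets share one vertex) the
    optimum coincides with the Steiner tree on the union of terminals,
    which is the regime where the prize-collecting encoding is exact.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 8))
    C = int(rng.integers(1, 4))
    names = [f"n{i}" for i in range(n)]
    g = ConditionGraph(num_conditions=C, directed=False)
    pairs = set()
    for i in range(1, n):
        j = int(rng.integers(i))
        pairs.add((names[j], names[i]))
    extra = int(rng.integers(0, 5))
    tries = 0
    while tries < 40 and extra > 0:
        tries += 1
        u, v = rng.choice(n, size=2, replace=False)
        key = (names[min(u, v)], names[max(u, v)])
        if key not in pairs:
            pairs.add(key)
            extra -= 1
    for (u, v) in sorted(pairs):
        w = float(np.round(rng.uniform(0.1, 2.0), 3))
        if uniform_conditions:
            conds = range(1, C + 1)
        elif monotonic:
            conds = range(int(rng.integers(1, C + 1)), C + 1)
        else:
            conds = {c for c in range(1, C + 1) if rng.random() < 0.7} or \
                {int(rng.integers(1, C + 1))}
        g.add_edge(u, v, w, conds)

    import networkx as nx
    from .model import frame
    terminal_sets = []
    root = names[0]
    for c in range(1, C + 1):
        fg = frame(g, c)
        comp = nx.node_connected_component(fg, root) if root in fg else {root}
        comp = sorted(comp)
        size = min(len(comp), int(rng.integers(1, 4)))
        chosen = set(map(str, rng.choice(comp, size=size, replace=False)))
        if shared_root:
            chosen.add(root)
        terminal_sets.append(frozenset(chosen))
    return CSTInstance(graph=g, terminal_sets=terminal_sets)
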