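"""Approximation algorithms: closure, shortest-path union, recursive greedy."""

import itertools
import math

import networkx as nx
import pytest

from csnet.model import ConditionGraph, CSNInstance, Demand, is_feasible
from csnet.approx import (
    charikar_closure_tree,
    charikar_tree,
    expand_closure_tree,
    metric_closure,
    shortest_path_union,
)
from csnet.generators import (
    random_monotonic_instance,
    random_small_instance,
    star_worst_case,
)
from csnet.oracle import InfeasibleInstanceError, brute_force_opt
from csnet.reductions import monotonic_ssdcsn_to_dst
from csnet.variants import to_edge_variant


class TestMetricClosure:
    def test_self_distance_zero(self):
        g = ConditionGraph(num_conditions=2)
        g.add_edge("u", "v", 2.0, {1})
        mc = metric_closure(g)
        assert mc.distance("u", "u", 1) == 0.0
        assert mc.distance("v", "v", 2) == 0.0

    def test_absent_condition_is_infinite(self):
        g = ConditionGraph(num_conditions=2)
        g.add_edge("u", "v", 2.0, {1})
        mc = metric_closure(g)
        assert mc.distance("u", "v", 1) == 2.0
        assert mc.distance("u", "v", 2) == math.inf

    def test_against_exhaustive_path_enumeration(self):
        """Closure distances equal the best over all simple paths."""
        inst = random_small_instance(7, variant="edge", max_vertices=5)
        g = inst.graph
        mc = metric_closure(g)
        from csnet.model import frame
        for c in range(1, g.num_conditions + 1):
            fg = frame(g, c)
            for u in sorted(g.vertices, key=repr):
                for v in sorted(g.vertices, key=repr):
                    if u == v:
                        continue
                    best = math.inf
                    for path in nx.all_simple_paths(fg, u, v):
                        w = sum(fg[a][b]["weight"]
                                for a, b in zip(path, path[1:]))
                        best = min(best, w)
                    assert mc.distance(u, v, c) == pytest.approx(best)

    def test_monotone_instances_have_nonincreasing_distances(self):
        inst = random_monotonic_instance(n=6, m=10, C=3, k=2, seed=2)
        mc = metric_closure(inst.graph)
        for u in inst.graph.vertices:
            for v in inst.graph.vertices:
                dists = [mc.distance(u, v, c) for c in (1, 2, 3)]
                assert dists == sorted(dists, reverse=True)

    def test_path_recovery_matches_distance(self):
        inst = random_small_instance(9, variant="edge")
        g = inst.graph
        mc = metric_closure(g)
        d = inst.demands[0]
        path = mc.recover_path(d.source, d.target, d.condition)
        w = sum(g.weight(a, b) for a, b in zip(path, path[1:]))
        assert w == pytest.approx(mc.distance(d.source, d.target, d.condition))


class TestShortestPathUnion:
    def test_single_demand_is_the_shortest_path(self):
        from conftest import path_instance
        inst = path_instance(weights=(1.0, 0.5))
        sol = shortest_path_union(inst)
        assert sol.cost == pytest.approx(1.5)

    def test_shared_paths_deduplicate(self):
        g = ConditionGraph(num_conditions=2, directed=True)
        g.add_edge("a", "b", 1.0, {1, 2})
        inst = CSNInstance(graph=g,
                           demands=[Demand("a", "b", 1), Demand("a", "b", 2)],
                           variant="edge")
        assert shortest_path_union(inst).cost == pytest.approx(1.0)

    def test_star_worst_case_ratio(self):
        inst = star_worst_case(k=5, M=10.0, eps=0.01)
        spu = shortest_path_union(inst)
        assert spu.cost == pytest.approx(5 * (10.0 - 0.01))
        assert brute_force_opt(inst).cost == pytest.approx(10.0)

    def test_unreachable_demand_named(self):
        g = ConditionGraph(num_conditions=2, directed=True)
        g.add_edge("a", "b", 1.0, {1})
        inst = CSNInstance(graph=g, demands=[Demand("b", "a", 2)],
                           variant="edge")
        with pytest.raises(InfeasibleInstanceError) as exc:
            shortest_path_union(inst)
        assert exc.value.demand == Demand("b", "a", 2)

    @pytest.mark.parametrize("seed", range(10))
    def test_envelope_between_opt_and_k_opt(self, seed):
        inst = to_edge_variant(random_small_instance(seed)).instance
        opt = brute_force_opt(inst).cost
        spu = shortest_path_union(inst).cost
        k = inst.num_demands
        assert opt - 1e-9 <= spu <= k * opt + 1e-9


def hub_instance():
    """Hub at cost 10 serving four targets; direct arcs cost 9 each."""
    g = ConditionGraph(num_conditions=1, directed=True)
    g.add_edge("root", "x", 10.0, {1})
    for j in range(1, 5):
        g.add_edge("x", f"b{j}", 0.0, {1})
        g.add_edge("root", f"b{j}", 9.0, {1})
    return CSNInstance(graph=g,
                       demands=[Demand("root", f"b{j}", 1) for j in range(1, 5)],
                       variant="edge")


class TestCharikar:
    def test_single_demand_degenerates_to_shortest_path(self):
        from conftest import path_instance
        inst = path_instance(weights=(1.0, 2.0))
        sol = charikar_tree(inst, level=2)
        assert sol.cost == pytest.approx(3.0)

    def test_hub_beats_per_demand_routing(self):
        """Depth 2 finds the dense hub subtree the union of paths misses."""
        inst = hub_instance()
        assert shortest_path_union(inst).cost == pytest.approx(36.0)
        assert charikar_tree(inst, level=2).cost == pytest.approx(10.0)

    def test_star_worst_case_recovered(self):
        inst = star_worst_case(k=5, M=10.0, eps=0.01)
        assert charikar_tree(inst, level=2).cost == pytest.approx(10.0)

    def test_non_monotonic_rejected(self):
        g = ConditionGraph(num_conditions=2, directed=True)
        g.add_edge("a", "b", 1.0, {1})
        inst = CSNInstance(graph=g, demands=[Demand("a", "b", 1)],
                           variant="edge")
        from csnet.model import ConditionGraphError
        with pytest.raises(ConditionGraphError):
            charikar_tree(inst, level=2)

    @pytest.mark.parametrize("seed", range(10))
    def test_guarantee_against_oracle(self, seed):
        """cost <= i²(i-1) k^(1/i) · OPT at depth i=2, and always feasible."""
        inst = random_monotonic_instance(n=7, m=12, C=3, k=3, seed=seed)
        sol = charikar_tree(inst, level=2)
        assert is_feasible(sol, inst)
        opt = brute_force_opt(inst).cost
        k = len({(d.target, d.condition) for d in inst.demands})
        assert sol.cost <= 4.0 * math.sqrt(k) * opt + 1e-9

    @pytest.mark.parametrize("seed", range(8))
    def test_layered_recursion_equivalence(self, seed):
        """The recursion on the layered one-condition graph gives the same tree cost."""
        inst = random_monotonic_instance(n=6, m=11, C=3, k=3, seed=seed)
        t1 = charikar_closure_tree(inst, level=2)
        layered = monotonic_ssdcsn_to_dst(inst).instance
        t2 = charikar_closure_tree(layered, level=2)
        assert t1.cost == pytest.approx(t2.cost)

    def test_expansion_never_exceeds_tree_cost(self):
        inst = random_monotonic_instance(n=7, m=12, C=3, k=3, seed=4)
        closure = metric_closure(inst.graph)
        tree = charikar_closure_tree(inst, level=2, closure=closure)
        sol = expand_closure_tree(tree, closure, inst.graph)
        assert sol.cost <= tree.cost + 1e-9
        assert tree.density == pytest.approx(tree.cost / len(tree.covered))
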