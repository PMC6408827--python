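"""Strict reductions: construction shapes and exact optimum preservation."""

import pytest

from csnet.model import (
    INF,
    ConditionGraph,
    ConditionGraphError,
    CSNInstance,
    CSTInstance,
    Demand,
    PrioritySteinerInstance,
    is_feasible,
)
from csnet.reductions import (
    csn_to_csp,
    csp_to_cst,
    cst_to_cpcst,
    lift_dst_solution,
    monotonic_csn_to_priority,
    monotonic_cst_to_csn,
    monotonic_ssdcsn_to_dst,
    priority_to_monotonic_csn,
)
from csnet.generators import (
    random_cst_instance,
    random_monotonic_instance,
    random_small_instance,
)
from csnet.oracle import (
    brute_force_opt,
    brute_force_priority_opt,
    brute_force_tree_opt,
)


class TestCsnToCsp:
    def test_gadget_counts(self):
        """k demands: k conditions, 2 + 2k new vertices, 4k zero-weight edges."""
        g = ConditionGraph(num_conditions=2, directed=True)
        g.add_edge("a", "b", 1.0, {1, 2})
        g.add_edge("b", "c", 1.0, {1})
        g.add_edge("a", "c", 3.0, {2})
        inst = CSNInstance(
            graph=g,
            demands=[Demand("a", "b", 1), Demand("a", "c", 2),
                     Demand("b", "c", 1)],
            variant="edge")
        red = csn_to_csp(inst)
        produced = red.instance
        k = inst.num_demands
        assert produced.graph.num_conditions == k
        new_vertices = produced.graph.vertices - inst.graph.vertices
        assert len(new_vertices) == 2 + 2 * k
        zero = [e for e in produced.graph.edges
                if produced.graph.weight(e) == 0.0
                and e not in inst.graph.edges]
        assert len(zero) == 4 * k

    def test_single_demand_reduces_to_shortest_path(self):
        from conftest import path_instance
        inst = path_instance(weights=(1.0, 2.0, 0.5))
        red = csn_to_csp(inst)
        assert brute_force_opt(red.instance).cost == pytest.approx(3.5)

    @pytest.mark.parametrize("seed", range(6))
    def test_optimum_preserved(self, seed):
        inst = random_small_instance(seed, variant="edge")
        before = brute_force_opt(inst)
        red = csn_to_csp(inst)
        after = brute_force_opt(red.instance, edge_budget=25)
        assert before.cost == pytest.approx(after.cost)
        lifted = red.lift(after)
        assert lifted.cost == pytest.approx(after.cost)
        assert is_feasible(lifted, inst)


class TestCspToCst:
    def test_terminal_sets_are_the_common_pair(self):
        inst = random_small_instance(2, variant="edge", directed=False)
        csp = csn_to_csp(inst).instance
        red = csp_to_cst(csp)
        (a, b) = csp.demands[0].source, csp.demands[0].target
        for X in red.instance.terminal_sets:
            assert X == frozenset({a, b})

    def test_directed_input_rejected(self):
        inst = random_small_instance(4, variant="edge", directed=True)
        csp = csn_to_csp(inst).instance
        with pytest.raises(ConditionGraphError):
            csp_to_cst(csp)

    @pytest.mark.parametrize("seed", range(6))
    def test_optimum_preserved(self, seed):
        inst = random_small_instance(seed, variant="edge", directed=False)
        csp = csn_to_csp(inst).instance
        red = csp_to_cst(csp)
        a = brute_force_opt(csp, edge_budget=25).cost
        b = brute_force_tree_opt(red.instance).cost
        assert a == pytest.approx(b)


class TestCstToCpcst:
    def test_penalty_assignment(self):
        g = ConditionGraph(num_conditions=3, directed=False)
        g.add_edge("v", "w", 1.0, {1, 2, 3})
        cst = CSTInstance(graph=g, terminal_sets=[{"w"}, {"v", "w"}, {"w"}])
        cp = cst_to_cpcst(cst).instance
        assert cp.get_penalty("v", 2) == INF
        assert cp.get_penalty("v", 1) == 0.0
        assert cp.get_penalty("v", 3) == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_optimum_preserved_on_uniform_rooted_family(self, seed):
        """Exactness regime: all edges at all conditions, a shared root terminal.

        There both optima equal the Steiner tree on the union of terminals,
        and the infinite penalties are what pins every terminal in the tree.
        """
        cst = random_cst_instance(seed, shared_root=True,
                                  uniform_conditions=True)
        red = cst_to_cpcst(cst)
        a = brute_force_tree_opt(cst).cost
        b = brute_force_tree_opt(red.instance).cost
        assert a == pytest.approx(b)


class TestPriorityEquivalence:
    def test_earliest_condition_becomes_priority(self):
        g = ConditionGraph(num_conditions=3, directed=False)
        g.add_edge("a", "b", 1.0, {2, 3})
        inst = CSNInstance(graph=g, demands=[Demand("a", "b", 3)],
                           variant="edge")
        ps = monotonic_csn_to_priority(inst).instance
        assert ps.edges[0][3] == 2
        assert ps.demands[0] == ("a", "b", 3)

    def test_non_monotonic_rejected(self):
        g = ConditionGraph(num_conditions=3, directed=False)
        g.add_edge("a", "b", 1.0, {1, 3})
        inst = CSNInstance(graph=g, demands=[Demand("a", "b", 3)],
                           variant="edge")
        with pytest.raises(ConditionGraphError):
            monotonic_csn_to_priority(inst)

    def test_multiedge_split_in_half(self):
        """Parallel 4- and 6-weight edges become halves 2,2,3,3 with midpoints."""
        ps = PrioritySteinerInstance(
            vertices={"u", "v"},
            edges=[("u", "v", 4.0, 1), ("u", "v", 6.0, 2)],
            demands=[("u", "v", 2)])
        red = priority_to_monotonic_csn(ps)
        weights = sorted(red.instance.graph.weight(e)
                         for e in red.instance.graph.edges)
        assert weights == [2.0, 2.0, 3.0, 3.0]
        assert len(red.instance.graph.vertices) == 4  # u, v, two midpoints

    def test_simple_graph_not_split(self):
        ps = PrioritySteinerInstance(
            vertices={"u", "v", "w"},
            edges=[("u", "v", 4.0, 1), ("v", "w", 6.0, 2)],
            demands=[("u", "w", 2)])
        red = priority_to_monotonic_csn(ps)
        assert len(red.instance.graph.vertices) == 3

    @pytest.mark.parametrize("seed", range(6))
    def test_optimum_preserved_both_directions(self, seed):
        inst = random_monotonic_instance(n=6, m=10, C=3, k=2, seed=seed,
                                         directed=False, single_source=False)
        opt = brute_force_opt(inst).cost
        red = monotonic_csn_to_priority(inst)
        popt = brute_force_priority_opt(red.instance)
        assert popt.cost == pytest.approx(opt)
        lifted = red.lift(popt)
        assert lifted.cost == pytest.approx(opt)
        assert is_feasible(lifted, inst)

        back = priority_to_monotonic_csn(red.instance)
        opt2 = brute_force_opt(back.instance, edge_budget=25)
        assert opt2.cost == pytest.approx(opt)
        assert back.lift(opt2).cost == pytest.approx(opt)


class TestMonotonicCstToCsn:
    def test_anchor_and_demand_count(self):
        g = ConditionGraph(num_conditions=1, directed=False)
        for (u, v) in [("a", "b"), ("b", "d"), ("a", "d")]:
            g.add_edge(u, v, 1.0, {1})
        cst = CSTInstance(graph=g, terminal_sets=[{"a", "b", "d"}])
        red = monotonic_cst_to_csn(cst)
        assert set(red.instance.demands) == {Demand("a", "b", 1),
                                             Demand("a", "d", 1)}

    def test_singleton_terminal_set_yields_no_demand(self):
        g = ConditionGraph(num_conditions=2, directed=False)
        g.add_edge("a", "b", 1.0, {1, 2})
        cst = CSTInstance(graph=g, terminal_sets=[{"a", "b"}, {"a"}])
        red = monotonic_cst_to_csn(cst)
        assert all(d.condition == 1 for d in red.instance.demands)

    @pytest.mark.parametrize("seed", range(6))
    def test_optimum_preserved(self, seed):
        cst = random_cst_instance(seed, monotonic=True)
        a = brute_force_tree_opt(cst).cost
        red = monotonic_cst_to_csn(cst)
        b = brute_force_opt(red.instance).cost
        assert a == pytest.approx(b)


class TestLayeredDst:
    def test_layer_counts(self):
        """4 vertices, max condition 3: 12 copies, 2 vertical arcs per chain."""
        g = ConditionGraph(num_conditions=3, directed=True)
        g.add_edge("a", "b", 1.0, {1, 2, 3})
        g.add_edge("b", "c", 1.0, {2, 3})
        g.add_edge("c", "d", 1.0, {3})
        inst = CSNInstance(graph=g, demands=[Demand("a", "d", 3)],
                           variant="edge")
        red = monotonic_ssdcsn_to_dst(inst)
        lg = red.instance.graph
        assert len(lg.vertices) == 12
        vertical = [e for e in lg.edges if e[0][0] == e[1][0]]
        assert len(vertical) == 4 * 2
        assert Demand(("a", 1), ("d", 3), 1) in red.instance.demands

    def test_demand_maps_to_layer(self):
        g = ConditionGraph(num_conditions=2, directed=True)
        g.add_edge("a", "b", 1.0, {2})
        inst = CSNInstance(graph=g, demands=[Demand("a", "b", 2)],
                           variant="edge")
        red = monotonic_ssdcsn_to_dst(inst)
        assert red.instance.demands == (Demand(("a", 1), ("b", 2), 1),)

    def test_preconditions(self):
        g = ConditionGraph(num_conditions=2, directed=False)
        g.add_edge("a", "b", 1.0, {1, 2})
        inst = CSNInstance(graph=g, demands=[Demand("a", "b", 1)],
                           variant="edge")
        with pytest.raises(ConditionGraphError):
            monotonic_ssdcsn_to_dst(inst)  # undirected

    def test_lift_counts_shared_edge_once(self):
        from csnet.model import Solution
        g = ConditionGraph(num_conditions=2, directed=True)
        g.add_edge("a", "b", 2.0, {1, 2})
        inst = CSNInstance(graph=g,
                           demands=[Demand("a", "b", 1), Demand("a", "b", 2)],
                           variant="edge")
        red = monotonic_ssdcsn_to_dst(inst)
        lg = red.instance.graph
        tree = Solution(chosen_edges={(("a", 1), ("b", 1)),
                                      (("a", 1), ("a", 2)),
                                      (("a", 2), ("b", 2))},
                        cost=4.0)
        lifted = red.lift(tree)
        assert lifted.chosen_edges == frozenset({("a", "b")})
        assert lifted.cost == pytest.approx(2.0)  # strictly below tree cost

    @pytest.mark.parametrize("seed", range(6))
    def test_optimum_preserved(self, seed):
        inst = random_monotonic_instance(n=6, m=10, C=3, k=2, seed=seed)
        a = brute_force_opt(inst).cost
        red = monotonic_ssdcsn_to_dst(inst)
        b = brute_force_opt(red.instance, edge_budget=25).cost
        assert a == pytest.approx(b)
        lifted = red.lift(brute_force_opt(red.instance, edge_budget=25))
        assert lifted.cost <= b + 1e-9
        assert is_feasible(lifted, inst)
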