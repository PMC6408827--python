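"""Instance generators: gadget structure, worst cases, random samplers."""

import networkx as nx
import pytest

from csnet.model import (
    ConditionGraphError,
    Demand,
    frame,
    is_monotonic,
)
from csnet.generators import (
    KPHLCInstance,
    example1,
    kphlc_to_dcsn,
    label_cover_to_2dcsn,
    random_kphlc,
    random_label_cover,
    random_monotonic_instance,
    random_single_source_instance,
    random_small_instance,
    star_worst_case,
)
from csnet.oracle import brute_force_opt
from csnet.ilp import solve_csn


class TestExample1:
    def test_optimum_is_one(self):
        assert brute_force_opt(example1()).cost == pytest.approx(1.0)

    def test_demands(self):
        inst = example1()
        assert set(inst.demands) == {Demand("u1_S", "u2_S", 1),
                                     Demand("v1_S", "v2_S", 2)}

    def test_condition_frames_separate_sides(self):
        """Frame 1 is the u-side subgraph (plus merged contacts), frame 2 the v-side."""
        inst = example1()
        f1 = frame(inst.graph, 1)
        f2 = frame(inst.graph, 2)
        u_chain = {"u1_S", "u2_S"}
        v_chain = {"v1_S", "v2_S"}
        assert u_chain <= {n for e in f1.edges for n in e}
        assert not v_chain & {n for e in f1.edges for n in e}
        assert v_chain <= {n for e in f2.edges for n in e}

    def test_merged_contacts_exist_at_both_conditions(self):
        inst = example1()
        g = inst.graph
        merged = [e for e in g.edges
                  if g.weight(e) == 1.0 and len(g.exists_at(e)) == 2]
        assert len(merged) == 2  # (u:1,v:2) and (u:2,v:2) agreeing pairs


class TestLabelCoverGadget:
    def test_reproduces_worked_toy_shape(self):
        inst = example1()
        g = inst.graph
        contacts = [e for e in g.edges if g.weight(e) == 1.0]
        # u-side: 2 strands; v-side: lone strand for r=1 plus 2 merged paths
        assert len(contacts) == 3  # 2 merged + 1 lone
        assert len(g.edges) == 13

    def test_underlying_digraph_acyclic(self):
        for seed in range(4):
            lc = random_label_cover(seed=seed)
            inst = label_cover_to_2dcsn(lc)
            nxg = nx.DiGraph()
            nxg.add_edges_from(inst.graph.edges)
            assert nx.is_directed_acyclic_graph(nxg)

    def test_minimal_traversal_weight_is_edge_count(self):
        """Every source->sink path on the u-side pays one contact per constraint edge."""
        lc = random_label_cover(num_left=2, num_right=2, num_edges=3, seed=1)
        inst = label_cover_to_2dcsn(lc)
        f1 = frame(inst.graph, 1)
        for path in nx.all_simple_paths(f1, "u1_S", "u3_S"):
            w = sum(f1[a][b]["weight"] for a, b in zip(path, path[1:]))
            assert w == pytest.approx(len(lc.edges))

    def test_satisfiable_instances_reach_edge_count(self):
        lc = random_label_cover(num_edges=3, seed=3, satisfiable=True)
        inst = label_cover_to_2dcsn(lc)
        assert brute_force_opt(inst, edge_budget=25).cost == pytest.approx(3.0)

    def test_no_agreement_forbids_merging(self):
        lc = random_label_cover(num_left=1, num_right=1, num_edges=1,
                                seed=0, satisfiable=False,
                                unsatisfiable_edge=True)
        inst = label_cover_to_2dcsn(lc)
        assert brute_force_opt(inst, edge_budget=25).cost == pytest.approx(2.0)


class TestKphlcGadget:
    def test_strongly_satisfiable_optimum_is_hyperedge_count(self):
        ph = random_kphlc(k=3, num_hyperedges=2, seed=1,
                          strongly_satisfiable=True)
        inst = kphlc_to_dcsn(ph)
        assert inst.graph.num_conditions == 3
        assert brute_force_opt(inst, edge_budget=25).cost == pytest.approx(2.0)

    def test_no_agreement_pays_k_per_hyperedge(self):
        ph = random_kphlc(k=3, num_hyperedges=1, seed=0, no_agreement=True)
        inst = kphlc_to_dcsn(ph)
        assert brute_force_opt(inst, edge_budget=25).cost == pytest.approx(3.0)

    def test_acyclic(self):
        ph = random_kphlc(k=3, num_hyperedges=2, seed=2)
        inst = kphlc_to_dcsn(ph)
        nxg = nx.DiGraph()
        nxg.add_edges_from(inst.graph.edges)
        assert nx.is_directed_acyclic_graph(nxg)


class TestStarWorstCase:
    def test_construction(self):
        inst = star_worst_case(k=5, M=10.0, eps=0.01)
        g = inst.graph
        assert len(inst.demands) == 5
        assert g.weight("root", "hub") == 10.0
        assert g.weight("root", "t1") == pytest.approx(9.99)
        assert g.weight("hub", "t1") == 0.0

    def test_single_target_makes_direct_arc_optimal(self):
        inst = star_worst_case(k=1, M=10.0, eps=0.01)
        assert brute_force_opt(inst).cost == pytest.approx(9.99)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            star_worst_case(k=3, M=1.0, eps=2.0)


class TestRandomSingleSource:
    def test_deterministic_in_seed(self):
        a = random_single_source_instance(n=40, m=100, beta=3, C=3, p=0.3, seed=7)
        b = random_single_source_instance(n=40, m=100, beta=3, C=3, p=0.3, seed=7)
        assert a.graph.edges == b.graph.edges
        assert a.demands == b.demands
        assert a.node_exists_at == b.node_exists_at

    def test_p_one_activates_everything(self):
        inst = random_single_source_instance(n=30, m=80, beta=2, C=2, p=1.0,
                                             seed=3)
        C = inst.graph.num_conditions
        assert all(inst.node_exists_at[v] == set(range(1, C + 1))
                   for v in inst.node_exists_at)

    def test_p_zero_single_target_is_one_path(self):
        """With no background activity the active set is one shortest path."""
        inst = random_single_source_instance(n=30, m=80, beta=1, C=1, p=0.0,
                                             seed=5)
        sol = solve_csn(inst)
        from csnet.approx import shortest_path_union
        from csnet.variants import to_edge_variant
        spu = shortest_path_union(to_edge_variant(inst).instance)
        assert sol.cost == pytest.approx(spu.cost)

    def test_demands_feasible(self):
        inst = random_single_source_instance(n=40, m=110, beta=3, C=3, p=0.2,
                                             seed=11)
        sol = solve_csn(inst)
        assert getattr(sol, "status", None) == "optimal"

    def test_too_few_reachable_refused(self):
        with pytest.raises(ConditionGraphError, match="reachable"):
            random_single_source_instance(n=5, m=4, beta=10, C=1, p=0.5, seed=0)


class TestRandomMonotonic:
    @pytest.mark.parametrize("seed", range(5))
    def test_always_monotonic_and_feasible(self, seed):
        inst = random_monotonic_instance(n=7, m=12, C=3, k=3, seed=seed)
        assert is_monotonic(inst.graph)
        from csnet.approx import shortest_path_union
        sol = shortest_path_union(inst)  # raises if any demand is unroutable
        assert sol.cost >= 0.0

    def test_single_condition_is_classic_steiner(self):
        inst = random_monotonic_instance(n=6, m=10, C=1, k=2, seed=1)
        assert inst.graph.num_conditions == 1
        assert all(inst.graph.exists_at(e) == frozenset({1})
                   for e in inst.graph.edges)


def test_random_small_instance_shapes():
    directed = variants = 0
    for seed in range(30):
        inst = random_small_instance(seed)
        assert len(inst.graph.vertices) <= 8
        assert inst.num_demands >= 1
        directed += inst.graph.directed
        variants += inst.variant != "edge"
    assert 0 < directed < 30
    assert 0 < variants < 30
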