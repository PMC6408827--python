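"""Walk a small instance through the strict reduction chain.

Every reduction preserves the optimal objective exactly and comes with a
lifting procedure, so a solution of the produced instance maps back to a
feasible solution of the source of equal cost.
"""

from csnet.generators import random_small_instance
from csnet.model import is_feasible
from csnet.oracle import brute_force_opt, brute_force_tree_opt
from csnet.reductions import csn_to_csp, csp_to_cst

inst = random_small_instance(seed=4, variant="edge", directed=False)
print(f"source instance: {len(inst.graph.vertices)} vertices, "
      f"{len(inst.graph.edges)} edges, {inst.num_demands} demands, "
      f"C={inst.graph.num_conditions}")
opt = brute_force_opt(inst)
print(f"optimum: {opt.cost:.3f}")

step1 = csn_to_csp(inst)
csp = step1.instance
print(f"-> common-pair form: C={csp.graph.num_conditions} "
      f"(one condition per original demand)")
csp_opt = brute_force_opt(csp, edge_budget=25)
print(f"   optimum: {csp_opt.cost:.3f}")

step2 = csp_to_cst(csp)
cst_opt = brute_force_tree_opt(step2.instance)
print(f"-> terminal-pair (Steiner tree) form, optimum: {cst_opt.cost:.3f}")

lifted = step1.lift(csp_opt)
print(f"lifted back to the source: cost {lifted.cost:.3f}, "
      f"feasible: {is_feasible(lifted, inst)}")
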