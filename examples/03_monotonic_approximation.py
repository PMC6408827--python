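"""Approximation algorithms on a worst case for per-demand routing.

The hub-and-spokes instance gives each of k targets a direct arc slightly
cheaper than the hub route, so routing every demand separately costs almost
k times the optimum.  The density-driven recursive greedy (depth 2) finds
the hub and recovers the optimum.
"""

from csnet.approx import charikar_tree, shortest_path_union
from csnet.generators import star_worst_case
from csnet.oracle import brute_force_opt

inst = star_worst_case(k=5, M=10.0, eps=0.01)
spu = shortest_path_union(inst)
greedy = charikar_tree(inst, level=2)
opt = brute_force_opt(inst)

print(f"k = {inst.num_demands} demands, hub cost M = 10, direct arcs 9.99")
print(f"union of shortest paths: {spu.cost:.2f}  "
      f"(ratio {spu.cost / opt.cost:.2f} — the k-approximation's worst case)")
print(f"recursive greedy (depth 2): {greedy.cost:.2f}")
print(f"exact optimum: {opt.cost:.2f}")
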