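"""Solve the worked two-condition toy with both exact solvers.

The instance is produced by the label-cover gadget: two chains of bundles
(one per condition) whose agreeing label pairs share merged unit-weight
contact edges.  Because one contact edge serves both conditions, the optimum
is 1 — half of what solving each condition separately would pay.
"""

from csnet.generators import example1
from csnet.ilp import solve_csn
from csnet.model import CSNInstance
from csnet.oracle import brute_force_opt

inst = example1()
print(f"instance: {len(inst.graph.vertices)} vertices, "
      f"{len(inst.graph.edges)} edges, {inst.graph.num_conditions} conditions")
for d in inst.demands:
    print(f"  demand: {d.source} -> {d.target} at condition {d.condition}")

oracle = brute_force_opt(inst)
ilp = solve_csn(inst)
print(f"brute-force optimum: {oracle.cost:.1f}")
print(f"flow-ILP optimum:    {ilp.cost:.1f}  (status {ilp.status})")

per_condition = sum(
    brute_force_opt(CSNInstance(graph=inst.graph, demands=[d],
                                variant="edge")).cost
    for d in inst.demands)
print(f"solving each condition separately costs {per_condition:.1f} — "
      "the shared contact edge halves it")
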