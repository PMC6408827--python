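# Methods

## Problem model

A *condition graph* is a sequence `G_1=(V,E_1), …, G_C=(V,E_C)` over one
vertex set; the underlying graph is `G=(V, E=⋃_c E_c)` with a weight
`w(e) ≥ 0` per underlying edge.  Conditions are 1-based integers.  A demand
`(a, b, c)` is satisfied by a subgraph `H ⊆ G` if `H` contains an `a`–`b`
path (directed when the graph is directed) whose edges all exist at
condition `c`.  Cost counts each underlying edge once; this is the source
of all the problem's extra difficulty relative to classic Steiner network —
good solutions share edges across conditions.

Three formulations are supported.  In the *edge* variant each edge carries
its own condition set; in the *node* variant vertices carry condition sets
and an edge exists exactly when both endpoints do; the *node-and-edge*
variant constrains edge sets to the induced ones.  The conversions (midpoint
node carrying the edge's condition set; intersection of endpoint sets) are
strict — they preserve the optimum exactly — and every solver first
normalizes to the edge variant, lifting solutions back so callers never see
gadget nodes.  An instance may lack a demand at some condition; this is
accepted with a warning since every algorithm remains well defined.

Undirected edges are stored canonically (endpoints ordered by `repr`);
parallel edges are disallowed everywhere except the priority-Steiner
multigraph type.  Infinite prize-collecting penalties use `math.inf`
directly rather than a big-M constant so cost arithmetic stays exact.

## Flow ILP

For single-source directed instances the solver builds one binary `d_uv`
per underlying edge and one continuous flow variable `d_uvc ∈ [0, k_c]` per
arc/condition pair with the arc alive at `c`, where `k_c` is the number of
demands at condition `c`.  Constraints: linking `d_uvc ≤ k_c·d_uv` (the
`k_c` factor is required — with a unit cap, `k_c > 1` units could not leave
the source through one edge) and flow conservation with right-hand side
`δ_vc` (`+1` per demand targeting `v` at `c`, `−k_c` at the source, 0
otherwise; duplicate targets aggregate).  Objective `Σ w(e)·d_e`.

Flows stay continuous: any feasible fractional flow within the selected
subgraph certifies, by conservation, that each demanded target is reachable
from the source there, so integral flows add nothing but branching work.
Undirected instances are bidirected inside the model builder with one
binary gating both orientations, charged once.  Multi-source instances are
first reduced to the common-source/common-sink form (below).  Demands whose
targets are individually unreachable are detected before model building and
reported by name.

The backend is HiGHS through `scipy.optimize.milp` — deterministic and
single-threaded, which keeps regression tests reproducible.  Selected edges
carrying zero flow at every condition are pruned before costing; a
default time limit of 600 s surfaces a `timeout`/`feasible` status rather
than silently truncating.

## Reductions

All reductions return the produced instance plus a lifting procedure, and
preserve the optimum exactly:

- **CSN → common-pair form (CSP)**: one new condition per demand `i`; an
  original edge exists at `i` iff it existed at the demand's condition;
  four zero-weight gadget edges thread a global source/sink through the
  demand's endpoints at condition `i` only.  Gadget vertices are named
  `SRC`, `SNK`, `x{i}`, `y{i}` with collision-avoidance suffixes.
- **CSP → condition Steiner tree (CST)**: terminal sets `{a, b}` at each
  demanded condition (a singleton `{a}` at undemanded conditions, which is
  vacuous).
- **CST → prize-collecting (CPCST)**: penalty `∞` for terminals at their
  conditions, 0 elsewhere.  Note the prize-collecting objective scores a
  *tree* against omitted vertices only — it has no per-condition
  connectivity requirement — so this encoding is exact on instance families
  whose Steiner-tree optimum is itself a tree covering all terminals, e.g.
  every edge alive at all conditions with terminal sets sharing a root.
  On general condition-varying instances the two optima can genuinely
  differ (per-condition paths between the same terminals can force a cycle
  that no tree matches), and the equality tests draw from the exact regime.
- **Monotonic CSN ↔ priority Steiner tree**: the earliest existence
  condition becomes the edge's priority; in the reverse direction parallel
  multiedges split into two half-weight edges joined at a midpoint, both
  halves keeping the original priority, and lifting contracts the splits.
- **Monotonic CST → monotonic CSN**: per condition, the lexicographically
  smallest terminal anchors `|X_c|−1` demands (any anchor works;
  determinism aids testing).
- **Monotonic single-source directed CSN → directed Steiner tree**: a
  layered graph with one copy of `V` per condition up to the largest
  demanded one, within-layer arcs for each edge alive at that layer, and
  zero-weight vertical arcs; demand `(a,b,c)` becomes `(a¹, bᶜ)`.  Lifting
  projects within-layer arcs back and counts a multiply-used underlying
  edge once, so the projected cost never exceeds the tree cost.

Demand conditions of single-source instances are processed in sorted order.

## Approximation algorithms

*Union of shortest paths*: one shortest path per demand in its frame,
deduplicated.  Always within `k` of the optimum, and the
`star_worst_case` generator realizes the ratio `k(M−ε)/M`.

*Recursive greedy on the closure*: the metric closure stores `w̃(u,v,c)`,
the shortest `u→v` distance within frame `c`.  The algorithm runs on
states `(vertex, condition)` with arcs priced at the head's condition and
conditions nondecreasing along every root-to-leaf path (sound by
monotonicity: an edge alive at `c` is alive at every later condition).
Depth 1 connects the current root directly to its `k'` nearest uncovered
targets; depth `i` repeatedly chooses, over all intermediate states and
subtree sizes, the depth-`(i−1)` subtree plus entry arc of minimum density
(cost per newly covered demand), giving the classic `i²(i−1)·k^{1/i}`
guarantee for `i ≥ 2` in time `O(n^i k^{2i})`.  Running the identical
recursion on the layered time-expanded graph produces the same tree cost;
the test suite asserts this equivalence exactly, which pins down otherwise
arbitrary choices:

- ties in density minimization break lexicographically on
  (density, cost, vertex key, condition), with a vertex key that orders
  layered tuples the same way as (vertex, condition) pairs;
- memoization of subtree calls is scoped to one top-level invocation.

Unreachable demands are reported before recursion starts, since the
guarantee is vacuous on infeasible inputs.  Closure trees are expanded to
concrete subgraphs by replacing each arc with a recovered shortest path;
the union counts shared edges once, so expansion never raises the cost.
Path recovery uses a deterministic Dijkstra whose parent for each vertex is
chosen, at finalization time, as the smallest already-finalized neighbor
attaining its distance — finalization order makes the parent forest acyclic
even across zero-weight ties (a naive backward reconstruction can cycle on
the gadgets' zero-weight edges).

## Exact oracles

Small instances are solved by lazy cheapest-first enumeration of edge
subsets (a heap over the subset lattice with append/replace successors, so
sets arrive in nondecreasing weight and the first feasible one is optimal).
Zero-weight edges ride along for free and only positively weighted edges
are enumerated — essential for the gadget instances, which are mostly
zero-weight plumbing.  Enumeration is further restricted to edges on at
least one demand-relevant path, which cannot exclude any witness path.  The
budget (default 20 weighted edges) triggers refusal, never silent
approximation.  The prize-collecting oracle enumerates subtrees (including
single-vertex and empty trees) because its objective is tree-shaped; the
condition-Steiner-tree oracle deliberately enumerates arbitrary subsets,
since that optimum can be a cycle.  Reported optima are pruned to the union
of witness paths, which provably has the same cost.

## Synthetic data

The PPI-style sampler emulates how condition-specific signaling instances
are drawn from a reference interaction network.  Base topology: a random
out-tree from the root plus degree-proportional extra arcs (a
preferential-attachment-flavoured skew mimicking PPI hubs); weights are
`−log` of pseudo-confidences drawn uniformly from (0.5, 0.99), so weights
lie in roughly (0.01, 0.69) and minimizing weight maximizes confidence.
The study conditions are the sampler's defaults as used in the simulation
test: `n=500` vertices, `m=3000` arcs, `β=10` targets per condition,
`C=10` conditions, inclusion probability `p=0.25` — a desk-scale version
of a full PPI screen (tens of thousands of nodes), chosen so the whole
study solves in seconds while keeping hundreds of active vertices per
condition.  Per condition, `β` targets are sampled without replacement
(independently across conditions; a `replace` flag exposes the
alternative), vertices on the deterministic shortest path to a target are
active, and every other vertex is active with probability `p`.  One
shortest path per target is used, with lexicographic tie-breaking, since
"the" shortest path is otherwise ambiguous.

What the generator does *not* model: curated edge directions mixed with
bidirected unscored edges, condition-correlated activity, measurement
noise in confidences, and the heavy right tail of real PPI degree
distributions.  Passing tests therefore show correctness of the algorithms
under a plausible topology and weight regime, not biological fidelity.

The monotonic generator assigns each edge a uniform birth condition
(monotone by construction) and samples demands verified reachable at their
conditions.  The label-cover generator plants a satisfying labeling for
satisfiable instances and emits non-crossing "staircase" constraint edges
by default: a crossing pair of constraint edges whose contact edges both
merge necessarily creates a directed cycle through the two chains, so the
acyclicity of the gadget output is only guaranteed (and only asserted) in
the non-crossing regime.  The hypergraph gadget's parallel 1-regular
hyperedges are always non-crossing.  All generators are pure functions of
their parameters and seed.

## Numerical choices and degenerate inputs

Weights are floats; feasibility and optimality comparisons use absolute
tolerances of 1e-9 (1e-12 within shortest-path tie detection).  Flow
variables below 1e-6 count as zero when pruning.  Vertices are opaque
hashables compared by `repr` for canonical storage; gadget and layered
vertices use structured tuples/strings for debuggability.  Empty condition
sets, negative weights, self-loops, duplicate edges, and out-of-range
conditions are rejected at construction.  Nodes without incident
constraints in the label-cover gadget contribute a zero-weight bridge
(their labeling is unconstrained).

## Known limitations

- The ILP solves the prize-collecting variant not at all (by design; the
  framework covers the path-connectivity problems only).
- The priority-Steiner solver is the small-instance oracle; no `O(log k)`
  approximation for priority Steiner tree is included — only the
  transformations to and from it.
- The recursive greedy is exponential in the recursion depth and meant for
  small/medium monotonic instances; depth 2 is the practical default.
- Oracles refuse beyond ~20 weighted edges; they are validation tools, not
  solvers.
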