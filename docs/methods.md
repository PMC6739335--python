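# Methods

## Model and semantics

A network is a tuple of named nodes with one Boolean update rule each,
applied synchronously: the successor of state S assigns every node the
value of its rule on S. States are unsigned integers, node 0 at the
least-significant bit; all modules share this encoding. Rules are stored
as truth tables over their *essential* inputs — inputs the function's
value actually depends on — so the edge set reflects functional, not
syntactic, dependence. This pruning happens at parse time and matters:
the structural classifications below are topological, and a spurious
syntactic edge (e.g. `B & !B`) would wrongly block peeling.

Attractors are cycles of the successor map, found by exact
visited-state hashing (transients in these models are short, and
exactness matters more than the constant-factor savings of
Floyd/Brent). Cycles are canonicalized by rotating to the minimal
integer encoding, which is unique because cycle states are distinct.
For n ≤ 22 the whole state space is classified at once: the successor
array is built vectorized, pointer doubling (n+1 squarings) lands every
state on its cycle, and basin sizes come from a bincount.

## Structural reductions

**Symmetric peeling.** A node of outdegree 0 regulates nothing, so for
any basin state the state with that node flipped is also a basin state:
the basin is a product of the reduced basin and {0,1}^{n_sym}, and every
peeled node has basin marginal exactly 0.5. Peeling repeats until no
outdegree-0 node remains; self-loops count toward outdegree, so a
self-regulating node never peels. The per-round order is recorded for
reporting, but downstream computation needs only the set (which is
order-independent; tested by randomized removal orders).

**Deterministic nodes.** On the core, x is deterministic when some node
y of indegree 1 has x as sole essential input through an *invertible*
rule — identity or negation. Then y(t+1) forces x(t) = f⁻¹(y(t+1)). An
indegree-1 node with a constant rule (only possible before pruning)
forces nothing and confers no deterministic status; this invertibility
restriction resolves a case the source material leaves open. When a
deterministic source feeds several indegree-1 targets, the first in node
order is the designated primary inverse; the others are consistency
checks.

## Backward basin search

Layer 1 is the (projected) attractor state; layer ℓ+1 is the exact
preimage of layer ℓ. For a core state S at time t+1:

* deterministic coordinates of any predecessor are forced by inversion;
  if two targets of the same source force contradictory values, S is
  *terminal* (no preimage) — first sufficient condition;
* a nondeterministic node with deterministic inputs whose value in S is
  unattainable for every setting of its nondeterministic inputs (exact
  truth-table restriction) also proves S terminal — second condition;
* otherwise the remaining system f_v(x) = S_v is solved by
  most-constrained-first branching with unit propagation. Variables no
  constraint touches stay wildcard, so solutions emerge as {0,1,*}
  cubes. Branching on variable values keeps sibling solution cubes
  disjoint by construction.

The terminal conditions are sufficient, not necessary; they only skip
work. A state they miss whose preimage is empty simply contributes no
new layer — exactness never depends on them.

Local basins (one per attractor state) exclude attractor states from
expansion, which keeps them pairwise disjoint; their union is the
reduced basin, and the full basin is its lift by 2^{n_sym}. Cube sets
stay pairwise disjoint by on-insert orthogonal subtraction, so the exact
count is a plain sum of cube sizes (python integers, no precision
loss), and global deduplication falls out for free: only genuinely new
cube pieces are expanded further. A configurable cap on stored cubes
(default 200 000) aborts exact mode with a pointer to the Monte-Carlo /
forward-search path; basins of ~50-node networks are cluster-scale, not
desk-scale.

## Control target identification

Against one basin, nodes partition into symmetric (structurally peeled
plus any core node under whose *individual* flip the cube set is closed
— the stronger of the two possible readings, verified at set level;
failures fall back to unfixed), fixed (column constant across all
cubes), and unfixed. For an undesired state α:

* ρ_fixed = number of fixed nodes where α disagrees with v_fixed
  (mandatory flips);
* ρ_unfixed = min over cubes of the mismatch count on specified unfixed
  coordinates (wildcards free). The linear scan over disjoint cubes is
  already exact at desk scale, so no branch-and-bound is layered on it;
* mHD = ρ_fixed + ρ_unfixed, 0 iff α is in the basin.

Every cube achieving ρ_unfixed contributes one target set (its mismatch
positions, flipped to the cube's values) on top of the mandatory fixed
flips; no other flip set of size mHD can land in the basin, because a
landing state lies in some cube whose mismatch set it must equal. Target
sets are deduplicated; boundary states (α with a target set applied) are
reported exhaustively up to a configurable cap (default 10⁴) alongside
the exact total. Distance to a union of desired basins is the minimum
over members, so union control pools the target sets of all minimizing
basins and is monotone: more desired attractors never increase mHD.

The forward-search mode (`large_basin_control_search`) needs no basin:
it walks flip sets of size 0,1,2,… over a caller-restricted candidate
set (case studies exclude inputs, outputs, conceptual nodes and known
persistent targets), simulates each flipped state, and stops at the
first size that converges to a desired attractor. On small networks it
provably returns the same mHD and sets as the exact method.

## Temporary vs persistent interventions

A temporary perturbation overwrites the target values once and evolves
freely; nothing else is ever touched. Persistent clamping replaces the
targets' rules by constants; the *fixation cascade* records which free
nodes become constant at each subsequent state (decided by exact
truth-table restriction, given everything fixed so far). The cascade is
monotone and closes in at most n stages; when it pins all nodes its
final state is a fixed point of the clamped network. Because published
counts are stated once as states and once as transitions (off by one:
the clamped pattern is itself the 1st state), both `total_states` and
`total_transitions` are reported.

The interruption experiment clamps for k transitions, releases, evolves
freely, and scores convergence to the desired attractor over a seeded
random sample, with binomial standard errors. k = 0 means no
intervention at all, so it estimates the unperturbed desired-basin
fraction; success is non-decreasing in k up to sampling noise.

## Monte-Carlo landscape

Initial states are drawn uniformly over the sampled network's nodes —
clamped models are constant-propagated first, so sampling ranges over
free nodes only (the distribution of "randomly selected states" is not
otherwise specified; uniform is assumed). Convergence is vectorized
Floyd cycle detection over the whole batch; meeting states are pooled
into canonical attractors. Ratios carry SE = sqrt(p(1−p)/n). Attractors
are pooled by exact canonical form, never by similarity. Phenotype
conditions (node=value, constant over all attractor states) label
attractors desired / undesired / other; rejection sampling draws states
of a requested polarity with an attempt cap. Pearson correlations
between per-node |V_undesired − V_desired| and control-target inclusion
probability use the t-transform p-value, with no multiple-testing
correction (single planned pair).

## Synthetic fixtures and what they show

The generator plants an outdegree-0 chain of configurable length on top
of a random core (defaults: k_max = 3, p_deterministic = 0.3 giving a
realistic share of indegree-1 links, n_peelable = 2), guaranteeing
peelable structure, deterministic sources, and nontrivial basins — the
features the algorithms exploit. Random truth tables are non-constant by
construction. These fixtures exercise every code path and allow exact
brute-force cross-checks at n ≤ 14, but they do not reproduce the long
transient times, canalizing logic, or modular topology of curated
biological models; passing tests certify algorithmic exactness, not
biological calibration. Problem sizes used throughout the suite and the
acceptance script (hundreds of networks at n = 8…14, 10⁵ Monte-Carlo
samples) were chosen so the whole battery runs in seconds on one core
while still covering the regimes where exhaustive oracles exist.

The bundled `toy_synthetic` model is a reconstruction found by
randomized search under the complete list of published constraints on
the toy walkthrough network (peel order, attractor, terminal state,
unique boundary state, fixed/unfixed decomposition, deterministic
structure); the original supplementary rule listing is not distributed.
The large case-study models load from user-supplied transcriptions by
registered name with documented clamp presets; node-name case
differences between figures and listings are normalized and the mapping
recorded.

## Known limitations

* Exact mode is bounded by the cube cap; very large cores need the
  forward/Monte-Carlo path.
* Only synchronous deterministic dynamics; no asynchronous or
  probabilistic schemes, no SBML-qual import.
* Peeling is the only structural reduction (no mediator or input-layer
  collapsing).
* Boundary selection ignores stochastic flip robustness; a boundary
  state adjacent to the basin's complement may be fragile under noise.
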