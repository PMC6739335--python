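# brcnet — boundary-reaching control of synchronous Boolean networks

Cell phenotypes are commonly modelled as attractors of a Boolean
regulatory network G(V, E, F): each molecule is a node with a logical
update rule, all nodes update synchronously, and every initial state
eventually falls into a cyclic attractor whose basin of attraction
partitions the 2^n state space. A central therapeutic question is how to
move a cell out of an undesired attractor (say, proliferation) into a
desired one (say, apoptosis) with the *smallest, one-time* intervention —
rather than clamping targets indefinitely, which risks resistance,
side-effects, and distortion of the attractor landscape itself.

`brcnet` implements boundary-reaching control (BRC): perturb an
undesired state α just far enough to cross onto the *boundary* of the
desired attractor's basin, after which the network converges on its own.
That requires two computations this package provides exactly:

1. **Exact basin of attraction** of an attractor β = [S₁ … S_c], by
   hierarchical backward search. Nodes of outdegree 0 ("symmetric"
   nodes) are peeled iteratively — basins are closed under flipping
   them, so the basin factorizes as (reduced basin) × 2^{n_sym}. On the
   remaining core, any node x that is the sole input of an indegree-1
   node y with invertible rule is *deterministic*: x(t) = f⁻¹(y(t+1)).
   Layer ℓ+1 of the basin is the exact preimage of layer ℓ, computed by
   rule inversion for deterministic coordinates and constraint solving
   (with wildcard cubes over {0,1,*} for don't-care coordinates) for the
   rest; sufficient conditions detect *terminal* basin states with
   provably empty preimage and prune the search. Counts are exact,
   arbitrary-precision.
2. **Minimum control target sets.** Basin nodes split into symmetric
   (cost 0), fixed (constant value v_fixed over the basin; every
   disagreement with α is a mandatory flip, ρ_fixed of them) and unfixed
   (cheapest completion ρ_unfixed over all basin members). The minimum
   Hamming distance is mHD = ρ_fixed + ρ_unfixed, and all minimum target
   sets and boundary states are enumerated. When the desired basin
   covers most of the state space, the same sets are found without the
   exact basin, by breadth-first search over flip sets with forward
   simulation.

The package also compares temporary against persistent interventions
(persistent clamping spreads through the network as a stage-wise
*fixation cascade*, and interrupting it too early loses the control
goal) and estimates attractor landscapes by seeded Monte-Carlo sampling.

## Worked example

A bundled 7-node model (`toy_synthetic`, nodes A…G; a synthetic
reconstruction of a published walkthrough network) has a desired
fixed-point attractor β = (A…G) = (1,0,1,1,1,1,0). The undesired state
α = (0,0,0,0,1,0,0) converges elsewhere. BRC finds the minimal one-time
intervention:

```sh
brc control --network toy_synthetic --alpha 0000100 --attractor-state 1011110
```

```json
{
  "alpha": "0000100",
  "found": true,
  "mhd": 1,
  "rho_fixed": 1,
  "rho_unfixed": 0,
  "n_target_sets": 1,
  "target_sets": [ { "C": 1 } ],
  "n_boundary_total": 1,
  "boundary_states": [ "0010100" ]
}
```

Reading: G and F peel as symmetric nodes; over the reduced basin C is
fixed at 1 while A, B, D, E are unfixed. α disagrees with the basin only
on C (ρ_fixed = 1, ρ_unfixed = 0), so mHD = 1: flipping C to 1 once
moves α to the boundary state (0,0,1,0,1,0,0), which then converges to β
with no further intervention. `brc basin --network toy_synthetic --state
1011110` reports the exact basin size 20 (out of 2^7 = 128), divisible
by 2^{n_sym} = 4 as the symmetry demands.

Other entry points: `brc attractors` (exhaustive census, n ≤ 22),
`brc landscape` (Monte-Carlo basin ratios), `brc compare` (temporary vs
persistent perturbation, fixation cascade, interruption curves),
`brc generate` (random fixtures with planted peelable chains), and the
`brcnet` Python API mirroring all of it.

Case-study rule sets from the literature are loaded by name
(`cacc21`, `cacc49`, `tcell54`, `mapk33`) once transcribed into the
`.bnet`-style dialect from their supplementary listings; each name
applies its documented clamp preset (e.g. DC = APC = ON for the 70-node
colon-cancer network, which fixes 21 nodes and leaves the 49-node free
subnetwork).

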