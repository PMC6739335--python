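"""Random Boolean network generation with controllable structure.

Generated networks plant an outdegree-0 chain (guaranteeing a known
number of peelable symmetric nodes) on top of a random core, so every
algorithm in the package — peeling, deterministic classification,
backward basin search, control — can be exercised and cross-checked
against brute force without any externally transcribed model.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .network import BooleanNetwork, Rule

__all__ = ["GeneratorSpec", "random_boolean_network"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the random-network generator.

    n            total node count
    k_max        maximum rule indegree (sampled 1..k_max per node)
    p_deterministic  probability a core node gets an indegree-1
                 copy/negation rule (these create deterministic sources)
    n_peelable   length of the planted outdegree-0 chain; the first chain
                 node has outdegree 0, each next one feeds only its
                 predecessor, so peeling removes at least this many nodes
    seed         RNG seed; identical specs reproduce identical networks
    """

    n: int
    k_max: int = 3
    p_deterministic: float = 0.3
    n_peelable: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 nodes")
        if not 1 <= self.k_max < self.n:
            raise ValueError("require 1 ≤ k_max < n")
        if not 0 <= self.n_peelable < self.n:
            raise ValueError("require 0 ≤ n_peelable < n")
        if not 0.0 <= self.p_deterministic <= 1.0:
            raise ValueError("p_deterministic must be in [0, 1]")


def random_boolean_network(spec: GeneratorSpec) -> BooleanNetwork:
    """Sample a network according to ``spec`` (seeded, reproducible).

    Core nodes (indices 0..n_core-1) read random subsets of the core;
    chain node j reads chain node j+1 (last chain node reads a core
    node), and nothing reads chain node 0 — so the whole chain peels.
    Non-constant tables are enforced so every sampled input stays
    essential with positive probability; rules are pruned on
    construction as usual.
    """
    rng = random.Random(spec.seed)
    n_core = spec.n - spec.n_peelable
    names = tuple(f"n{i:02d}" for i in range(n_core)) + tuple(
        f"chain{j}" for j in range(spec.n_peelable)
    )
    rules: list[Rule] = []
    core_pool = list(range(n_core))
    for i in range(n_core):
        if rng.random() < spec.p_deterministic:
            src = rng.choice(core_pool)
            rules.append(Rule((src,), rng.choice((0b10, 0b01))))
            continue
        k = rng.randint(1, min(spec.k_max, n_core))
        inputs = tuple(sorted(rng.sample(core_pool, k)))
        table = rng.randrange(1, (1 << (1 << k)) - 1)  # non-constant
        rules.append(Rule(inputs, table))
    for j in range(spec.n_peelable):
        # chain j reads chain j+1; the last chain node reads the core
        if j + 1 < spec.n_peelable:
            src = n_core + j + 1
        else:
            src = rng.randrange(n_core)
        rules.append(Rule((src,), rng.choice((0b10, 0b01))))
    return BooleanNetwork(names, tuple(rules))
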