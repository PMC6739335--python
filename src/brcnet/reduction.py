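"""Structural node classifications feeding the backward basin search.

Two orthogonal classifications:

* *Symmetric* (a.k.a. independent) nodes: iteratively peel every node of
  outdegree 0.  Such a node regulates nothing, so the basin of any
  attractor is closed under flipping its value — its basin marginal mean
  is exactly 0.5 and it can be dropped before backward search, then
  restored by a 2^n_sym lift.  Self-loops count toward outdegree, so a
  self-regulating node is never peeled.

* On the remaining core, a node is *deterministic* if some core node of
  indegree 1 has it as sole essential input through an invertible rule
  (identity or negation): that target's value at time t+1 then forces the
  source's value at time t.  An indegree-1 node with a constant rule
  forces nothing and confers no deterministic status.  Everything else is
  nondeterministic; nondeterministic nodes with at least one
  deterministic input support an extra terminal-state test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

from .network import Attractor, BooleanNetwork, Rule

__all__ = [
    "NodeClassification",
    "peel_symmetric_nodes",
    "classify_deterministic",
    "classify_network",
    "project_attractor",
]


@dataclass(frozen=True)
class NodeClassification:
    """Peeling and deterministic/nondeterministic partition of a network.

    ``peel_rounds`` lists, per peeling round, the node names removed in
    that round; ``core`` is the induced subnetwork with no outdegree-0
    node.  ``deterministic`` / ``nondeterministic`` partition the core;
    ``nondet_with_det_input`` is the subset of nondeterministic core
    nodes reading at least one deterministic node.
    """

    network: BooleanNetwork
    peel_rounds: tuple[tuple[str, ...], ...]
    core: BooleanNetwork
    deterministic: tuple[str, ...]
    nondeterministic: tuple[str, ...]
    nondet_with_det_input: tuple[str, ...]

    @property
    def symmetric_nodes(self) -> tuple[str, ...]:
        return tuple(name for rnd in self.peel_rounds for name in rnd)

    @property
    def n_sym(self) -> int:
        return sum(len(r) for r in self.peel_rounds)

    def category(self, name: str) -> str:
        for k, rnd in enumerate(self.peel_rounds, start=1):
            if name in rnd:
                return f"symmetric(round {k})"
        if name in self.deterministic:
            return "deterministic"
        if name in self.nondet_with_det_input:
            return "nondeterministic-with-det-input"
        if name in self.nondeterministic:
            return "nondeterministic"
        raise KeyError(f"unknown node {name!r}")

    def report(self) -> str:
        """JSON classification report, one category per node."""
        return json.dumps(
            {name: self.category(name) for name in self.network.nodes}, indent=2
        )


def _subnetwork(net: BooleanNetwork, keep: Sequence[int]) -> BooleanNetwork:
    index_map = {old: new for new, old in enumerate(keep)}
    rules = []
    for i in keep:
        r = net.rules[i]
        # peeled nodes had outdegree 0, so every input of a kept rule survives
        rules.append(r.remap(index_map))
    return BooleanNetwork(tuple(net.nodes[i] for i in keep), tuple(rules))


def peel_symmetric_nodes(
    net: BooleanNetwork,
) -> tuple[tuple[tuple[str, ...], ...], BooleanNetwork]:
    """Iteratively remove outdegree-0 nodes until none remain.

    Returns the per-round peel order and the core subnetwork (possibly
    empty, e.g. for a pure feed-forward cascade).  The result does not
    depend on removal order within a round.
    """
    alive = list(range(net.n))
    rounds: list[tuple[str, ...]] = []
    while True:
        alive_set = set(alive)
        outdeg = {i: 0 for i in alive}
        for t in alive:
            for src in net.rules[t].inputs:
                if src in alive_set:
                    outdeg[src] += 1
        removed = [i for i in alive if outdeg[i] == 0]
        if not removed:
            break
        rounds.append(tuple(net.nodes[i] for i in removed))
        alive = [i for i in alive if outdeg[i] != 0]
    return tuple(rounds), _subnetwork(net, alive)


_INVERTIBLE_TABLES = {0b10: "identity", 0b01: "negation"}


def invertible_targets(core: BooleanNetwork) -> dict[int, list[int]]:
    """Map core node index -> indegree-1 targets with an invertible rule.

    Only identity and negation qualify; a constant rule of an indegree-1
    node (possible only pre-pruning) forces nothing.
    """
    out: dict[int, list[int]] = {}
    for t, r in enumerate(core.rules):
        if len(r.inputs) == 1 and r.table in _INVERTIBLE_TABLES:
            out.setdefault(r.inputs[0], []).append(t)
    return out


def classify_deterministic(
    core: BooleanNetwork,
) -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
    """Split core nodes into deterministic / nondeterministic sets."""
    det_idx = set(invertible_targets(core))
    det = tuple(n for i, n in enumerate(core.nodes) if i in det_idx)
    nondet = tuple(n for i, n in enumerate(core.nodes) if i not in det_idx)
    nondet_inputdet = tuple(
        core.nodes[i]
        for i in range(core.n)
        if i not in det_idx
        and any(src in det_idx for src in core.rules[i].inputs)
    )
    return det, nondet, nondet_inputdet


def classify_network(net: BooleanNetwork) -> NodeClassification:
    """Full classification: peel, then partition the core."""
    rounds, core = peel_symmetric_nodes(net)
    det, nondet, nondet_inputdet = classify_deterministic(core)
    return NodeClassification(
        network=net,
        peel_rounds=rounds,
        core=core,
        deterministic=det,
        nondeterministic=nondet,
        nondet_with_det_input=nondet_inputdet,
    )


def project_state(net: BooleanNetwork, core: BooleanNetwork, state: int) -> int:
    """Drop symmetric-node coordinates from a full-network state."""
    s = 0
    for j, name in enumerate(core.nodes):
        s |= ((state >> net.index(name)) & 1) << j
    return s


def project_attractor(
    attractor: Attractor, classification: NodeClassification
) -> Attractor:
    """Project a full-network attractor onto the core.

    The projected sequence must itself be an attractor of the core
    (guaranteed when peeling is consistent); violating that signals a
    reduction bug and raises.
    """
    net, core = classification.network, classification.core
    seq = [project_state(net, core, s) for s in attractor.states]
    # duplicate projected states would mean a symmetric node broke a cycle
    if len(set(seq)) != len(seq):
        raise RuntimeError("projection collapsed attractor states; reduction bug")
    reduced = Attractor(tuple(seq))
    if not reduced.verify(core):
        raise RuntimeError("projected sequence is not a core attractor")
    return reduced
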