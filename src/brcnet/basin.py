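"""Exact basin of attraction by hierarchical backward search.

The attractor sits at layer 1; each further layer is the exact preimage
of the previous one.  Three devices keep this tractable:

* symmetric (outdegree-0) nodes are peeled first and restored at the end
  by a 2^n_sym lift, since basins are closed under flipping them;
* deterministic nodes' past values are forced by inverting the rules of
  their indegree-1 targets, so only nondeterministic coordinates need
  constraint solving — don't-care coordinates come out as wildcard cubes;
* two sufficient conditions prune states that provably have no preimage
  (terminal basin states): contradictory forced values from two
  indegree-1 targets of the same source, and a nondeterministic node
  whose observed value is unattainable once its deterministic inputs are
  replaced by their forced values.  These checks are accelerators only —
  the preimage computation itself is exact, so an unflagged state with an
  empty preimage still ends its branch correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .cubes import Cube, CubeSet
from .network import Attractor, BooleanNetwork, Rule
from .reduction import (
    NodeClassification,
    classify_network,
    invertible_targets,
    project_attractor,
    project_state,
)

__all__ = [
    "DeterministicInverses",
    "build_deterministic_inverses",
    "terminal_check",
    "predecessor_states",
    "local_basin",
    "basin_of_attractor",
    "basin_union",
    "BasinResult",
    "BasinUnion",
]

DEFAULT_MAX_CUBES = 200_000


@dataclass(frozen=True)
class DeterministicInverses:
    """Inverse bookkeeping for deterministic core nodes.

    ``primary`` maps a deterministic source index to its designated
    indegree-1 target and that target's rule table; ``consistency`` holds
    the remaining targets, whose inverted values must agree with the
    primary one for a preimage to exist.
    """

    primary: dict[int, tuple[int, int]]
    consistency: dict[int, tuple[tuple[int, int], ...]]

    def forced_value(self, source: int, target_value: int, table: int) -> int:
        # identity table 0b10: x = y(t+1); negation 0b01: x = 1 - y(t+1)
        return target_value if table == 0b10 else 1 - target_value

    def force(self, source: int, state: int) -> tuple[int | None, bool]:
        """Forced time-t value of ``source`` given a time-t+1 core state.

        Returns (value, consistent); value is from the primary target and
        consistent is False when any secondary target disagrees (the
        first terminal sufficient condition).
        """
        target, table = self.primary[source]
        v = self.forced_value(source, (state >> target) & 1, table)
        for t2, tab2 in self.consistency[source]:
            if self.forced_value(source, (state >> t2) & 1, tab2) != v:
                return v, False
        return v, True


def build_deterministic_inverses(
    core: BooleanNetwork, classification: NodeClassification | None = None
) -> DeterministicInverses:
    """Collect invertible indegree-1 targets per deterministic source.

    The first target in node order is the primary inverse; the rest serve
    as consistency checks.
    """
    targets = invertible_targets(core)
    primary: dict[int, tuple[int, int]] = {}
    consistency: dict[int, tuple[tuple[int, int], ...]] = {}
    for src, tgt_list in targets.items():
        tgt_list = sorted(tgt_list)
        first = tgt_list[0]
        primary[src] = (first, core.rules[first].table)
        consistency[src] = tuple(
            (t, core.rules[t].table) for t in tgt_list[1:]
        )
    return DeterministicInverses(primary, consistency)


def _forced_assignment(
    inv: DeterministicInverses, state: int
) -> tuple[dict[int, int], list[tuple[str, int]]]:
    forced: dict[int, int] = {}
    fired: list[tuple[str, int]] = []
    for src in inv.primary:
        v, ok = inv.force(src, state)
        forced[src] = v
        if not ok:
            fired.append(("inverse-contradiction", src))
    return forced, fired


def terminal_check(
    core: BooleanNetwork,
    classification: NodeClassification,
    state: int,
    inverses: DeterministicInverses | None = None,
) -> tuple[bool, list[tuple[str, int]]]:
    """Sufficient (not necessary) test for an empty preimage.

    Fires on (a) contradictory forced values of a deterministic source
    from two of its indegree-1 targets, or (b) a nondeterministic node
    with deterministic inputs whose value in ``state`` is unattainable
    for every setting of its nondeterministic inputs.  ``False`` means
    "unknown", never "has a preimage".
    """
    inv = inverses or build_deterministic_inverses(core)
    forced, fired = _forced_assignment(inv, state)
    det_set = set(forced)
    for i, rule in enumerate(core.rules):
        if i in det_set or not any(src in det_set for src in rule.inputs):
            continue
        restricted = rule.restrict({s: forced[s] for s in rule.inputs if s in det_set})
        target = (state >> i) & 1
        if restricted.is_constant() and (restricted.table & 1) != target:
            fired.append(("unattainable-value", i))
    return bool(fired), fired


def predecessor_states(
    core: BooleanNetwork,
    classification: NodeClassification,
    state: int,
    inverses: DeterministicInverses | None = None,
) -> CubeSet:
    """Exact preimage of a core state, as disjoint wildcard cubes.

    Deterministic coordinates are forced by rule inversion; the remaining
    coordinates are solved by most-constrained-first branching with unit
    propagation over the Boolean system  f_v(x) = state_v.  Coordinates
    no constraint touches stay wildcard.
    """
    inv = inverses or build_deterministic_inverses(core)
    out = CubeSet(core.n)
    forced, fired = _forced_assignment(inv, state)
    if fired:
        return out

    # constraints: every core rule must reproduce state's bit
    constraints: list[tuple[Rule, int]] = []
    for i, rule in enumerate(core.rules):
        target = (state >> i) & 1
        r = rule.restrict({s: v for s, v in forced.items() if s in rule.inputs})
        if r.is_constant():
            if (r.table & 1) != target:
                return out
            continue
        constraints.append((r, target))

    def solve(assign: dict[int, int], pending: list[tuple[Rule, int]]) -> None:
        # propagate: restrict by current assignment, detect units/conflicts
        while True:
            nxt: list[tuple[Rule, int]] = []
            unit: tuple[int, int] | None = None
            for rule, target in pending:
                r = rule.restrict({i: assign[i] for i in rule.inputs if i in assign})
                if r.is_constant():
                    if (r.table & 1) != target:
                        return
                    continue
                if len(r.inputs) == 1:
                    # essential single-input rule is identity or negation
                    v = target if r.table == 0b10 else 1 - target
                    var = r.inputs[0]
                    if var in assign:
                        if assign[var] != v:
                            return
                        continue
                    if unit is None:
                        unit = (var, v)
                    elif unit[0] == var and unit[1] != v:
                        return
                nxt.append((r, target))
            if unit is not None:
                assign = dict(assign)
                assign[unit[0]] = unit[1]
                pending = nxt
                continue
            pending = nxt
            break
        if not pending:
            care = value = 0
            for i, v in {**forced, **assign}.items():
                care |= 1 << i
                value |= v << i
            out.add(Cube(core.n, care, value))
            return
        # branch on the unassigned variable hit by the most constraints
        counts: dict[int, int] = {}
        for rule, _ in pending:
            for i in rule.inputs:
                if i not in assign:
                    counts[i] = counts.get(i, 0) + 1
        var = max(counts, key=lambda i: (counts[i], -i))
        for v in (0, 1):
            a2 = dict(assign)
            a2[var] = v
            solve(a2, pending)

    solve({}, constraints)
    return out


# ---------------------------------------------------------------------------
# basin construction


@dataclass
class BasinResult:
    """Exact basin of one attractor, in reduced (core) coordinates.

    ``local_basins[q]`` holds the states whose backward derivation roots
    at reduced attractor state q; ``layers`` maps each reduced basin
    state to its backward layer (attractor states are layer 1).  The full
    basin is the reduced basin times all 2^n_sym symmetric-node settings.
    """

    classification: NodeClassification
    attractor: Attractor
    reduced_attractor: Attractor
    local_basins: dict[int, CubeSet]
    terminal_states: list[int]
    layers: dict[int, int]
    n_sym: int

    @property
    def network(self) -> BooleanNetwork:
        return self.classification.network

    @property
    def core(self) -> BooleanNetwork:
        return self.classification.core

    @property
    def reduced_cubes(self) -> CubeSet:
        merged = CubeSet(self.core.n)
        for cs in self.local_basins.values():
            merged.cubes.extend(cs.cubes)  # local basins are disjoint
        return merged

    def reduced_count(self) -> int:
        return sum(cs.count() for cs in self.local_basins.values())

    def full_count(self) -> int:
        return self.reduced_count() << self.n_sym

    def contains_reduced(self, core_state: int) -> bool:
        return any(cs.contains(core_state) for cs in self.local_basins.values())

    def contains(self, state: int) -> bool:
        """Full-network membership: core coordinates decide."""
        return self.contains_reduced(
            project_state(self.network, self.core, state)
        )

    def export_metadata(self) -> dict:
        """JSON-ready summary; counts as decimal strings (no precision loss)."""
        return {
            "nodes": list(self.network.nodes),
            "core_nodes": list(self.core.nodes),
            "symmetric_nodes": list(self.classification.symmetric_nodes),
            "attractor_length": self.attractor.length,
            "n_sym": self.n_sym,
            "reduced_count": str(self.reduced_count()),
            "full_count": str(self.full_count()),
            "n_terminal_states": len(self.terminal_states),
            "n_cubes": sum(len(cs) for cs in self.local_basins.values()),
        }


def local_basin(
    core: BooleanNetwork,
    classification: NodeClassification,
    sq: int,
    attractor_states: Iterable[int] = (),
    inverses: DeterministicInverses | None = None,
    max_cubes: int | None = DEFAULT_MAX_CUBES,
    layers: dict[int, int] | None = None,
    terminal_states: list[int] | None = None,
) -> CubeSet:
    """Backward breadth-first closure rooted at one core attractor state.

    Layer 1 is {sq}; each next layer is the exact preimage of the
    previous, minus attractor states (which keeps local basins disjoint)
    and minus anything already recorded (backward graphs reconverge).
    States passing the terminal check are not expanded.
    """
    inv = inverses or build_deterministic_inverses(core)
    attractor_set = set(attractor_states) | {sq}
    basin = CubeSet(core.n, max_cubes=max_cubes)
    basin.add_state(sq)
    if layers is not None:
        layers[sq] = 1
    frontier = [sq]
    depth = 1
    while frontier:
        depth += 1
        nxt: list[int] = []
        for s in frontier:
            flagged, _ = terminal_check(core, classification, s, inv)
            if flagged:
                if terminal_states is not None:
                    terminal_states.append(s)
                continue
            preds = predecessor_states(core, classification, s, inv)
            new_any = False
            for cube in preds:
                pieces = [cube]
                for a in attractor_set:
                    pieces = [
                        p
                        for piece in pieces
                        for p in (
                            piece.subtract(Cube.from_state(core.n, a))
                            if piece.contains(a)
                            else [piece]
                        )
                    ]
                for piece in pieces:
                    for added in basin.add(piece):
                        new_any = True
                        for st in added.states():
                            nxt.append(st)
                            if layers is not None:
                                layers[st] = depth
            if preds.count() == 0 and terminal_states is not None:
                terminal_states.append(s)
        frontier = nxt
    return basin


def basin_of_attractor(
    net: BooleanNetwork,
    attractor: Attractor,
    max_cubes: int | None = DEFAULT_MAX_CUBES,
    track_layers: bool = True,
) -> BasinResult:
    """Exact basin of a full-network attractor.

    Peels symmetric nodes, projects the attractor onto the core, runs the
    backward search per attractor state, and lifts the result by the
    symmetric-node factor.
    """
    if not attractor.verify(net):
        raise ValueError("attractor is not reproduced by forward stepping")
    classification = classify_network(net)
    core = classification.core
    reduced = project_attractor(attractor, classification)
    inv = build_deterministic_inverses(core)
    layers: dict[int, int] | None = {} if track_layers else None
    terminal_states: list[int] = []
    local: dict[int, CubeSet] = {}
    att_states = set(reduced.states)
    for q, sq in enumerate(reduced.states):
        local[q] = local_basin(
            core,
            classification,
            sq,
            attractor_states=att_states,
            inverses=inv,
            max_cubes=max_cubes,
            layers=layers,
            terminal_states=terminal_states,
        )
    return BasinResult(
        classification=classification,
        attractor=attractor,
        reduced_attractor=reduced,
        local_basins=local,
        terminal_states=sorted(set(terminal_states)),
        layers=layers or {},
        n_sym=classification.n_sym,
    )


@dataclass
class BasinUnion:
    """Union of basins of distinct attractors of one network.

    Basins of distinct attractors are disjoint, so the exact union count
    is the plain sum; membership is the disjunction.
    """

    results: tuple[BasinResult, ...]

    def __post_init__(self) -> None:
        nets = {id(r.network): r.network for r in self.results}
        if len({r.network for r in self.results}) > 1:
            raise ValueError("basin union requires a single network")
        if not self.results:
            raise ValueError("empty union")

    @property
    def network(self) -> BooleanNetwork:
        return self.results[0].network

    def full_count(self) -> int:
        seen: set[Attractor] = set()
        total = 0
        for r in self.results:
            if r.attractor in seen:
                continue
            seen.add(r.attractor)
            total += r.full_count()
        return total

    def contains(self, state: int) -> bool:
        return any(r.contains(state) for r in self.results)


def basin_union(results: Sequence[BasinResult]) -> BasinUnion:
    return BasinUnion(tuple(results))
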