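"""Temporary versus persistent interventions on a Boolean network.

A temporary (one-time) perturbation overwrites some node values once and
lets the network evolve freely; no other node is ever perturbed,
directly or indirectly.  A persistent perturbation clamps the targets
for good: their constant values propagate, stage by stage, through nodes
whose rules become constant given everything already fixed — the
*fixation cascade* — until (typically) the whole state is pinned.
Interrupting a persistent perturbation before the trajectory has reached
the desired attractor can lose the control goal; the interruption
experiment measures that success rate as a function of duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .network import (
    Attractor,
    BooleanNetwork,
    PhenotypeCondition,
    Rule,
    clamp_and_propagate,
    find_attractor,
)
from .landscape import converge_batch

__all__ = [
    "FixationCascade",
    "temporary_perturbation",
    "persistent_fixation_cascade",
    "interruption_success_rate",
]


def apply_assignments(
    net: BooleanNetwork, state: int, assignments: Mapping[str, int]
) -> int:
    for name, v in assignments.items():
        i = net.index(name)
        if v not in (0, 1):
            raise ValueError(f"assignment for {name!r} must be 0 or 1")
        state = (state & ~(1 << i)) | (v << i)
    return state


def temporary_perturbation(
    net: BooleanNetwork,
    state: int,
    assignments: Mapping[str, int],
    max_steps: int | None = None,
) -> tuple[int, list[int], Attractor]:
    """One-time overwrite, then free synchronous evolution.

    Returns the perturbed state, the full trajectory (perturbed state
    first, then one full attractor period), and the reached attractor.
    """
    perturbed = apply_assignments(net, state, assignments)
    attractor, transient = find_attractor(net, perturbed, max_steps)
    trajectory = [perturbed]
    x = perturbed
    for _ in range(transient + attractor.length - 1):
        x = net.step(x)
        trajectory.append(x)
    return perturbed, trajectory, attractor


@dataclass
class FixationCascade:
    """Stage-wise spread of forced-constant values under clamping.

    ``stages[0]`` is the clamped set itself; ``stages[k]`` the nodes
    newly pinned at the (k+1)-th state of the clamped run.  Once fixed, a
    value never changes.  If the closure pins every node, ``final_state``
    is the fully fixed state (a fixed point of the clamped network);
    otherwise ``free_nodes`` names the residual subnetwork.

    The "state count" / "transition count" conventions differ by one
    (the clamped pattern is itself the 1st state); both are exposed.
    """

    stages: list[list[tuple[str, int]]]
    free_nodes: tuple[str, ...]
    final_state: int | None

    @property
    def all_fixed(self) -> bool:
        return not self.free_nodes

    @property
    def total_states(self) -> int:
        return len(self.stages)

    @property
    def total_transitions(self) -> int:
        return len(self.stages) - 1

    def fixed_assignment(self) -> dict[str, int]:
        return {name: v for stage in self.stages for name, v in stage}


def persistent_fixation_cascade(
    net: BooleanNetwork, clamps: Mapping[str, int]
) -> FixationCascade:
    """Trace which nodes become constant at which step under clamping.

    Stage k+1 fixes every node whose rule evaluates to one value for all
    settings of the still-free inputs, given the values fixed so far
    (exact truth-table restriction, no heuristics).  The cascade is
    monotone and closes in at most n stages.
    """
    fixed: dict[int, int] = {}
    for name, v in clamps.items():
        i = net.index(name)
        if v not in (0, 1):
            raise ValueError(f"clamp value for {name!r} must be 0 or 1")
        if fixed.get(i, v) != v:
            raise ValueError(f"contradictory clamp on {name!r}")
        fixed[i] = v
    stages = [[(net.nodes[i], v) for i, v in sorted(fixed.items())]]
    rules = list(net.rules)
    for i, v in fixed.items():
        rules[i] = Rule((), v)
    while True:
        newly: list[tuple[str, int]] = []
        restricted = {}
        for i in range(net.n):
            if i in fixed:
                continue
            r = rules[i].restrict(fixed)
            restricted[i] = r
            if r.is_constant():
                newly.append((net.nodes[i], r.table & 1))
        if not newly:
            break
        for name, v in newly:
            fixed[net.index(name)] = v
        stages.append(newly)
    free = tuple(net.nodes[i] for i in range(net.n) if i not in fixed)
    final = None
    if not free:
        final = 0
        for i, v in fixed.items():
            final |= v << i
    return FixationCascade(stages=stages, free_nodes=free, final_state=final)


def clamped_rules(
    net: BooleanNetwork, clamps: Mapping[str, int]
) -> BooleanNetwork:
    """The same node set with clamped nodes' rules replaced by constants."""
    rules = list(net.rules)
    for name, v in clamps.items():
        rules[net.index(name)] = Rule((), v)
    return BooleanNetwork(net.nodes, tuple(rules))


def interruption_success_rate(
    net: BooleanNetwork,
    clamps: Mapping[str, int],
    interrupt_step: int,
    desired: PhenotypeCondition | Sequence[Attractor],
    initial_states: Sequence[int] | None = None,
    n_samples: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Success probability when clamping is released after k transitions.

    Simulates ``interrupt_step`` transitions of the clamped network
    (clamped nodes overwritten from the start), releases the clamp, and
    evolves freely to an attractor; ``interrupt_step=0`` means no
    intervention at all.  Success is convergence to a desired
    attractor — given either explicitly or as a phenotype condition.
    Returns (fraction, binomial standard error).
    """
    if interrupt_step < 0:
        raise ValueError("interrupt_step must be ≥ 0")
    rng = np.random.default_rng(seed)
    if initial_states is None:
        states = rng.integers(0, 1 << net.n, size=n_samples, dtype=np.int64)
    else:
        states = np.asarray(list(initial_states), dtype=np.int64)
    clamp_mask = 0
    clamp_value = 0
    for name, v in clamps.items():
        i = net.index(name)
        clamp_mask |= 1 << i
        clamp_value |= v << i
    cnet = clamped_rules(net, clamps)
    if interrupt_step > 0:
        # the clamped pattern is the 1st state of the perturbed run
        states = (states & ~clamp_mask) | clamp_value
        for _ in range(interrupt_step):
            states = cnet.step_batch(states)
    attractors, assignment = converge_batch(net, states)
    if isinstance(desired, PhenotypeCondition):
        ok = [desired.satisfied_by(net, a) for a in attractors]
    else:
        want = set(desired)
        ok = [a in want for a in attractors]
    ok_arr = np.array(ok, dtype=bool)
    successes = int(ok_arr[assignment].sum())
    n = len(states)
    p = successes / n
    se = math.sqrt(p * (1 - p) / n)
    return p, se
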