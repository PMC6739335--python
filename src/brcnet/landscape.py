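"""Monte-Carlo estimation of the attractor landscape and node profiles.

For networks too large for exhaustive state-space enumeration, uniform
random initial states are forwarded to their attractors; pooling by
canonical cycle gives basin-ratio estimates with binomial standard
errors.  Node-level summaries — mean activity over a state collection,
how often a node appears in minimum control target sets, and how often
its target value is 0 — support the difference-vs-probability analyses:
nodes whose mean activity differs most between undesired and desired
states tend to be the control targets, and the sign of the difference
sets the perturbation direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .control import ControlResult
from .network import Attractor, BooleanNetwork, PhenotypeCondition

__all__ = [
    "LandscapeSummary",
    "NodeProfile",
    "converge_batch",
    "mc_attractor_landscape",
    "sample_states_by_phenotype",
    "control_target_probability",
    "activity_level_profile",
    "difference_correlation",
]


def converge_batch(
    net: BooleanNetwork, states: np.ndarray, max_steps: int = 1_000_000
) -> tuple[list[Attractor], np.ndarray]:
    """Forward every state to its attractor, vectorized.

    Floyd tortoise/hare run in lockstep over the whole batch; meeting
    states lie on their cycles and are pooled into canonical attractors.
    Returns the attractor list and a per-sample attractor-index array.
    """
    states = np.asarray(states, dtype=np.int64)
    slow = net.step_batch(states)
    fast = net.step_batch(slow)
    meet = np.full_like(states, -1)
    active = slow != fast
    meet[~active] = slow[~active]
    steps = 0
    while active.any():
        steps += 1
        if steps > max_steps:
            raise RuntimeError("cycle detection exceeded max_steps")
        slow_a = net.step_batch(slow[active])
        fast_a = net.step_batch(net.step_batch(fast[active]))
        slow[active] = slow_a
        fast[active] = fast_a
        met_now = active.copy()
        met_now[active] = slow_a == fast_a
        meet[met_now] = slow[met_now]
        active &= ~met_now
    # pool unique meeting states into canonical attractors
    uniq, inverse = np.unique(meet, return_inverse=True)
    rep_to_idx: dict[int, int] = {}
    attractors: list[Attractor] = []
    uniq_idx = np.empty(len(uniq), dtype=np.int64)
    for u, s in enumerate(uniq.tolist()):
        if s in rep_to_idx:
            uniq_idx[u] = rep_to_idx[s]
            continue
        cyc = [s]
        x = net.step(s)
        while x != s:
            cyc.append(x)
            x = net.step(x)
        a = Attractor(tuple(cyc))
        # distinct meeting states may share one cycle
        existing = None
        for c in cyc:
            if c in rep_to_idx:
                existing = rep_to_idx[c]
                break
        if existing is None:
            existing = len(attractors)
            attractors.append(a)
        for c in cyc:
            rep_to_idx[c] = existing
        uniq_idx[u] = existing
    return attractors, uniq_idx[inverse]


@dataclass
class LandscapeSummary:
    """Estimated attractor landscape from uniform random initial states."""

    network: BooleanNetwork
    attractors: list[Attractor]
    counts: list[int]
    labels: list[str]
    n_samples: int
    seed: int

    @property
    def ratios(self) -> list[float]:
        return [c / self.n_samples for c in self.counts]

    @property
    def standard_errors(self) -> list[float]:
        return [
            math.sqrt(p * (1 - p) / self.n_samples) for p in self.ratios
        ]

    def fraction(self, label: str) -> float:
        return sum(
            c for c, lab in zip(self.counts, self.labels) if lab == label
        ) / self.n_samples

    def attractors_with_label(self, label: str) -> list[Attractor]:
        return [
            a for a, lab in zip(self.attractors, self.labels) if lab == label
        ]

    def to_dict(self) -> dict:
        from .network import state_to_string

        return {
            "n_samples": self.n_samples,
            "seed": self.seed,
            "attractors": [
                {
                    "states": [
                        state_to_string(s, self.network.n) for s in a.states
                    ],
                    "length": a.length,
                    "label": lab,
                    "ratio": c / self.n_samples,
                    "se": math.sqrt(
                        (c / self.n_samples)
                        * (1 - c / self.n_samples)
                        / self.n_samples
                    ),
                }
                for a, c, lab in zip(self.attractors, self.counts, self.labels)
            ],
        }


def mc_attractor_landscape(
    net: BooleanNetwork,
    n_samples: int,
    seed: int = 0,
    phenotype: PhenotypeCondition | None = None,
    batch_size: int = 100_000,
) -> LandscapeSummary:
    """Estimate basin ratios from uniform random initial states.

    Sampling is uniform over the full state space of ``net`` (clamped
    networks should be reduced first so sampling ranges over free nodes
    only).  Seeded runs are bit-reproducible.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be ≥ 1")
    rng = np.random.default_rng(seed)
    attractors: list[Attractor] = []
    index_of: dict[Attractor, int] = {}
    counts: list[int] = []
    remaining = n_samples
    while remaining > 0:
        m = min(batch_size, remaining)
        remaining -= m
        states = rng.integers(0, 1 << net.n, size=m, dtype=np.int64)
        found, assignment = converge_batch(net, states)
        local_counts = np.bincount(assignment, minlength=len(found))
        for a, c in zip(found, local_counts.tolist()):
            if a not in index_of:
                index_of[a] = len(attractors)
                attractors.append(a)
                counts.append(0)
            counts[index_of[a]] += c
    labels = [
        phenotype.label(net, a) if phenotype is not None else "other"
        for a in attractors
    ]
    return LandscapeSummary(net, attractors, counts, labels, n_samples, seed)


def sample_states_by_phenotype(
    net: BooleanNetwork,
    phenotype: PhenotypeCondition,
    polarity: str,
    n: int,
    seed: int = 0,
    max_attempts: int = 10_000_000,
    batch_size: int = 50_000,
) -> list[int]:
    """Rejection-sample uniform states whose attractor has a given label.

    ``polarity`` is "desired" or "undesired".  Raises with the achieved
    count if the acceptance probability is too low within the attempt cap.
    """
    if polarity not in ("desired", "undesired"):
        raise ValueError("polarity must be 'desired' or 'undesired'")
    rng = np.random.default_rng(seed)
    out: list[int] = []
    attempts = 0
    while len(out) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"rejection sampling exhausted {max_attempts} attempts; "
                f"achieved {len(out)}/{n} {polarity} states"
            )
        m = min(batch_size, max_attempts - attempts)
        attempts += m
        states = rng.integers(0, 1 << net.n, size=m, dtype=np.int64)
        found, assignment = converge_batch(net, states)
        keep = np.array(
            [phenotype.label(net, a) == polarity for a in found], dtype=bool
        )
        out.extend(states[keep[assignment]].tolist())
    return out[:n]


@dataclass
class NodeProfile:
    """Per-node summaries over states and/or control target sets."""

    nodes: tuple[str, ...]
    activity: dict[str, float] | None = None
    inclusion_probability: dict[str, float] | None = None
    zero_activity_probability: dict[str, float] | None = None


def control_target_probability(
    net: BooleanNetwork, control_results: Sequence[ControlResult]
) -> NodeProfile:
    """Inclusion frequency of each node over all pooled target sets.

    Also records, per node, the fraction of its inclusions with target
    value 0 (the zero-activity probability).  Nodes never included get
    inclusion probability exactly 0 and zero-activity probability NaN.
    """
    if not control_results:
        raise ValueError("need at least one control result")
    incl = {name: 0 for name in net.nodes}
    zero = {name: 0 for name in net.nodes}
    total = 0
    for res in control_results:
        for tset in res.target_sets:
            total += 1
            for name, v in tset.items():
                incl[name] += 1
                if v == 0:
                    zero[name] += 1
    if total == 0:
        raise ValueError("control results contain no target sets")
    return NodeProfile(
        nodes=net.nodes,
        inclusion_probability={n: incl[n] / total for n in net.nodes},
        zero_activity_probability={
            n: (zero[n] / incl[n]) if incl[n] else float("nan")
            for n in net.nodes
        },
    )


def activity_level_profile(
    net: BooleanNetwork, states: Sequence[int]
) -> NodeProfile:
    """Per-node mean value over a state collection (0=inhibited, 1=active)."""
    if not len(states):
        raise ValueError("empty state collection")
    arr = np.asarray(list(states), dtype=np.int64)
    activity = {
        name: float(((arr >> i) & 1).mean())
        for i, name in enumerate(net.nodes)
    }
    return NodeProfile(nodes=net.nodes, activity=activity)


def basin_activity_profile(net, basin) -> NodeProfile:
    """Exact cube-weighted node means over a computed reduced basin.

    Symmetric (peeled) nodes have mean exactly 0.5; core nodes average
    their cube columns weighted by cube size (wildcards count half).
    """
    core = basin.core
    total = basin.reduced_count()
    sums = {name: 0 for name in core.nodes}
    for cube in basin.reduced_cubes:
        size = cube.size()
        for j, name in enumerate(core.nodes):
            bit = 1 << j
            if cube.care & bit:
                if cube.value & bit:
                    sums[name] += size
            else:
                sums[name] += size // 2
    activity = {}
    for name in net.nodes:
        if name in sums:
            activity[name] = sums[name] / total
        else:
            activity[name] = 0.5  # peeled symmetric node
    return NodeProfile(nodes=net.nodes, activity=activity)


def difference_correlation(
    profile_undesired: NodeProfile,
    profile_desired: NodeProfile,
    inclusion: NodeProfile,
) -> tuple[float, float, list[dict]]:
    """Association between basin-activity differences and targeting.

    Pearson r (with two-sided p from the t transform) between
    |V_undesired − V_desired| and the control-target inclusion
    probability, plus a per-node table pairing the signed difference
    with the zero-activity probability.
    """
    nodes = [
        n
        for n in inclusion.nodes
        if n in profile_undesired.activity and n in profile_desired.activity
    ]
    if len(nodes) < 3:
        raise ValueError("need at least 3 nodes")
    diff = np.array(
        [
            profile_undesired.activity[n] - profile_desired.activity[n]
            for n in nodes
        ]
    )
    prob = np.array([inclusion.inclusion_probability[n] for n in nodes])
    if np.ptp(np.abs(diff)) == 0 or np.ptp(prob) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(np.abs(diff), prob)
    table = [
        {
            "node": n,
            "signed_difference": float(d),
            "abs_difference": float(abs(d)),
            "inclusion_probability": float(ip),
            "zero_activity_probability": (
                inclusion.zero_activity_probability[n]
                if inclusion.zero_activity_probability
                else float("nan")
            ),
        }
        for n, d, ip in zip(nodes, diff, prob)
    ]
    return float(r), float(p), table
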