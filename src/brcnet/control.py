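"""Boundary-reaching control: minimal one-time perturbations onto a basin.

Given an undesired state α and the exact (reduced) basin of a desired
attractor, nodes split into three groups:

* symmetric nodes — structurally peeled ones plus any core node under
  whose individual flip the reduced basin is closed.  They cost nothing:
  whatever α holds there, a matching basin member exists.
* fixed nodes — constant across the basin; each disagreement with α is a
  mandatory flip (ρ_fixed of them).
* unfixed nodes — everything else; the cheapest completion is the
  minimum mismatch count against any basin member (ρ_unfixed).

mHD = ρ_fixed + ρ_unfixed.  Every minimum control target set is the
mandatory fixed flips plus one minimizing unfixed flip tuple; applying it
to α lands exactly on a boundary state of the basin.

When the desired basin covers most of the state space, the exact basin is
unnecessary: a breadth-first search over flip sets of growing size with
forward simulation finds the same minimal sets (`large_basin_control_search`).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .basin import BasinResult, BasinUnion
from .network import Attractor, BooleanNetwork, find_attractor, state_to_string
from .reduction import project_state

__all__ = [
    "BasinNodeDecomposition",
    "ControlResult",
    "decompose_basin_nodes",
    "minimum_hamming_distance",
    "control_target_sets",
    "control_union",
    "large_basin_control_search",
]

DEFAULT_BOUNDARY_CAP = 10_000


@dataclass(frozen=True)
class BasinNodeDecomposition:
    """Symmetric / fixed / unfixed partition of the node set for one basin."""

    symmetric: tuple[str, ...]
    fixed: dict[str, int]
    unfixed: tuple[str, ...]

    def partition_ok(self, net: BooleanNetwork) -> bool:
        names = set(self.symmetric) | set(self.fixed) | set(self.unfixed)
        disjoint = (
            len(self.symmetric) + len(self.fixed) + len(self.unfixed)
            == len(names)
        )
        return disjoint and names == set(net.nodes)


def decompose_basin_nodes(basin: BasinResult) -> BasinNodeDecomposition:
    """Classify every network node against the reduced basin.

    Fixed nodes are detected from cube columns (constant, never wildcard
    across all cubes).  Basin-symmetric core nodes are verified by the
    individual-flip closure test on the cube set; a node failing
    verification is treated as unfixed.
    """
    if basin.reduced_count() == 0:
        raise ValueError("empty basin")
    core = basin.core
    cubes = basin.reduced_cubes
    symmetric = list(basin.classification.symmetric_nodes)
    fixed: dict[str, int] = {}
    unfixed: list[str] = []
    for j, name in enumerate(core.nodes):
        vals = cubes.column_values(j)
        if len(vals) == 1:
            fixed[name] = vals.pop()
        elif cubes.flip(j).set_equals(cubes):
            symmetric.append(name)
        else:
            unfixed.append(name)
    return BasinNodeDecomposition(tuple(symmetric), fixed, tuple(unfixed))


@dataclass
class ControlResult:
    """Minimum control target sets driving α onto a basin boundary.

    ``target_sets`` maps node name -> value to apply once; every set has
    exactly ``mhd`` entries.  ``boundary_states`` are the basin members
    reached (full-network encoding), possibly truncated at
    ``boundary_cap`` with ``n_boundary_total`` the exact total.
    """

    alpha: int
    mhd: int
    rho_fixed: int
    rho_unfixed: int
    target_sets: list[dict[str, int]]
    boundary_states: list[int]
    n_boundary_total: int
    found: bool = True

    @property
    def index_set_size(self) -> int:
        return len(self.target_sets)

    def to_json(self, net: BooleanNetwork) -> str:
        return json.dumps(
            {
                "alpha": state_to_string(self.alpha, net.n),
                "found": self.found,
                "mhd": self.mhd,
                "rho_fixed": self.rho_fixed,
                "rho_unfixed": self.rho_unfixed,
                "n_target_sets": self.index_set_size,
                "target_sets": self.target_sets,
                "n_boundary_total": self.n_boundary_total,
                "boundary_states": [
                    state_to_string(s, net.n) for s in self.boundary_states
                ],
            },
            indent=2,
        )


def _alpha_core_bits(basin: BasinResult, alpha: int) -> int:
    return project_state(basin.network, basin.core, alpha)


def minimum_hamming_distance(
    alpha: int,
    basin: BasinResult,
    decomposition: BasinNodeDecomposition | None = None,
) -> tuple[int, int, int]:
    """(mHD, ρ_fixed, ρ_unfixed) from α to the basin.

    Symmetric nodes contribute nothing.  ρ_unfixed is the minimum over
    cubes of the mismatch count on specified unfixed coordinates
    (wildcards match for free); the scan over disjoint cubes is exact.
    """
    dec = decomposition or decompose_basin_nodes(basin)
    core = basin.core
    ac = _alpha_core_bits(basin, alpha)
    rho_fixed = sum(
        1
        for name, v in dec.fixed.items()
        if ((ac >> core.index(name)) & 1) != v
    )
    unfixed_idx = [core.index(name) for name in dec.unfixed]
    unfixed_mask = 0
    for i in unfixed_idx:
        unfixed_mask |= 1 << i
    rho_unfixed = 0
    if unfixed_idx:
        best = None
        for cube in basin.reduced_cubes:
            mism = ((cube.value ^ ac) & cube.care & unfixed_mask).bit_count()
            if best is None or mism < best:
                best = mism
                if best == 0:
                    break
        rho_unfixed = best if best is not None else 0
    if basin.contains(alpha):
        return 0, 0, 0
    return rho_fixed + rho_unfixed, rho_fixed, rho_unfixed


def control_target_sets(
    alpha: int,
    basin: BasinResult,
    decomposition: BasinNodeDecomposition | None = None,
    boundary_cap: int = DEFAULT_BOUNDARY_CAP,
) -> ControlResult:
    """Enumerate all minimum control target sets and boundary states.

    Mandatory part: flip every fixed node where α disagrees, to its basin
    value.  Optional part: each distinct minimizing mismatch tuple over
    unfixed coordinates (scanned exhaustively over the cubes).  Boundary
    states keep α's values on symmetric and matching coordinates.
    """
    dec = decomposition or decompose_basin_nodes(basin)
    net, core = basin.network, basin.core
    if basin.contains(alpha):
        return ControlResult(alpha, 0, 0, 0, [{}], [alpha], 1)
    mhd, rho_fixed, rho_unfixed = minimum_hamming_distance(alpha, basin, dec)
    ac = _alpha_core_bits(basin, alpha)

    fixed_flips = {
        name: v
        for name, v in dec.fixed.items()
        if ((ac >> core.index(name)) & 1) != v
    }
    unfixed_mask = 0
    for name in dec.unfixed:
        unfixed_mask |= 1 << core.index(name)

    target_sets: list[dict[str, int]] = []
    seen_sets: set[frozenset[tuple[str, int]]] = set()
    boundary: set[int] = set()
    for cube in basin.reduced_cubes:
        mism = (cube.value ^ ac) & cube.care & unfixed_mask
        if mism.bit_count() != rho_unfixed:
            continue
        tset = dict(fixed_flips)
        for j in range(core.n):
            if (mism >> j) & 1:
                tset[core.nodes[j]] = (cube.value >> j) & 1
        key = frozenset(tset.items())
        if key not in seen_sets:
            seen_sets.add(key)
            target_sets.append(tset)
        # boundary state: α with the target set applied (full encoding)
        b = alpha
        for name, v in tset.items():
            i = net.index(name)
            b = (b & ~(1 << i)) | (v << i)
        boundary.add(b)

    boundary_list = sorted(boundary)
    return ControlResult(
        alpha=alpha,
        mhd=mhd,
        rho_fixed=rho_fixed,
        rho_unfixed=rho_unfixed,
        target_sets=target_sets,
        boundary_states=boundary_list[:boundary_cap],
        n_boundary_total=len(boundary_list),
    )


def control_union(
    alpha: int,
    union: BasinUnion,
    boundary_cap: int = DEFAULT_BOUNDARY_CAP,
) -> ControlResult:
    """Control against a union of desired basins.

    The distance to a union is the minimum over its members, so the
    result pools the target sets of every basin achieving that minimum.
    Enlarging the union can therefore never increase the mHD.
    """
    per = [
        control_target_sets(alpha, b, boundary_cap=boundary_cap)
        for b in union.results
    ]
    best = min(r.mhd for r in per)
    winners = [r for r in per if r.mhd == best]
    seen: set[frozenset] = set()
    target_sets = []
    boundary: set[int] = set()
    for r in winners:
        for t in r.target_sets:
            key = frozenset(t.items())
            if key not in seen:
                seen.add(key)
                target_sets.append(t)
        boundary.update(r.boundary_states)
    w0 = winners[0]
    boundary_list = sorted(boundary)
    return ControlResult(
        alpha=alpha,
        mhd=best,
        rho_fixed=w0.rho_fixed,
        rho_unfixed=w0.rho_unfixed,
        target_sets=target_sets,
        boundary_states=boundary_list[:boundary_cap],
        n_boundary_total=len(boundary_list),
    )


def large_basin_control_search(
    net: BooleanNetwork,
    alpha: int,
    candidate_nodes: Sequence[str] | None,
    desired_attractors: Iterable[Attractor],
    max_hd: int = 3,
) -> ControlResult:
    """Minimal flip sets by forward search, no exact basin required.

    Breadth-first over flip subsets of the candidate nodes, size 0 up to
    ``max_hd``; each flipped state is simulated forward and counts as a
    hit when it converges to a desired attractor.  Stops at the first
    size with a hit and returns all hits at that size.  Suited to large
    desired basins, where small flip sets almost always suffice.
    """
    desired = set(desired_attractors)
    if candidate_nodes is None:
        candidate_nodes = net.nodes
    cand_idx = [net.index(name) for name in candidate_nodes]
    cache: dict[int, bool] = {}

    def hits(state: int) -> bool:
        if state not in cache:
            a, _ = find_attractor(net, state)
            cache[state] = a in desired
        return cache[state]

    for size in range(0, max_hd + 1):
        target_sets = []
        boundary = []
        for combo in itertools.combinations(cand_idx, size):
            s = alpha
            for i in combo:
                s ^= 1 << i
            if hits(s):
                target_sets.append(
                    {net.nodes[i]: (s >> i) & 1 for i in combo}
                )
                boundary.append(s)
        if target_sets:
            return ControlResult(
                alpha=alpha,
                mhd=size,
                rho_fixed=0,
                rho_unfixed=size,
                target_sets=target_sets,
                boundary_states=sorted(boundary),
                n_boundary_total=len(boundary),
            )
    return ControlResult(
        alpha=alpha,
        mhd=-1,
        rho_fixed=0,
        rho_unfixed=0,
        target_sets=[],
        boundary_states=[],
        n_boundary_total=0,
        found=False,
    )
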