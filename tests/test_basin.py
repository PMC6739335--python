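"""Backward basin search against exhaustive forward classification."""

import numpy as np
import pytest

import brcnet as b
from brcnet.basin import (
    build_deterministic_inverses,
    local_basin,
    predecessor_states,
    terminal_check,
)
from brcnet.reduction import classify_network

from conftest import make_net


def core_preimages(core):
    succ = core.successor_table()
    pre: dict[int, list[int]] = {}
    for s, t in enumerate(succ.tolist()):
        pre.setdefault(t, []).append(s)
    return pre


class TestDeterministicInverses:
    def test_identity_and_negation_inverses(self):
        net = b.parse_network("X, Y\nY, !X\nZ, X | Y | Z")
        cls = classify_network(net)
        core = cls.core
        inv = build_deterministic_inverses(core)
        # X(t+1)=Y(t): Y's past value equals X's present value
        y = core.index("Y")
        tgt, table = inv.primary[y]
        assert core.nodes[tgt] == "X" and table == 0b10
        assert inv.force(y, 1 << core.index("X"))[0] == 1
        # Y(t+1)=!X(t): X's past value is the complement of Y's present
        x = core.index("X")
        assert inv.force(x, 1 << core.index("Y"))[0] == 0
        assert inv.force(x, 0)[0] == 1

    def test_toy_forced_value(self, toy):
        cls = classify_network(toy)
        core = cls.core
        inv = build_deterministic_inverses(core)
        c = core.index("C")
        # B(t+1) = !C(t): observing B=0 forces C's past value to 1
        v, ok = inv.force(c, 0)
        assert (v, ok) == (1, True)


class TestTerminalCheck:
    def test_contradictory_copy_targets(self):
        # y1 and y2 both copy x; y1 != y2 has provably no preimage
        net = b.parse_network("x, y1 | y2 | x\ny1, x\ny2, x")
        cls = classify_network(net)
        core = cls.core
        s = 1 << core.index("y1")  # y1=1, y2=0
        flagged, fired = terminal_check(core, cls, s)
        assert flagged
        assert any(kind == "inverse-contradiction" for kind, _ in fired)

    @pytest.mark.parametrize("seed", range(30))
    def test_flagged_states_have_empty_preimage(self, seed):
        net = make_net(seed, n=10)
        cls = classify_network(net)
        core = cls.core
        if core.n == 0 or core.n > 12:
            return
        pre = core_preimages(core)
        inv = build_deterministic_inverses(core)
        for s in range(1 << core.n):
            flagged, _ = terminal_check(core, cls, s, inv)
            if flagged:
                assert not pre.get(s)


class TestPredecessors:
    def test_fixed_point_is_its_own_predecessor(self, toy):
        cls = classify_network(toy)
        core = cls.core
        sq = b.string_to_state("10111")
        preds = predecessor_states(core, cls, sq)
        assert preds.contains(sq)

    @pytest.mark.parametrize("seed", range(30))
    def test_exact_preimage_on_random_cores(self, seed):
        net = make_net(seed, n=11)
        cls = classify_network(net)
        core = cls.core
        if core.n == 0 or core.n > 12:
            return
        pre = core_preimages(core)
        inv = build_deterministic_inverses(core)
        rng = np.random.default_rng(seed)
        for s in rng.integers(0, 1 << core.n, size=40).tolist():
            got = sorted(predecessor_states(core, cls, s, inv).states())
            assert got == sorted(pre.get(s, []))

    def test_terminal_states_get_empty_preimage(self, seed=3):
        net = make_net(seed, n=10)
        cls = classify_network(net)
        core = cls.core
        inv = build_deterministic_inverses(core)
        for s in range(min(1 << core.n, 512)):
            flagged, _ = terminal_check(core, cls, s, inv)
            if flagged:
                assert predecessor_states(core, cls, s, inv).count() == 0


class TestLocalBasin:
    def test_attractor_state_with_only_cyclic_predecessor_is_singleton(self):
        # x flips itself: the sole predecessor of each cycle state is the
        # other cycle state, which local basins exclude, so LB = {state}
        net = b.parse_network("x, !x")
        cls = classify_network(net)
        core = cls.core
        att, _ = b.find_attractor(core, 0)
        for sq in att.states:
            lb = local_basin(core, cls, sq, attractor_states=att.states)
            assert sorted(lb.states()) == [sq]

    def test_toy_trajectory_contained(self, toy, toy_basin):
        # published walkthrough: the trajectory from the terminal state
        # (0,0,1,0,0,0,0) runs inside the basin down to the attractor
        s = b.string_to_state("0010000")
        while True:
            assert toy_basin.contains(s)
            nxt = toy.step(s)
            if nxt == s:
                break
            s = nxt

    @pytest.mark.parametrize("seed", range(25))
    def test_local_basins_partition_the_brute_force_basin(self, seed):
        net = make_net(seed, n=10, n_peelable=2)
        cls = classify_network(net)
        if cls.core.n == 0:
            return
        atts, sizes, assign = b.enumerate_attractors_exhaustive(net)
        att = atts[seed % len(atts)]
        res = b.basin_of_attractor(net, att)
        # local basins disjoint
        all_states: list[int] = []
        for cs in res.local_basins.values():
            all_states.extend(cs.states())
        assert len(all_states) == len(set(all_states))
        # each member's forward path enters the cycle at its root state
        reduced_states = res.reduced_attractor.states
        for q, cs in res.local_basins.items():
            root = reduced_states[q]
            for s in list(cs.states())[:50]:
                x = s
                while x not in reduced_states:
                    x = cls.core.step(x)
                assert x == root


class TestBasinOfAttractor:
    def test_whole_space_basin(self):
        net = b.parse_network("A, B\nB, !A\nC, A & B")
        atts, _, _ = b.enumerate_attractors_exhaustive(net)
        assert len(atts) == 1
        res = b.basin_of_attractor(net, atts[0])
        assert res.full_count() == 1 << net.n

    def test_toy_basin_members_and_count(self, toy_basin):
        assert toy_basin.contains(b.string_to_state("0010000"))
        assert toy_basin.contains(b.string_to_state("0010100"))
        assert toy_basin.full_count() % (1 << toy_basin.n_sym) == 0

    def test_rejects_non_attractor(self, toy):
        with pytest.raises(ValueError):
            b.basin_of_attractor(toy, b.Attractor((0,)))

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_state_for_state(self, seed):
        net = make_net(seed, n=11, n_peelable=2)
        atts, sizes, assign = b.enumerate_attractors_exhaustive(net)
        for ai, att in enumerate(atts[:3]):
            res = b.basin_of_attractor(net, att)
            brute = np.nonzero(assign == ai)[0]
            assert res.full_count() == len(brute)
            brute_set = set(brute.tolist())
            for s in range(1 << net.n):
                assert res.contains(s) == (s in brute_set)

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_members_forward_converge(self, seed):
        net = make_net(seed, n=12, n_peelable=3)
        atts, _, _ = b.enumerate_attractors_exhaustive(net)
        res = b.basin_of_attractor(net, atts[0])
        rng = np.random.default_rng(seed)
        core = res.core
        reduced_states = [s for cs in res.local_basins.values() for s in cs.states()]
        pick = rng.choice(len(reduced_states), size=min(1000, len(reduced_states)))
        for k in pick.tolist():
            att, _ = b.find_attractor(core, reduced_states[k])
            assert att == res.reduced_attractor


class TestBasinUnion:
    def test_union_of_all_basins_is_the_whole_space(self):
        net = make_net(7, n=9)
        atts, _, _ = b.enumerate_attractors_exhaustive(net)
        results = [b.basin_of_attractor(net, a) for a in atts]
        union = b.basin_union(results)
        assert union.full_count() == 1 << net.n
        for s in range(0, 1 << net.n, 17):
            assert union.contains(s)

    def test_self_union_keeps_count(self, toy_basin):
        union = b.basin_union([toy_basin, toy_basin])
        assert union.full_count() == toy_basin.full_count()

    @pytest.mark.parametrize("seed", range(8))
    def test_union_count_is_sum_of_disjoint_counts(self, seed):
        net = make_net(seed + 50, n=10)
        atts, sizes, _ = b.enumerate_attractors_exhaustive(net)
        take = atts[: min(3, len(atts))]
        results = [b.basin_of_attractor(net, a) for a in take]
        union = b.basin_union(results)
        assert union.full_count() == sum(sizes[a] for a in take)
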