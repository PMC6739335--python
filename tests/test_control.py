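"""Boundary-reaching control: decomposition, mHD, target enumeration."""

import itertools

import numpy as np
import pytest

import brcnet as b

from conftest import make_net


def apply_target_set(net, alpha, tset):
    s = alpha
    for name, v in tset.items():
        i = net.index(name)
        s = (s & ~(1 << i)) | (v << i)
    return s


class TestDecomposition:
    def test_toy_decomposition(self, toy, toy_basin):
        dec = b.decompose_basin_nodes(toy_basin)
        assert dec.fixed == {"C": 1}
        assert set(dec.symmetric) == {"F", "G"}
        assert set(dec.unfixed) == {"A", "B", "D", "E"}
        assert dec.partition_ok(toy)

    def test_whole_space_basin_is_all_symmetric(self):
        net = b.parse_network("A, B\nB, !A")
        atts, _, _ = b.enumerate_attractors_exhaustive(net)
        res = b.basin_of_attractor(net, atts[0])
        dec = b.decompose_basin_nodes(res)
        assert set(dec.symmetric) == {"A", "B"}
        assert not dec.fixed and not dec.unfixed

    @pytest.mark.parametrize("seed", range(15))
    def test_fixed_nodes_constant_over_brute_force_basin(self, seed):
        net = make_net(seed, n=10)
        atts, _, assign = b.enumerate_attractors_exhaustive(net)
        res = b.basin_of_attractor(net, atts[0])
        dec = b.decompose_basin_nodes(res)
        basin = np.nonzero(assign == 0)[0]
        for name, v in dec.fixed.items():
            i = net.index(name)
            assert set(((basin >> i) & 1).tolist()) == {v}
        basin_set = set(basin.tolist())
        for name in dec.symmetric:
            i = net.index(name)
            assert all(s ^ (1 << i) in basin_set for s in basin_set)


class TestMinimumHammingDistance:
    def test_toy_alpha(self, toy_basin):
        alpha = b.string_to_state("0000100")
        mhd, rho_f, rho_u = b.minimum_hamming_distance(alpha, toy_basin)
        assert (mhd, rho_f, rho_u) == (1, 1, 0)

    def test_member_has_distance_zero(self, toy_basin):
        member = b.string_to_state("0010100")
        assert b.minimum_hamming_distance(member, toy_basin) == (0, 0, 0)

    @pytest.mark.parametrize("seed", range(25))
    def test_equals_brute_force_minimum(self, seed):
        net = make_net(seed, n=11, n_peelable=2)
        atts, _, assign = b.enumerate_attractors_exhaustive(net)
        ai = seed % len(atts)
        res = b.basin_of_attractor(net, atts[ai])
        basin = np.nonzero(assign == ai)[0]
        rng = np.random.default_rng(seed)
        for alpha in rng.integers(0, 1 << net.n, size=8).tolist():
            mhd, _, _ = b.minimum_hamming_distance(int(alpha), res)
            brute = min(int(bin(int(alpha) ^ int(s)).count("1")) for s in basin)
            assert mhd == brute


class TestControlTargetSets:
    def test_toy_single_set_on_c(self, toy, toy_basin):
        alpha = b.string_to_state("0000100")
        cr = b.control_target_sets(alpha, toy_basin)
        assert cr.mhd == 1
        assert cr.target_sets == [{"C": 1}]
        assert cr.boundary_states == [b.string_to_state("0010100")]

    def test_member_gets_empty_set(self, toy_basin):
        member = b.string_to_state("0010100")
        cr = b.control_target_sets(member, toy_basin)
        assert cr.mhd == 0 and cr.target_sets == [{}]
        assert cr.boundary_states == [member]

    @pytest.mark.parametrize("seed", range(20))
    def test_sets_land_in_basin_and_none_smaller_works(self, seed):
        net = make_net(seed, n=10, n_peelable=2)
        atts, _, assign = b.enumerate_attractors_exhaustive(net)
        ai = seed % len(atts)
        res = b.basin_of_attractor(net, atts[ai])
        basin_set = set(np.nonzero(assign == ai)[0].tolist())
        rng = np.random.default_rng(seed + 1)
        for alpha in rng.integers(0, 1 << net.n, size=4).tolist():
            alpha = int(alpha)
            cr = b.control_target_sets(alpha, res)
            for tset in cr.target_sets:
                assert len(tset) == cr.mhd
                assert apply_target_set(net, alpha, tset) in basin_set
            # exhaustive: no smaller flip set reaches the basin
            for size in range(cr.mhd):
                for combo in itertools.combinations(range(net.n), size):
                    s = alpha
                    for i in combo:
                        s ^= 1 << i
                    assert s not in basin_set

    @pytest.mark.parametrize("seed", range(15))
    def test_enumeration_is_complete(self, seed):
        net = make_net(seed + 30, n=9)
        atts, _, assign = b.enumerate_attractors_exhaustive(net)
        res = b.basin_of_attractor(net, atts[0])
        basin = np.nonzero(assign == 0)[0].tolist()
        alpha = int(np.random.default_rng(seed).integers(0, 1 << net.n))
        cr = b.control_target_sets(alpha, res)
        brute_mhd = min(bin(alpha ^ s).count("1") for s in basin)
        expected = set()
        for s in basin:
            if bin(alpha ^ s).count("1") == brute_mhd:
                d = alpha ^ s
                expected.add(
                    frozenset(
                        (net.nodes[i], (s >> i) & 1)
                        for i in range(net.n)
                        if (d >> i) & 1
                    )
                )
        got = {frozenset(t.items()) for t in cr.target_sets}
        assert got == expected

    def test_temporary_sufficiency_end_to_end(self, toy, toy_beta, toy_basin):
        alpha = b.string_to_state("0000100")
        cr = b.control_target_sets(alpha, toy_basin)
        for tset in cr.target_sets:
            s = apply_target_set(toy, alpha, tset)
            att, _ = b.find_attractor(toy, s)
            assert att == toy_beta


class TestUnionControl:
    @pytest.mark.parametrize("seed", range(10))
    def test_union_never_increases_mhd(self, seed):
        net = make_net(seed + 60, n=10)
        atts, _, _ = b.enumerate_attractors_exhaustive(net)
        results = [b.basin_of_attractor(net, a) for a in atts]
        rng = np.random.default_rng(seed)
        alpha = int(rng.integers(0, 1 << net.n))
        prev = None
        for k in range(1, len(results) + 1):
            cr = b.control_union(alpha, b.basin_union(results[:k]))
            if prev is not None:
                assert cr.mhd <= prev
            prev = cr.mhd


class TestLargeBasinSearch:
    def test_converging_state_needs_no_flip(self, toy, toy_beta):
        member = b.string_to_state("0010100")
        cr = b.large_basin_control_search(toy, member, None, [toy_beta])
        assert cr.mhd == 0 and cr.found

    def test_not_found_within_bound(self, toy, toy_beta):
        alpha = b.string_to_state("0000100")
        cr = b.large_basin_control_search(
            toy, alpha, ["F", "G"], [toy_beta], max_hd=2
        )
        assert not cr.found and cr.mhd == -1

    @pytest.mark.parametrize("seed", range(15))
    def test_agrees_with_exact_method(self, seed):
        net = make_net(seed, n=9, n_peelable=2)
        atts, _, assign = b.enumerate_attractors_exhaustive(net)
        ai = seed % len(atts)
        res = b.basin_of_attractor(net, atts[ai])
        rng = np.random.default_rng(seed + 2)
        alpha = int(rng.integers(0, 1 << net.n))
        exact = b.control_target_sets(alpha, res)
        forward = b.large_basin_control_search(
            net, alpha, None, [atts[ai]], max_hd=net.n
        )
        # forward search measures distance to the whole basin of the
        # attractor, i.e. the same quantity as the exact method
        assert forward.found and forward.mhd == exact.mhd
        got = {frozenset(t.items()) for t in forward.target_sets}
        want = {frozenset(t.items()) for t in exact.target_sets}
        assert got == want
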