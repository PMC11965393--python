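import pytest
from hypothesis import given, settings, strategies as st

from domentropy import (
    brute_force_mds,
    domination_degrees,
    enumerate_minimal_dominating_sets,
    is_dominating,
    is_minimal_dominating,
    random_connected_graph,
)
from domentropy.domination import ResourceCapError

from conftest import make_complete, make_cycle, make_path, make_star

# The 23 minimal dominating sets of naphthalene (1-based conventional labels).
NAPHTHALENE_MDS = [
    {9, 2, 5}, {8, 3, 6}, {1, 2, 4, 9}, {8, 1, 3, 4}, {8, 1, 3, 5},
    {1, 4, 9, 7}, {1, 10, 4, 7}, {8, 1, 4, 9}, {8, 1, 10, 4},
    {1, 10, 5, 7}, {8, 1, 10, 5}, {8, 2, 3, 5}, {9, 2, 3, 6},
    {9, 2, 4, 6}, {2, 10, 5, 7}, {8, 2, 10, 5}, {9, 3, 6, 7},
    {10, 3, 6, 7}, {9, 4, 6, 7}, {10, 4, 6, 7}, {10, 5, 6, 7},
    {1, 3, 5, 7, 9}, {2, 4, 6, 8, 10},
]


def _zero_based(sets):
    return sorted(tuple(sorted(v - 1 for v in s)) for s in sets)


class TestIsDominating:
    def test_closed_neighborhood_convention(self, naphthalene):
        # {v9, v2, v5} dominates the whole two-ring skeleton
        assert is_dominating(naphthalene, (8, 1, 4))

    def test_whole_vertex_set_dominates(self, naphthalene):
        assert is_dominating(naphthalene, range(10))

    def test_empty_set_does_not(self, naphthalene):
        assert not is_dominating(naphthalene, ())

    def test_invalid_vertex_rejected(self, naphthalene):
        with pytest.raises(Exception):
            is_dominating(naphthalene, (99,))


class TestIsMinimalDominating:
    def test_alternating_five_set(self, naphthalene):
        # {v2, v4, v6, v8, v10}
        assert is_minimal_dominating(naphthalene, (1, 3, 5, 7, 9))

    def test_complete_graph_triple_not_minimal(self):
        assert not is_minimal_dominating(make_complete(3), (0, 1, 2))

    def test_dominating_but_removable_member(self, naphthalene):
        # {v2, v5, v6, v9} dominates, but dropping v6 leaves {v9, v2, v5}
        D = (1, 4, 5, 8)
        assert is_dominating(naphthalene, D)
        assert not is_minimal_dominating(naphthalene, D)


class TestEnumeration:
    def test_naphthalene_matches_hand_enumeration(self, naphthalene):
        coll = enumerate_minimal_dominating_sets(naphthalene)
        assert coll.count == 23
        assert list(coll.sets) == _zero_based(NAPHTHALENE_MDS)

    def test_hexagon_has_five(self, benzene):
        assert enumerate_minimal_dominating_sets(benzene).count == 5

    def test_complete_graph_singletons(self):
        coll = enumerate_minimal_dominating_sets(make_complete(3))
        assert list(coll.sets) == [(0,), (1,), (2,)]

    def test_path4_sets(self):
        coll = enumerate_minimal_dominating_sets(make_path(4))
        assert list(coll.sets) == [(0, 2), (0, 3), (1, 2), (1, 3)]

    def test_vertex_cap(self):
        g = make_path(12)
        with pytest.raises(ResourceCapError, match="cap"):
            enumerate_minimal_dominating_sets(g, cap=10)
        assert enumerate_minimal_dominating_sets(g, cap=12).count > 0

    def test_every_member_minimal_no_subset_pairs(self, naphthalene):
        coll = enumerate_minimal_dominating_sets(naphthalene)
        masks = [sum(1 << v for v in s) for s in coll.sets]
        for s in coll.sets:
            assert is_minimal_dominating(naphthalene, s)
        for i, a in enumerate(masks):
            for b in masks[i + 1:]:
                assert a & b not in (a, b), "one member contains another"

    def test_deterministic_ordering(self, naphthalene):
        a = enumerate_minimal_dominating_sets(naphthalene)
        b = enumerate_minimal_dominating_sets(naphthalene)
        assert a.sets == b.sets


class TestDominationDegrees:
    def test_naphthalene_degree_vector(self, naphthalene):
        coll = enumerate_minimal_dominating_sets(naphthalene)
        assert domination_degrees(coll) == [10, 8, 8, 10, 9, 9, 10, 9, 9, 10]

    def test_complete_graph(self):
        coll = enumerate_minimal_dominating_sets(make_complete(3))
        assert domination_degrees(coll) == [1, 1, 1]

    def test_path4(self):
        coll = brute_force_mds(make_path(4))
        assert domination_degrees(coll) == [2, 2, 2, 2]

    def test_conservation_naphthalene(self, naphthalene):
        """Sum of domination degrees equals total membership: 92."""
        coll = enumerate_minimal_dominating_sets(naphthalene)
        assert sum(domination_degrees(coll)) == sum(len(s) for s in coll.sets) == 92


class TestOracleEquivalence:
    @pytest.mark.parametrize("maker", [make_path, make_cycle, make_star,
                                       make_complete])
    @pytest.mark.parametrize("n", range(3, 11))
    def test_structured_families(self, maker, n):
        g = maker(n)
        assert enumerate_minimal_dominating_sets(g).sets == brute_force_mds(g).sets

    def test_k2(self):
        assert list(brute_force_mds(make_complete(2)).sets) == [(0,), (1,)]

    def test_k6_singletons(self):
        assert enumerate_minimal_dominating_sets(make_complete(6)).count == 6

    def test_naphthalene_against_oracle(self, naphthalene):
        assert (enumerate_minimal_dominating_sets(naphthalene).sets
                == brute_force_mds(naphthalene).sets)

    def test_random_graph_seed7(self):
        g = random_connected_graph(10, 0.3, seed=7)
        assert enumerate_minimal_dominating_sets(g).sets == brute_force_mds(g).sets

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(n=st.integers(4, 11), p=st.floats(0.15, 0.9),
           seed=st.integers(0, 2**16))
    def test_random_graphs_property(self, n, p, seed):
        """Enumerator equals brute force, and membership counts conserve."""
        g = random_connected_graph(n, p, seed)
        coll = enumerate_minimal_dominating_sets(g)
        assert coll.sets == brute_force_mds(g).sets
        dd = domination_degrees(coll)
        assert sum(dd) == sum(len(s) for s in coll.sets)
        assert all(d >= 1 for d in dd)  # every vertex lies in some M.D.S.


class TestRandomConnectedGraph:
    def test_deterministic_for_seed(self):
        a = random_connected_graph(8, 0.4, seed=3)
        b = random_connected_graph(8, 0.4, seed=3)
        assert a.edges == b.edges

    def test_p1_is_complete(self):
        assert random_connected_graph(2, 1.0, seed=0).m == 1
        assert random_connected_graph(6, 1.0, seed=0).m == 15
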